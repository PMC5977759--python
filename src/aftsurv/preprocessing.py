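"""Feature normalisation, filtering and univariate-Cox ranking.

The chain mirrors how the targeted study prepares RNA-seq features before
model fitting: a closed-form intron normalisation, removal of features with
over 80% zero counts among *training* samples, optional subsetting of genes
and transcripts to a disease-related gene list, ranking every feature by a
single-covariate Cox proportional-hazards fit on the training set, and
retention of the top-k (k=2000 in the study) smallest-p features.  All
decisions use training samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "RankingResult",
    "normalize_intron",
    "filter_zero_fraction",
    "subset_by_gene_list",
    "cox_univariate",
    "rank_features_cox",
    "select_top_k",
    "standardize",
    "read_feature_table",
    "read_gene_list",
]

FEATURE_KINDS = ("gene", "transcript", "intron", "clinical")


@dataclass
class FeatureTable:
    """A features x samples real matrix with an annotation kind.

    ``values`` is a DataFrame indexed by unique feature ids with sample ids
    as columns.
    """

    values: pd.DataFrame
    kind: str = "gene"

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(ids)], self.kind)


@dataclass
class RankingResult:
    """Univariate Cox ranking, sorted ascending by p-value (ties by id)."""

    feature_ids: list[str]
    pvalues: np.ndarray
    coef: np.ndarray
    converged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "coef": self.coef,
                "pvalue": self.pvalues,
                "rank": np.arange(1, len(self.feature_ids) + 1),
                "converged": self.converged,
            }
        )


def normalize_intron(supporting_reads, total_supporting_reads) -> np.ndarray | float:
    """log2((1 + supporting reads) * 1e6 / total supporting reads).

    The intron expression measure: reads supporting the intron, scaled per
    million reads supporting any intron, on a log2 scale with a +1 offset.
    """
    total = np.asarray(total_supporting_reads, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_supporting_reads must be positive (denominator)")
    reads = np.asarray(supporting_reads, dtype=float)
    if np.any(reads < 0):
        raise ValueError("supporting_reads must be non-negative")
    out = np.log2((1.0 + reads) * 1e6 / total)
    return float(out) if out.ndim == 0 else out


def filter_zero_fraction(
    table: FeatureTable, train_ids: Sequence[str], threshold: float = 0.8
) -> FeatureTable:
    """Drop features whose zero fraction among *training* samples is
    strictly greater than ``threshold`` (default: over 80% zeros).

    Test samples never influence the decision; a feature with exactly the
    threshold fraction of zeros is retained ("over" is strict).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("empty training set")
    missing = set(train_ids) - set(table.sample_ids)
    if missing:
        raise ValueError(f"train ids not in table: {sorted(missing)[:5]}")
    zero_frac = (table.values[train_ids] == 0).mean(axis=1)
    keep = zero_frac <= threshold
    return FeatureTable(table.values.loc[keep], table.kind)


def subset_by_gene_list(table: FeatureTable, gene_list: Iterable[str]) -> FeatureTable:
    """Keep gene/transcript features whose id is in ``gene_list``.

    Intron (and clinical) tables pass through unchanged — the disease gene
    list does not annotate introns.  An empty intersection returns an empty
    table with a warning.
    """
    if table.kind in ("intron", "clinical"):
        return table
    wanted = set(gene_list)
    keep = [fid for fid in table.feature_ids if fid in wanted]
    if not keep:
        warnings.warn(
            f"gene list does not intersect the {table.kind} table; "
            "returning an empty table",
            RuntimeWarning,
            stacklevel=2,
        )
    return FeatureTable(table.values.loc[keep], table.kind)


def cox_univariate(
    x: np.ndarray, times: np.ndarray, events: np.ndarray, max_iter: int = 50
) -> tuple[float, float, bool]:
    """Single-covariate Cox proportional-hazards fit (Breslow ties).

    Newton iteration on the log partial likelihood; returns
    ``(coef, wald_pvalue, converged)``.  A covariate with no variation has
    score identically zero and returns (0, 1, True).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if np.ptp(x) == 0:
        return 0.0, 1.0, True

    order = np.argsort(t, kind="stable")
    x, t, d = x[order], t[order], d[order]
    _, first_idx = np.unique(t, return_index=True)
    d_f = np.add.reduceat(d, first_idx)
    ev = d_f > 0
    # per distinct event time: sum of x over deaths and count of deaths
    sx_f = np.add.reduceat(d * x, first_idx)[ev]
    d_f = d_f[ev]
    start = first_idx[ev]  # risk set at time f = indices >= start

    # |beta| capped: a monotone partial likelihood (perfect concordance)
    # has no finite maximiser; the cap mirrors how survival packages
    # plateau, and the Wald p-value there is effectively the limit value
    BMAX = 15.0

    def suffix_sums(beta):
        z = beta * x
        w = np.exp(z - z.max())  # stabilised; S1/S0 etc. are scale-free
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w * x)[::-1])[::-1]
        s2 = np.cumsum((w * x * x)[::-1])[::-1]
        return s0[start], s1[start], s2[start]

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        S0, S1, S2 = suffix_sums(beta)
        U = float(np.sum(sx_f - d_f * S1 / S0))
        I = float(np.sum(d_f * (S2 / S0 - (S1 / S0) ** 2)))
        if not np.isfinite(I) or I <= 0:
            break
        new = float(np.clip(beta + np.clip(U / I, -5.0, 5.0), -BMAX, BMAX))
        delta_step = new - beta
        beta = new
        if abs(delta_step) < 1e-9:
            converged = True
            break
    if not converged or not np.isfinite(beta):
        return (beta if np.isfinite(beta) else 0.0), 1.0, False

    S0, S1, S2 = suffix_sums(beta)
    info = float(np.sum(d_f * (S2 / S0 - (S1 / S0) ** 2)))
    if not np.isfinite(info) or info <= 0:
        return beta, 1.0, False
    z = beta * np.sqrt(info)
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return beta, pval, True


def rank_features_cox(
    table: FeatureTable, times: Sequence[float], events: Sequence[int]
) -> RankingResult:
    """Rank every feature by its univariate Cox Wald p-value, ascending.

    One time/event pair per sample (in the table's column order) is
    required, along with at least one event.  Non-converging features are
    recorded with p-value 1 and a flag rather than aborting.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size != len(table.sample_ids) or d.size != t.size:
        raise ValueError("need one time/event per sample")
    if d.sum() == 0:
        raise ValueError("need at least one event to rank features")

    ids = table.feature_ids
    coefs = np.empty(len(ids))
    pvals = np.empty(len(ids))
    conv = np.empty(len(ids), dtype=bool)
    values = table.values.to_numpy(dtype=float)
    for j in range(len(ids)):
        coefs[j], pvals[j], conv[j] = cox_univariate(values[j], t, d)

    order = np.lexsort((np.asarray(ids, dtype=object), pvals))
    return RankingResult(
        feature_ids=[ids[i] for i in order],
        pvalues=pvals[order],
        coef=coefs[order],
        converged=conv[order],
    )


def select_top_k(ranking: RankingResult, k: int) -> list[str]:
    """The first min(k, available) feature ids in rank order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranking.feature_ids[:k]


def standardize(
    table: FeatureTable, train_ids: Sequence[str]
) -> tuple[FeatureTable, pd.Series, pd.Series]:
    """Centre and scale every feature using *training* moments.

    All samples are transformed with the training means/sds, which are
    returned so test-set and prediction-time inputs reuse the identical
    transform.  Features with zero training variance are dropped with a
    warning.  Note the transform is not idempotent: re-applying it to
    already-standardised values rescales by the stored moments again.
    """
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("empty training set")
    tr = table.values[train_ids]
    means = tr.mean(axis=1)
    sds = tr.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} zero-variance feature(s) before scaling",
            RuntimeWarning,
            stacklevel=2,
        )
    vals = table.values.loc[keep]
    out = vals.sub(means[keep], axis=0).div(sds[keep], axis=0)
    return FeatureTable(out, table.kind), means[keep], sds[keep]


def read_feature_table(path: str | Path, kind: str) -> FeatureTable:
    """Read a features x samples TSV (first column feature ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FeatureTable(df, kind)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines ignored."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }
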