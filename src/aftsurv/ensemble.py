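"""Bagging with out-of-bag rank aggregation across candidate models.

Candidate models (different feature sets x fitting methods) are compared
by bagging: in each of B iterations, resample n training patients with
replacement (the bag), fit every candidate on the bag, evaluate K
performance measures on the out-of-bag (OOB) patients, aggregate the K
rankings (Borda / mean rank), and keep the top-ranked model.  The ensemble
prediction is the plain average of the B kept members' predicted survival
times.  Defaults: B = 20 iterations, K = 3 measures (IPCW-RMSE lower is
better, the two LPS logrank statistics higher is better).

Because fitting requires complete data, censored training times are
imputed ONCE before bagging — by convention with the predicted times of
the single best individual model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .aft_fitters import AFTModelFit, predict_time
from .survival_stats import ipcw_rmse, logrank_test

__all__ = [
    "EnsembleSettings",
    "EnsembleCandidate",
    "BagRecord",
    "EnsembleModel",
    "draw_bag",
    "rank_aggregate",
    "evaluate_oob",
    "train_ensemble",
    "predict_ensemble",
]

logger = logging.getLogger(__name__)

#: default measure orientations: IPCW-RMSE small is good; the logrank
#: statistics measure group separation, so large is good
DEFAULT_MEASURES = (
    ("ipcw_rmse", "lower_better"),
    ("logrank_lps2", "higher_better"),
    ("logrank_lps5", "higher_better"),
)


@dataclass(frozen=True)
class EnsembleSettings:
    n_bags: int = 20  # B
    measures: tuple = DEFAULT_MEASURES  # K = len(measures)
    seed: int = 0
    lps_cutoffs: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self):
        if self.n_bags < 1:
            raise ValueError("n_bags must be positive")
        if not self.measures:
            raise ValueError("need at least one measure")


@dataclass
class EnsembleCandidate:
    """One candidate model: a name, a fitter and its training/test design
    matrices (the candidates differ in feature set, so each carries its
    own columns)."""

    name: str
    fitter: Callable[[np.ndarray, np.ndarray], AFTModelFit]
    X_train: np.ndarray


@dataclass
class BagRecord:
    iteration: int
    bag: np.ndarray
    oob: np.ndarray
    measure_values: np.ndarray  # K x M
    ranking: np.ndarray  # permutation of candidate indices, best first
    selected: int


@dataclass
class EnsembleModel:
    members: list[tuple[str, AFTModelFit]]
    records: list[BagRecord] = field(default_factory=list)
    candidate_names: list[str] = field(default_factory=list)


def draw_bag(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """n draws with replacement; OOB is the complement of the distinct bag
    set.  An empty OOB (possible for tiny n) triggers a logged redraw."""
    if n < 2:
        raise ValueError("need n >= 2 to bag")
    while True:
        bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), bag)
        if oob.size > 0:
            return bag, oob
        logger.info("empty OOB sample; redrawing bag")


def rank_aggregate(
    measures: np.ndarray, orientations: Sequence[str]
) -> np.ndarray:
    """Borda (mean-rank) aggregation of K measures over M models.

    ``measures`` is K x M; each row is ranked in its orientation (rank 1 =
    best, average ranks on ties; NaN = failed evaluation gets the worst
    rank).  Models are ordered by ascending mean rank; ties break by the
    first-listed measure's rank, then by model order.
    """
    measures = np.asarray(measures, dtype=float)
    if measures.ndim != 2 or measures.shape[0] != len(orientations):
        raise ValueError("measures must be K x M with one orientation per row")
    K, M = measures.shape
    from scipy.stats import rankdata

    ranks = np.empty((K, M))
    for k in range(K):
        row = measures[k].copy()
        if orientations[k] == "higher_better":
            row = -row
        elif orientations[k] != "lower_better":
            raise ValueError(f"unknown orientation {orientations[k]!r}")
        bad = np.isnan(row)
        if bad.any():
            logger.info("assigning worst rank to %d failed evaluation(s)", bad.sum())
            row[bad] = np.inf
        ranks[k] = rankdata(row, method="average")
    mean_rank = ranks.mean(axis=0)
    return np.lexsort((np.arange(M), ranks[0], mean_rank))


def evaluate_oob(
    fits: Sequence[AFTModelFit],
    candidates: Sequence[EnsembleCandidate],
    times: np.ndarray,
    events: np.ndarray,
    high_risk: np.ndarray | None,
    oob: np.ndarray,
    settings: EnsembleSettings = EnsembleSettings(),
) -> np.ndarray:
    """K x M matrix of OOB measure values; NaN marks a failed evaluation.

    Only rows indexed by ``oob`` are read — bag rows never influence the
    evaluation.  The LPS logrank measures are computed on the clinically
    high-risk members of the OOB sample when flags are supplied.
    """
    K, M = len(settings.measures), len(fits)
    out = np.full((K, M), np.nan)
    t_oob, d_oob = times[oob], events[oob]
    hr_mask = (
        high_risk[oob].astype(bool) if high_risk is not None
        else np.ones(oob.size, dtype=bool)
    )
    for m, (fit, cand) in enumerate(zip(fits, candidates)):
        if fit is None:
            continue
        pred = predict_time(fit, cand.X_train[oob])
        for k, (name, _) in enumerate(settings.measures):
            try:
                if name == "ipcw_rmse":
                    out[k, m] = ipcw_rmse(t_oob, d_oob, pred)
                elif name.startswith("logrank_lps"):
                    cutoff = settings.lps_cutoffs[0] if name.endswith("2") else settings.lps_cutoffs[1]
                    lab = (pred[hr_mask] <= cutoff).astype(int)
                    out[k, m] = logrank_test(
                        t_oob[hr_mask], d_oob[hr_mask], lab
                    ).statistic
                else:
                    raise ValueError(f"unknown measure {name!r}")
            except ValueError:
                pass  # degenerate OOB sample for this measure: stays NaN
    return out


def train_ensemble(
    candidates: Sequence[EnsembleCandidate],
    y_complete: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    high_risk: np.ndarray | None = None,
    settings: EnsembleSettings = EnsembleSettings(),
) -> EnsembleModel:
    """B bagging iterations of fit-all / rank-on-OOB / keep-the-best.

    ``y_complete`` are imputed-complete training times used for fitting;
    ``times``/``events`` are the original observed outcomes used by the OOB
    measures.  A candidate that fails to fit on a bag is assigned the worst
    rank for that iteration (logged), never an abort.
    """
    y_complete = np.asarray(y_complete, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = y_complete.size
    if times.size != n or events.size != n:
        raise ValueError("observed outcomes must match y_complete in length")
    rng = np.random.default_rng(settings.seed)
    orientations = [o for _, o in settings.measures]

    members: list[tuple[str, AFTModelFit]] = []
    records: list[BagRecord] = []
    logy = np.log(y_complete)
    for b in range(settings.n_bags):
        bag, oob = draw_bag(n, rng)
        fits: list[AFTModelFit | None] = []
        for cand in candidates:
            try:
                fits.append(cand.fitter(cand.X_train[bag], logy[bag]))
            except Exception as exc:  # noqa: BLE001
                logger.warning("candidate %s failed on bag %d: %s", cand.name, b, exc)
                fits.append(None)
        values = evaluate_oob(fits, candidates, times, events, high_risk, oob, settings)
        order = rank_aggregate(values, orientations)
        sel = next(int(i) for i in order if fits[i] is not None)
        members.append((candidates[sel].name, fits[sel]))
        records.append(BagRecord(b, bag, oob, values, order, sel))
    return EnsembleModel(members, records, [c.name for c in candidates])


def predict_ensemble(model: EnsembleModel, X_new_by_name: dict[str, np.ndarray]) -> np.ndarray:
    """Arithmetic mean over members of the predicted survival times (years).

    ``X_new_by_name`` maps candidate names to their design matrices for the
    new samples."""
    missing = {name for name, _ in model.members} - set(X_new_by_name)
    if missing:
        raise ValueError(f"missing design matrices for members: {sorted(missing)}")
    preds = [predict_time(fit, X_new_by_name[name]) for name, fit in model.members]
    return np.mean(preds, axis=0)
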