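"""End-to-end orchestration: preprocess, impute-and-fit each model spec,
evaluate on the test set, subclassify high-risk patients by predicted
survival, train the bagged ensemble, and write a report bundle.

A model spec combines a feature set — clinical covariates only, genes (G),
transcripts (T), introns (I), or transcripts+introns (TI) — with one of
the four fitting methods, numbered 1-4 for PLS, SPLS, lasso and elastic
net ("TI-4" is the elastic net on transcripts and introns).  Patients with
predicted survival at or below a cutoff t (2 or 5 years) are labelled LPS
(low predicted survival); the clinically high-risk subgroup is split into
LPS vs non-LPS and the groups compared by 2-year Kaplan-Meier survival and
the logrank test.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .aft_fitters import AFTModelFit, CVFitter, predict_time
from .ensemble import (
    EnsembleCandidate,
    EnsembleModel,
    EnsembleSettings,
    predict_ensemble,
    train_ensemble,
)
from .imputation import ImputationSettings, iterate_imputation
from .survival_stats import (
    LogrankResult,
    PerformanceReport,
    bootstrap_ci,
    harrell_c,
    ipcw_rmse,
    km_estimate,
    km_survival_at,
    logrank_test,
)
from .synthetic_data import SimulationDesign, SurvivalDataset, generate_dataset

__all__ = [
    "ModelSpec",
    "LPSLabeling",
    "HighRiskReport",
    "StudyConfig",
    "label_lps",
    "subclassify_high_risk",
    "derive_seed",
    "build_design_matrices",
    "run_model",
    "run_study",
]

METHOD_NUMBERS = {"1": "PLS", "2": "SPLS", "3": "LASSO", "4": "ELNET"}
FEATURE_SETS = ("clinical_only", "G", "T", "I", "TI")
KIND_OF = {"G": ["gene"], "T": ["transcript"], "I": ["intron"],
           "TI": ["transcript", "intron"]}


@dataclass(frozen=True)
class ModelSpec:
    feature_set: str  # clinical_only | G | T | I | TI
    method: str  # PLS | SPLS | LASSO | ELNET (ignored for clinical_only)
    outcome: str = "os"

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.feature_set != "clinical_only" and self.method not in (
            "PLS", "SPLS", "LASSO", "ELNET"
        ):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def name(self) -> str:
        if self.feature_set == "clinical_only":
            return "null"
        num = {v: k for k, v in METHOD_NUMBERS.items()}[self.method]
        return f"{self.feature_set}-{num}"

    @classmethod
    def parse(cls, label: str, outcome: str = "os") -> "ModelSpec":
        """Parse labels like ``null``, ``G-1``, ``TI-4``."""
        if label == "null":
            return cls("clinical_only", "OLS", outcome)
        fs, _, num = label.partition("-")
        if fs not in KIND_OF or num not in METHOD_NUMBERS:
            raise ValueError(f"cannot parse model label {label!r}")
        return cls(fs, METHOD_NUMBERS[num], outcome)


@dataclass
class LPSLabeling:
    """Low-predicted-survival labels: label 1 iff yhat <= cutoff years."""

    cutoff: float
    labels: np.ndarray


@dataclass
class HighRiskReport:
    """Subclassification of the clinically high-risk test patients."""

    cutoff: float
    labeling: LPSLabeling  # restricted to HR patients
    logrank: LogrankResult | None
    km_lps: object | None  # KMCurve per group, None when group empty
    km_nonlps: object | None
    surv2y: dict  # group -> {"prob", "se", "n"} at the 2-year mark


def label_lps(predictions, t: float) -> LPSLabeling:
    if t <= 0:
        raise ValueError("cutoff t must be positive")
    pred = np.asarray(predictions, dtype=float)
    return LPSLabeling(cutoff=t, labels=(pred <= t).astype(int))


def subclassify_high_risk(times, events, high_risk, predictions, t: float = 2.0,
                          at_years: float = 2.0) -> HighRiskReport:
    """Split the clinically high-risk patients into LPS vs non-LPS and
    compare their survival: logrank test plus per-group Kaplan-Meier
    survival probability (with Greenwood SE) at ``at_years``.

    With an empty group the logrank entry is None and only the non-empty
    group's KM summary is reported.
    """
    t_arr = np.asarray(times, dtype=float)
    d_arr = np.asarray(events, dtype=int)
    hr = np.asarray(high_risk, dtype=int).astype(bool)
    pred = np.asarray(predictions, dtype=float)
    if not hr.any():
        raise ValueError("no clinically high-risk patients present")
    th, dh, ph = t_arr[hr], d_arr[hr], pred[hr]
    lab = label_lps(ph, t)

    curves, surv2y = {}, {}
    for g, name in ((1, "lps"), (0, "nonlps")):
        mask = lab.labels == g
        if mask.sum() == 0:
            curves[name] = None
            continue
        km = km_estimate(th[mask], dh[mask])
        prob, se = km_survival_at(km, at_years)
        curves[name] = km
        surv2y[name] = {"prob": prob, "se": se, "n": int(mask.sum())}

    if curves["lps"] is None or curves["nonlps"] is None:
        lr = None
    else:
        lr = logrank_test(th, dh, lab.labels)
    return HighRiskReport(t, lab, lr, curves["lps"], curves["nonlps"], surv2y)


def derive_seed(master: int, *tags) -> int:
    """Deterministic child seed below 2^31 from a master seed and stage
    tags (strings are hashed with crc32; the scheme is the documented
    counter for every stochastic stage of a study run)."""
    parts = [int(master) & 0x7FFFFFFF]
    for tag in tags:
        parts.append(zlib.crc32(str(tag).encode()) if isinstance(tag, str) else int(tag))
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# feature assembly


def build_design_matrices(
    dataset: SurvivalDataset,
    spec: ModelSpec,
    top_k: int = 2000,
    zero_threshold: float = 0.8,
    gene_list=None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X_train, X_test, feature ids) for a spec, using training samples
    only for filtering, ranking and scaling.

    For TI the transcript and intron sets are processed independently (each
    filtered, ranked and truncated to ``top_k``) and concatenated.
    """
    train_ids, test_ids = dataset.train_ids, dataset.test_ids
    if spec.feature_set == "clinical_only":
        clin = dataset.clinical
        age = clin["age_days"].astype(float)
        mu, sd = age.loc[train_ids].mean(), age.loc[train_ids].std(ddof=1)
        design = pd.DataFrame(
            {
                "sex": clin["sex"].astype(float),
                "age_std": (age - mu) / (sd if sd > 0 else 1.0),
                "mycn_status": clin["mycn_status"].astype(float),
            }
        )
        return (
            design.loc[train_ids].to_numpy(),
            design.loc[test_ids].to_numpy(),
            list(design.columns),
        )

    times, events = dataset.outcome(spec.outcome, train_ids)
    blocks_train, blocks_test, ids = [], [], []
    for kind in KIND_OF[spec.feature_set]:
        table = dataset.expression[kind]
        table = prep.filter_zero_fraction(table, train_ids, zero_threshold)
        if gene_list is not None:
            table = prep.subset_by_gene_list(table, gene_list)
        if not table.feature_ids:
            continue
        train_table = prep.FeatureTable(table.values[train_ids], table.kind)
        ranking = prep.rank_features_cox(train_table, times, events)
        keep = prep.select_top_k(ranking, top_k)
        table = table.subset_features(keep)
        std, _, _ = prep.standardize(table, train_ids)
        blocks_train.append(std.values[train_ids].to_numpy(dtype=float).T)
        blocks_test.append(std.values[test_ids].to_numpy(dtype=float).T)
        ids.extend(std.feature_ids)
    if not blocks_train:
        raise ValueError(f"no features survived preprocessing for {spec.name}")
    return np.hstack(blocks_train), np.hstack(blocks_test), ids


# ---------------------------------------------------------------------------
# per-model run


@dataclass
class ModelRunResult:
    spec: ModelSpec
    fit: AFTModelFit
    predictions_test: np.ndarray
    report: PerformanceReport
    lps2: LPSLabeling
    lps5: LPSLabeling
    hr_report: HighRiskReport | None
    cv_mse: float | None
    X_train: np.ndarray = field(repr=False, default=None)
    X_test: np.ndarray = field(repr=False, default=None)
    feature_ids: list = field(default_factory=list)
    trace: list = field(default_factory=list)


def _evaluate(
    times, events, high_risk, predictions, n_boot: int, seed: int
) -> tuple[PerformanceReport, HighRiskReport | None]:
    rmse = ipcw_rmse(times, events, predictions)
    c = harrell_c(times, events, predictions)
    ci = {
        "rmse": bootstrap_ci(ipcw_rmse, (times, events, predictions), n_boot,
                             derive_seed(seed, "boot-rmse")),
        "c_index": bootstrap_ci(harrell_c, (times, events, predictions), n_boot,
                                derive_seed(seed, "boot-c")),
    }

    hr_mask = high_risk.astype(bool) if high_risk is not None else None
    lrs = {}
    if hr_mask is not None and hr_mask.any():
        for t in (2.0, 5.0):
            th, dh, ph = times[hr_mask], events[hr_mask], predictions[hr_mask]
            lab = label_lps(ph, t).labels
            lrs[t] = logrank_test(th, dh, lab) if 0 < lab.sum() < lab.size else None
            if lrs[t] is not None:
                def stat(tt, dd, pp, _t=t):
                    ll = label_lps(pp, _t).labels
                    if not 0 < ll.sum() < ll.size:
                        return np.nan
                    return logrank_test(tt, dd, ll).statistic

                try:
                    ci[f"logrank_lps{int(t)}"] = bootstrap_ci(
                        stat, (th, dh, ph), n_boot, derive_seed(seed, f"boot-lr{t}")
                    )
                except RuntimeError:
                    pass
        hr_rep = subclassify_high_risk(times, events, hr_mask, predictions, t=2.0)
    else:
        lrs = {2.0: None, 5.0: None}
        hr_rep = None
    report = PerformanceReport(rmse, c, lrs.get(2.0), lrs.get(5.0), ci)
    return report, hr_rep


def run_model(
    dataset: SurvivalDataset,
    spec: ModelSpec,
    imputation: ImputationSettings | None = None,
    master_seed: int = 0,
    top_k: int = 2000,
    n_boot: int = 1000,
    retune: str = "first",
    grid=None,
    gene_list=None,
) -> ModelRunResult:
    """Full single-model analysis: preprocess, impute-and-fit on the
    training set, predict test-set survival times, evaluate all measures
    with bootstrap CIs, and produce the LPS outputs."""
    X_train, X_test, ids = build_design_matrices(dataset, spec, top_k,
                                                 gene_list=gene_list)
    y_tr, d_tr = dataset.outcome(spec.outcome, dataset.train_ids)
    y_te, d_te = dataset.outcome(spec.outcome, dataset.test_ids)
    hr_te = dataset.high_risk(dataset.test_ids)

    method = "OLS_CLINICAL" if spec.feature_set == "clinical_only" else spec.method
    fitter = CVFitter(method, retune=retune, grid=grid,
                      cv_seed=derive_seed(master_seed, spec.name, "cv"))
    imp = imputation or ImputationSettings()
    imp = ImputationSettings(imp.n_outer, imp.n_datasets,
                             derive_seed(master_seed, spec.name, "imp", imp.seed))
    fit, trace = iterate_imputation(X_train, y_tr, d_tr, fitter, imp)
    fit.feature_ids = ids

    pred = predict_time(fit, X_test)
    report, hr_rep = _evaluate(y_te, d_te, hr_te, pred, n_boot,
                               derive_seed(master_seed, spec.name))
    return ModelRunResult(
        spec=spec,
        fit=fit,
        predictions_test=pred,
        report=report,
        lps2=label_lps(pred, 2.0),
        lps5=label_lps(pred, 5.0),
        hr_report=hr_rep,
        cv_mse=fitter.cv_mse_,
        X_train=X_train,
        X_test=X_test,
        feature_ids=ids,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# study driver


@dataclass
class StudyConfig:
    """Configuration of a full study run (YAML-serialisable).

    ``models`` are labels like ``null``, ``G-1``, ``TI-4``; the ensemble
    pools the listed models.  Seeds for every stochastic stage derive from
    ``master_seed`` via :func:`derive_seed`.
    """

    outcome: str = "os"
    models: tuple = ("null", "T-1", "I-3", "TI-4")
    run_ensemble: bool = True
    master_seed: int = 0
    n_outer: int = 5
    n_datasets: int = 5
    retune: str = "first"
    top_k: int = 2000
    n_boot: int = 1000
    n_bags: int = 20
    design: dict = field(default_factory=dict)  # SimulationDesign overrides
    data_dir: str | None = None  # read real data instead of simulating
    gene_list: str | None = None
    grids: dict = field(default_factory=dict)  # per-method CV grid overrides

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.setdefault("models", None)
        if raw["models"] is None:
            raw.pop("models")
        else:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_dataset(config: StudyConfig) -> SurvivalDataset:
    if config.data_dir:
        ddir = Path(config.data_dir)
        clinical = pd.read_csv(ddir / "clinical.csv", index_col="sample_id")
        expression = {}
        for kind in ("gene", "transcript", "intron"):
            path = ddir / f"expression_{kind}.tsv"
            if path.exists():
                expression[kind] = prep.read_feature_table(path, kind)
        return SurvivalDataset(clinical, expression)
    design = SimulationDesign(
        **{"seed": derive_seed(config.master_seed, "simulate"), **config.design}
    )
    dataset, _ = generate_dataset(design)
    return dataset


def _table1_rows(outcome: str, label: str, result_hr: HighRiskReport | None,
                 rows: list) -> None:
    if result_hr is None:
        return
    p = result_hr.logrank.pvalue if result_hr.logrank else np.nan
    for group in ("lps", "nonlps"):
        if group in result_hr.surv2y:
            s = result_hr.surv2y[group]
            rows.append(
                {
                    "outcome": outcome.upper(),
                    "model": label,
                    "group": "LPS" if group == "lps" else "non-LPS",
                    "prob_2yr": round(s["prob"], 6),
                    "se_2yr": round(s["se"], 6),
                    "n": s["n"],
                    "logrank_p": round(p, 6) if np.isfinite(p) else "",
                }
            )


def run_study(config: StudyConfig, outdir) -> dict:
    """Drive the whole analysis and write the report bundle.

    Writes per-model report JSONs, a Table-1-equivalent CSV of the
    high-risk subclassification (outcome, model, group, 2-year survival,
    SE, N, logrank p), per-group KM curve CSVs, and a run manifest.
    Partial failures are recorded in the manifest; the returned dict has a
    ``failed`` list the CLI turns into a nonzero exit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = _load_dataset(config)
    imp = ImputationSettings(config.n_outer, config.n_datasets, 0)

    results: dict[str, ModelRunResult] = {}
    failed: list[dict] = []
    table_rows: list[dict] = []
    for label in config.models:
        spec = ModelSpec.parse(label, config.outcome)
        grid = config.grids.get(spec.method) if spec.feature_set != "clinical_only" else None
        try:
            res = run_model(
                dataset, spec, imp, config.master_seed, config.top_k,
                config.n_boot, config.retune, grid,
                gene_list=set(prep.read_gene_list(config.gene_list))
                if config.gene_list else None,
            )
        except Exception as exc:  # noqa: BLE001 — record and continue
            failed.append({"model": label, "error": str(exc)})
            continue
        results[label] = res
        (outdir / f"report_{label}.json").write_text(
            json.dumps({"model": label, "outcome": config.outcome,
                        "tuning": res.fit.to_dict()["tuning"],
                        "cv_mse": res.cv_mse,
                        **res.report.to_dict()}, indent=2)
        )
        _table1_rows(config.outcome, label, res.hr_report, table_rows)
        if res.hr_report:
            for group, km in (("LPS", res.hr_report.km_lps),
                              ("nonLPS", res.hr_report.km_nonlps)):
                if km is not None:
                    km.to_frame().to_csv(
                        outdir / f"km_{label}_{group}.csv", index=False,
                        float_format="%.10g",
                    )

    if config.run_ensemble and len(results) >= 2:
        ens_label = "ensemble"
        try:
            ens_res = _run_ensemble_stage(config, dataset, results)
            results[ens_label] = ens_res
            (outdir / f"report_{ens_label}.json").write_text(
                json.dumps({"model": ens_label, "outcome": config.outcome,
                            **ens_res.report.to_dict()}, indent=2)
            )
            _table1_rows(config.outcome, ens_label, ens_res.hr_report, table_rows)
        except Exception as exc:  # noqa: BLE001
            failed.append({"model": ens_label, "error": str(exc)})

    table = pd.DataFrame(
        table_rows,
        columns=["outcome", "model", "group", "prob_2yr", "se_2yr", "n", "logrank_p"],
    )
    table.to_csv(outdir / "table1_equivalent.csv", index=False, float_format="%.10g")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "config_digest": config.digest(),
        "master_seed": config.master_seed,
        "models_run": sorted(results),
        "failed": failed,
        "n_train": len(dataset.train_ids),
        "n_test": len(dataset.test_ids),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_ensemble_stage(
    config: StudyConfig,
    dataset: SurvivalDataset,
    results: dict[str, ModelRunResult],
) -> ModelRunResult:
    """Bagged-ensemble stage over the already-run individual models.

    The censored training times are imputed once using the predictions of
    the best individual model (lowest CV error); each candidate refits with
    its tuning frozen at the individual model's final choice.
    """
    y_tr, d_tr = dataset.outcome(config.outcome, dataset.train_ids)
    hr_tr = dataset.high_risk(dataset.train_ids)
    y_te, d_te = dataset.outcome(config.outcome, dataset.test_ids)
    hr_te = dataset.high_risk(dataset.test_ids)

    scored = {k: v for k, v in results.items() if v.cv_mse is not None}
    best_label = min(scored, key=lambda k: scored[k].cv_mse)
    best = results[best_label]
    pred_train = predict_time(best.fit, best.X_train)
    y_complete = np.where(d_tr == 1, y_tr,
                          np.maximum(pred_train, np.nextafter(y_tr, np.inf)))

    candidates = []
    for label, res in results.items():
        method = "OLS_CLINICAL" if res.spec.feature_set == "clinical_only" else res.spec.method
        tuning = _final_tuning(res)
        fitter = CVFitter(method, retune="never", tuning=tuning) \
            if method != "OLS_CLINICAL" else CVFitter(method)
        candidates.append(EnsembleCandidate(label, fitter, res.X_train))

    settings = EnsembleSettings(
        n_bags=config.n_bags, seed=derive_seed(config.master_seed, "ensemble")
    )
    model = train_ensemble(candidates, y_complete, y_tr, d_tr, hr_tr, settings)
    X_test_by_name = {label: results[label].X_test for label in results}
    pred = predict_ensemble(model, X_test_by_name)
    report, hr_rep = _evaluate(y_te, d_te, hr_te, pred, config.n_boot,
                               derive_seed(config.master_seed, "ensemble"))
    return ModelRunResult(
        spec=ModelSpec.parse(best_label, config.outcome),
        fit=best.fit,
        predictions_test=pred,
        report=report,
        lps2=label_lps(pred, 2.0),
        lps5=label_lps(pred, 5.0),
        hr_report=hr_rep,
        cv_mse=None,
    )


def _final_tuning(res: ModelRunResult) -> dict | None:
    """Tuning of the last refit inside the imputation loop (majority of the
    final iteration's datasets, falling back to the first)."""
    tuning = res.fit.tuning
    per = tuning.get("per_dataset")
    if per:
        tuning = per[0]
    keep = {k: v for k, v in tuning.items() if k in ("v", "eta", "lambda", "alpha")}
    return keep or None
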