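"""End-to-end orchestration: simulate -> impute -> score -> evaluate.

A :class:`RunConfig` fixes every seed and tuning knob; re-running an
identical config reproduces every emitted artifact byte for byte.  The
global seed fans out to per-stage seeds through numpy ``SeedSequence`` with a
fixed per-stage spawn key, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    brier,
    calibration_bins,
    calibration_slope,
    fit_risk_model,
    precision_recall,
    select_threshold_for_ppv,
)
from .contribution import DEFAULT_HYPERPARAMS, stratum_contrast
from .discrimination import auroc, delong_compare, fit_age_spline, sliding_window_auroc
from .errors import ConfigurationError
from .imputation import ImputationConfig, apply_exclusions, impute
from .io import read_cohort_csv, write_cohort_csv, write_table
from .score_engine import compute_all_scores, load_default_definitions
from .synthetic import CohortConfig, generate_cohort

_STAGES = ("simulate", "missingness", "impute", "evaluate", "contribution")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global, spawn_key=stage index)."""
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=global_seed,
                                spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    seed: int = 1
    input_csv: str | None = None       # score an existing cohort instead of simulating
    n: int = 20000
    prevalence: float = 0.024
    severity_shift: float = 1.0
    age_fade: float = 0.0
    missing_rate: float = 0.02
    m_imputations: int = 20
    bootstrap_B: int = 2000
    ppv_margins: tuple = (0.05, 0.10)
    window_width: int = 5
    window_step: int = 1
    min_window_events: int = 10
    spline_df: int = 3
    age_cut: int = 87
    shap_B: int = 1000
    max_shap_samples: int = 1000
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    run_contribution: bool = True

    def validate(self) -> None:
        if list(self.ppv_margins) != sorted(self.ppv_margins):
            raise ConfigurationError("ppv_margins must be sorted ascending")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = json.load(fh)
        cfg = cls(**obj)
        cfg.validate()
        return cfg


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages, write the report bundle, return the metrics dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort --------------------------------------------------------
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
    else:
        cc = CohortConfig(
            n=config.n,
            prevalence=config.prevalence,
            seed=stage_seed(config.seed, "simulate"),
            severity_shift=config.severity_shift,
            age_fade=config.age_fade,
            missing_rate=config.missing_rate,
        )
        cohort = generate_cohort(cc).records
        write_cohort_csv(cohort, out / "cohort.csv")

    # --- exclusions and imputation ------------------------------------
    retained, exclusion_log = apply_exclusions(cohort)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(exclusion_log, fh, indent=2, sort_keys=True)
    completed = impute(
        retained,
        ImputationConfig(m=config.m_imputations,
                         seed=stage_seed(config.seed, "impute")),
    )
    write_cohort_csv(completed, out / "completed.csv")

    # --- scoring -------------------------------------------------------
    definitions = load_default_definitions()
    scores = compute_all_scores(completed, definitions)
    scored = pd.concat(
        [completed[["patient_id", "age", "outcome24h"]].reset_index(drop=True),
         scores.reset_index(drop=True)], axis=1,
    )
    write_table(scored, out / "scores.csv")

    y = completed["outcome24h"].astype(int).to_numpy()
    ages = completed["age"].to_numpy()
    eval_seed = stage_seed(config.seed, "evaluate")
    metrics: dict = {"scores": {}, "delong": [], "spline": {}}

    # --- discrimination ------------------------------------------------
    disc_rows = []
    roc_results = {}
    for name in scores.columns:
        r = auroc(scores[name].to_numpy(), y)
        roc_results[name] = r
        disc_rows.append({
            "score": name, "auroc": r.auroc,
            "ci_low": r.ci95[0], "ci_high": r.ci95[1],
            "n_pos": r.n_pos, "n_neg": r.n_neg,
        })
        metrics["scores"][name] = {"auroc": r.auroc, "auroc_ci": list(r.ci95)}
    write_table(pd.DataFrame(disc_rows), out / "discrimination.csv")

    best = max(roc_results, key=lambda k: roc_results[k].auroc)
    pair_rows = []
    names = list(scores.columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cmpres = delong_compare(scores[a].to_numpy(), scores[b].to_numpy(), y)
            pair_rows.append({
                "score_a": a, "score_b": b,
                "delta_auroc": cmpres.delta_auroc,
                "z": cmpres.z, "p": cmpres.p,
            })
            metrics["delong"].append(pair_rows[-1])
    write_table(pd.DataFrame(pair_rows), out / "delong_pairs.csv")

    # --- calibration ---------------------------------------------------
    best_pred = fit_risk_model(scores[best].to_numpy(), y).probabilities
    cal_rows, bin_frames = [], []
    for name in names:
        rm = fit_risk_model(scores[name].to_numpy(), y)
        br = brier(rm.probabilities, y, B=config.bootstrap_B, seed=eval_seed,
                   ref_pred=None if name == best else best_pred)
        slope, intercept = calibration_slope(rm.probabilities, y)
        bins = calibration_bins(rm.probabilities, y)
        bins.insert(0, "score", name)
        bin_frames.append(bins)
        cal_rows.append({
            "score": name, "brier": br.brier,
            "brier_ci_low": br.ci95[0], "brier_ci_high": br.ci95[1],
            "p_vs_null": br.p_vs_null,
            "p_vs_best": br.p_vs_ref if name != best else np.nan,
            "slope": slope, "intercept": intercept,
            "separation_flag": rm.separation,
        })
        metrics["scores"][name].update({"brier": br.brier, "slope": slope})
    null_p = float(y.mean())
    metrics["null_brier"] = null_p * (1 - null_p)
    write_table(pd.DataFrame(cal_rows), out / "calibration.csv")
    write_table(pd.concat(bin_frames, ignore_index=True), out / "calibration_bins.csv")

    # --- classification ------------------------------------------------
    thr_rows, pr_rows = [], []
    for name in names:
        s = scores[name].to_numpy()
        for margin in config.ppv_margins:
            tm = select_threshold_for_ppv(s, y, margin)
            thr_rows.append({
                "score": name, "margin": margin, "attainable": tm.attainable,
                "threshold": tm.threshold,
                "sens": tm.sens, "spec": tm.spec, "ppv": tm.ppv, "npv": tm.npv,
                "tp": tm.tp, "fp": tm.fp, "tn": tm.tn, "fn": tm.fn,
            })
        pr = precision_recall(s, y)
        metrics["scores"][name]["auprc"] = pr.auprc
        pr_rows.append(pd.DataFrame({
            "score": name,
            "recall": pr.recall[:-1][::-1],
            "precision": pr.precision[:-1][::-1],
        }))
    write_table(pd.DataFrame(thr_rows), out / "thresholds.csv")
    write_table(pd.concat(pr_rows, ignore_index=True), out / "pr_curves.csv")

    # --- AUROC by age --------------------------------------------------
    win_rows, spl_rows = [], []
    for name in names:
        series = sliding_window_auroc(
            ages, scores[name].to_numpy(), y,
            width=config.window_width, step=config.window_step,
            min_events=config.min_window_events,
        )
        frame = pd.DataFrame({
            "score": name,
            "center": series.window_centers,
            "auroc": series.window_auroc,
            "n": series.window_n,
            "events": series.window_events,
        })
        if len(series.window_centers) >= config.spline_df + 2:
            fit = fit_age_spline(series, df=config.spline_df)
            frame["spline_pred"] = fit.predicted
            frame["spline_lo"] = fit.ci_low
            frame["spline_hi"] = fit.ci_high
            spl_rows.append({"score": name, "f_stat": fit.f_stat,
                             "p_value": fit.p_value,
                             "n_windows": len(series.window_centers)})
            metrics["spline"][name] = {"f": fit.f_stat, "p": fit.p_value}
        win_rows.append(frame)
    write_table(pd.concat(win_rows, ignore_index=True), out / "age_windows.csv")
    write_table(pd.DataFrame(spl_rows), out / "spline_stats.csv")

    # --- contribution --------------------------------------------------
    if config.run_contribution:
        report = stratum_contrast(
            completed, age_cut=config.age_cut, B=config.shap_B,
            seed=stage_seed(config.seed, "contribution"),
            hyperparams=config.hyperparams,
            max_shap_samples=config.max_shap_samples,
        )
        contrib = pd.DataFrame({
            "feature": report.older.features,
            "raw_younger": report.younger.mean_abs_shap.values,
            "raw_older": report.older.mean_abs_shap.values,
            "norm_younger": report.younger.normalized.values,
            "norm_older": report.older.normalized.values,
            "shap_difference": report.shap_difference.values,
            "p_boot": report.p_boot.values,
        })
        write_table(contrib, out / "contribution.csv")
        metrics["contribution"] = {
            "age_cut": report.age_cut,
            "shap_difference": report.shap_difference.to_dict(),
            "p_boot": report.p_boot.to_dict(),
        }

    # --- manifest and metrics -----------------------------------------
    import scipy
    import sklearn
    import statsmodels

    manifest = {
        "config": asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "versions": {
            "ewsbench": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
    return metrics
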