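"""End-to-end orchestration: simulate, fit, analyze, classify, ablate.

A run directory is self-contained: the echoed configuration (with its hash),
the dataset (connectome, per-subject spectra and optional time series,
cohort table), per-subject fit results, and JSON + Markdown reports.  Every
numeric report cell is reproducible from the run directory's configuration
and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .connectome import ConnectomeGraph, load_connectome, save_connectome
from .fitting import FitConfig, fit_cohort
from .sgm import FrequencyGrid, RegionalSpectrum
from .spectral import (
    RegionalTimeSeries,
    autocorr_timescale,
    bandpass_filter,
)
from .synth import CohortSpec, synth_cohort, synth_connectome, synth_timeseries

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "MODES"]

MODES = ("simulate", "fit", "analyze", "classify", "ablate", "all")


class DependencyError(RuntimeError):
    """A stage was requested before its upstream artifacts exist."""


@dataclass
class PipelineConfig:
    """Structured configuration for a pipeline run.

    Simulate-mode fields control the synthetic cohort; path fields point at
    externally supplied data and take precedence over simulation when set.
    """

    out_dir: str = "run"
    seed: int = 0
    # simulate mode
    n_regions: int = 68
    n_control: int = 10
    n_ad: int = 10
    noise_db: float = 1.0
    effect_mode: str = "default"
    with_timeseries: bool = True
    timeseries_regions: int = 8
    timeseries_duration: float = 60.0
    timeseries_fs: float = 600.0
    timeseries_tau_scale: float = 5.0  # target tau_ac = scale * tau_G
    # frequency grid
    f_lo: float = 1.0
    f_hi: float = 35.0
    f_step: float = 0.25
    # external inputs (non-simulate runs)
    connectome_path: str | None = None
    distance_path: str | None = None
    labels_path: str | None = None
    spectra_dir: str | None = None
    cohort_path: str | None = None
    # fitting
    maxiter: int = 500
    K: int | None = None
    w: float = 10.0
    # analysis / classification
    repeats: int = 100
    n_estimators: int = 100
    ablation_maxiter: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.default(self.f_lo, self.f_hi, self.f_step)


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {**_provenance(config), **payload}
    path.write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = [
            f"{v:.4g}" if isinstance(v, (float, np.floating)) else str(v)
            for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _write_spectrum(path: Path, spec: RegionalSpectrum) -> None:
    df = pd.DataFrame(spec.values, index=spec.labels,
                      columns=[f"{f:g}" for f in spec.grid.frequencies])
    df.to_csv(path, index_label="region")


def _read_spectrum(path: Path, grid: FrequencyGrid) -> RegionalSpectrum:
    df = pd.read_csv(path, index_col="region")
    freqs = np.array([float(c) for c in df.columns])
    if not np.allclose(freqs, grid.frequencies):
        raise ValueError(f"{path} frequency columns do not match the grid")
    return RegionalSpectrum(values=df.to_numpy(), grid=grid,
                            labels=list(df.index), kind="empirical")


def _dataset_dir(config: PipelineConfig) -> Path:
    return Path(config.out_dir) / "dataset"


def _load_dataset(config: PipelineConfig):
    """Graph, grid, cohort table and per-subject spectra for downstream
    stages, from explicit paths when configured, else the run's dataset."""
    ds = _dataset_dir(config)
    grid = config.grid()
    if config.connectome_path:
        graph = load_connectome(config.connectome_path, config.distance_path,
                                config.labels_path)
        cohort_csv = Path(config.cohort_path)
        spectra_dir = Path(config.spectra_dir)
    else:
        if not (ds / "connectome.csv").exists():
            raise DependencyError(
                "no dataset found; run the 'simulate' stage first or point "
                "the config at external connectome/spectra/cohort paths"
            )
        graph = load_connectome(ds / "connectome.csv", ds / "distances.csv",
                                ds / "labels.txt")
        cohort_csv = ds / "cohort.csv"
        spectra_dir = ds / "spectra"
    table = pd.read_csv(cohort_csv)
    spectra = {
        row_id: _read_spectrum(spectra_dir / f"{row_id}.csv", grid)
        for row_id in table["id"]
        if (spectra_dir / f"{row_id}.csv").exists()
    }
    return graph, grid, table, spectra


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig) -> None:
    ds = _dataset_dir(config)
    (ds / "spectra").mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    graph = synth_connectome(config.n_regions, seed=config.seed)
    save_connectome(graph, ds / "connectome.csv", ds / "distances.csv",
                    ds / "labels.txt")
    np.savetxt(ds / "frequencies.csv", grid.frequencies, fmt="%g")

    spec = CohortSpec(n_control=config.n_control, n_ad=config.n_ad,
                      noise_db=config.noise_db,
                      effect_mode=config.effect_mode, seed=config.seed)
    table, spectra = synth_cohort(spec, graph, grid)
    table.to_csv(ds / "cohort.csv", index=False)
    _write_json(ds / "ground_truth.json", {
        "note": "synthetic cohort; the cohort table holds the ground-truth "
                "parameters used to generate each subject's spectra",
        "cohort_spec": dataclasses.asdict(spec),
    }, config)
    for sid, s in spectra.items():
        _write_spectrum(ds / "spectra" / f"{sid}.csv", s)

    if config.with_timeseries:
        tdir = ds / "timeseries"
        tdir.mkdir(exist_ok=True)
        rng = np.random.default_rng(config.seed + 1)
        for _, row in table.iterrows():
            tau = config.timeseries_tau_scale * row["tau_G_ms"] / 1e3
            ts = synth_timeseries(
                tau, n_regions=config.timeseries_regions,
                fs=config.timeseries_fs, duration=config.timeseries_duration,
                seed=int(rng.integers(2 ** 31)),
            )
            np.savetxt(tdir / f"{row['id']}.csv", ts.values, fmt="%.6g",
                       delimiter=",")
        (tdir / "meta.json").write_text(json.dumps(
            {"fs": config.timeseries_fs,
             "duration": config.timeseries_duration}))
    logger.info("simulated cohort of %d+%d subjects in %s",
                config.n_control, config.n_ad, ds)


def _fits_path(config: PipelineConfig) -> Path:
    return Path(config.out_dir) / "fits" / "fits.csv"


def _stage_fit(config: PipelineConfig) -> pd.DataFrame:
    graph, grid, table, spectra = _load_dataset(config)
    if not spectra:
        raise DependencyError("no per-subject spectra found; run 'simulate'")
    fit_config = FitConfig(maxiter=config.maxiter, w=config.w,
                           seed=config.seed, K=config.K)
    out = _fits_path(config)
    fits = fit_cohort(spectra, graph, fit_config, out_dir=out.parent)
    fits.to_csv(out, index=False)
    logger.info("fitted %d subjects -> %s", len(fits), out)
    return fits


def _require_fits(config: PipelineConfig) -> pd.DataFrame:
    out = _fits_path(config)
    if not out.exists():
        raise DependencyError(
            f"{out} not found; run the 'fit' stage before this one"
        )
    return pd.read_csv(out)


def _merged_table(config: PipelineConfig) -> pd.DataFrame:
    _, _, table, _ = _load_dataset(config)
    fits = _require_fits(config)
    fitted_cols = ["id"] + [c for c in fits.columns
                            if c in cohort_mod.PARAM_REPORT_COLUMNS
                            or c in ("spectral_r", "spatial_r", "objective",
                                     "stage", "converged")]
    merged = table[["id", "group", "age", "mmse", "cdr"]].merge(
        fits[fitted_cols], on="id", how="inner")
    if "converged" in merged:
        merged = merged[merged["converged"].astype(bool)]
    return merged


def _stage_analyze(config: PipelineConfig) -> dict:
    reports = Path(config.out_dir) / "reports"
    reports.mkdir(parents=True, exist_ok=True)
    merged = _merged_table(config)

    comparison_rows = [
        cohort_mod.adjusted_group_compare(merged, p, m_tests=7).to_dict()
        for p in cohort_mod.PARAM_REPORT_COLUMNS
    ]
    comp_df = pd.DataFrame(comparison_rows)
    comp_df.to_csv(reports / "group_comparison.csv", index=False)

    sig_predictors = ["tau_G_ms", "tau_e_ms", "g_ii"]
    regressions = {}
    for outcome in ("mmse", "cdr"):
        if merged[outcome].notna().sum() < len(sig_predictors) + 3:
            continue
        regressions[outcome] = {
            "univariate": {
                p: cohort_mod.regress_cognition(merged, outcome, [p])
                for p in sig_predictors
            },
            "multivariate": cohort_mod.regress_cognition(
                merged, outcome, sig_predictors, include_age=True),
        }

    timescales = _timescale_analysis(config, merged)

    payload = {"group_comparison": comparison_rows,
               "cognition_regressions": regressions,
               "timescales": timescales}
    _write_json(reports / "analysis.json", payload, config)
    md = ["# Cohort analysis", "", "## Group comparison (age-adjusted)", "",
          _markdown_table(comp_df.drop(columns=["ci_control", "ci_ad"]))]
    if timescales:
        md += ["## Intrinsic timescales", "",
               f"control mean {timescales['mean_control']:.4f} s, "
               f"patient mean {timescales['mean_ad']:.4f} s, "
               f"KS p = {timescales['ks_p']:.3g}", ""]
    (reports / "analysis.md").write_text("\n".join(md))
    logger.info("analysis reports written to %s", reports)
    return payload


def _timescale_analysis(config: PipelineConfig, merged: pd.DataFrame):
    tdir = _dataset_dir(config) / "timeseries"
    if not tdir.exists():
        return None
    meta = json.loads((tdir / "meta.json").read_text())
    taus = {}
    for sid in merged["id"]:
        path = tdir / f"{sid}.csv"
        if not path.exists():
            continue
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        ts = RegionalTimeSeries(values=values, fs=meta["fs"])
        ts = bandpass_filter(ts, config.f_lo, config.f_hi)
        taus[sid] = autocorr_timescale(ts).tau_ac
    if not taus:
        return None
    merged = merged.set_index("id")
    ctrl = [t for s, t in taus.items() if merged.loc[s, "group"] != "AD"]
    ad = [t for s, t in taus.items() if merged.loc[s, "group"] == "AD"]
    if min(len(ctrl), len(ad)) >= 5:
        stat, p = cohort_mod.ks_group_test(ctrl, ad)
    else:  # KS needs >= 5 per sample; report means only on tiny cohorts
        stat, p = float("nan"), float("nan")
    return {"tau_ac": taus, "mean_control": float(np.mean(ctrl)),
            "mean_ad": float(np.mean(ad)), "ks_stat": stat, "ks_p": p}


def _stage_classify(config: PipelineConfig) -> cohort_mod.ClassificationReport:
    reports = Path(config.out_dir) / "reports"
    reports.mkdir(parents=True, exist_ok=True)
    merged = _merged_table(config)
    features = list(cohort_mod.PARAM_REPORT_COLUMNS) + ["age"]
    cc = cohort_mod.ClassifyConfig(repeats=config.repeats,
                                   n_estimators=config.n_estimators,
                                   seed=config.seed)
    report = cohort_mod.classify_groups(merged, features, cc)
    _write_json(reports / "classification.json", report.to_dict(), config)
    pd.DataFrame(report.confusion,
                 index=["true_control", "true_AD"],
                 columns=["pred_control", "pred_AD"]).to_csv(
        reports / "confusion.csv")
    (reports / "classification.md").write_text(
        "# Classification (random forest, nested stratified CV)\n\n"
        f"AUROC {report.auroc_mean:.3f} ± {report.auroc_sd:.3f}; "
        f"accuracy {report.accuracy:.3f}, precision {report.precision:.3f}, "
        f"recall {report.recall:.3f}, F1 {report.f1:.3f}\n\n"
        "Importance order: "
        + ", ".join(report.importance_order()) + "\n")
    logger.info("classification AUROC %.3f", report.auroc_mean)
    return report


def _stage_ablate(config: PipelineConfig) -> cohort_mod.AblationResult:
    reports = Path(config.out_dir) / "reports"
    reports.mkdir(parents=True, exist_ok=True)
    graph, grid, table, spectra = _load_dataset(config)
    fits = _require_fits(config)
    mean_params = cohort_mod.cohort_mean_parameters(fits)

    cls_json = reports / "classification.json"
    if cls_json.exists():
        data = json.loads(cls_json.read_text())
        importances = data["feature_importances"]
        order = [f for f in sorted(importances, key=importances.get,
                                   reverse=True) if f != "age"]
    else:
        raise DependencyError(
            "classification report not found; run 'classify' first to "
            "establish the parameter importance order"
        )
    order_natural = [cohort_mod._REPORT_TO_NATURAL[c][0] for c in order]
    fit_config = FitConfig(
        maxiter=config.ablation_maxiter or config.maxiter,
        w=config.w, seed=config.seed, K=config.K,
    )
    result = cohort_mod.parameter_ablation(
        spectra, graph, mean_params, order_natural, fit_config)
    payload = {
        "stages": [
            {"free": list(free), "mean_spectral_r": sr, "mean_spatial_r": pr}
            for free, sr, pr in result.stages
        ],
        "spectral_gains": [
            {"freed": name, "gain": g} for name, g in result.spectral_gains()
        ],
    }
    _write_json(reports / "ablation.json", payload, config)
    result.per_subject.to_csv(reports / "ablation_per_subject.csv",
                              index=False)
    (reports / "ablation.md").write_text(
        "# Parameter ablation\n\n"
        + _markdown_table(pd.DataFrame(payload["stages"]).assign(
            free=lambda d: d["free"].map(
                lambda f: ",".join(f) if f else "None"))))
    logger.info("ablation complete: %d stages", len(result.stages))
    return result


def run_pipeline(config: PipelineConfig, mode: str = "all") -> Path:
    """Execute the requested stage(s) in dependency order.

    Returns the run directory.  ``all`` runs simulate, fit, analyze,
    classify and ablate in sequence on a simulated cohort.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(
        {**config.to_dict(), "config_hash": config.config_hash()}))

    if mode in ("simulate", "all"):
        _stage_simulate(config)
    if mode in ("fit", "all"):
        _stage_fit(config)
    if mode in ("analyze", "all"):
        _stage_analyze(config)
    if mode in ("classify", "all"):
        _stage_classify(config)
    if mode in ("ablate", "all"):
        _stage_ablate(config)
    return out
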