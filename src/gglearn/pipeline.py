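"""End-to-end orchestration: simulate -> fit -> analyze, with manifests.

One global seed deterministically fans out into per-module seeds via
``numpy.random.SeedSequence`` (spawn keys 0..3 for simulate / fit /
classification / spare), so a partial rerun of any step with the same
global seed reproduces its outputs byte for byte.  Every CSV written
carries a leading comment line recording the seed and a hash of the
configuration; readers skip ``#`` lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import association_table, proportional_odds_fit
from .errors import DataError
from .estimation import FEATURE_COLUMNS, PriorConfig, QuadratureConfig, fit_cohort
from .prediction import CVConfig, compare_predictors
from .simulate import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "derive_seeds", "run_simulate", "run_fit",
           "run_analyze", "run_all", "read_csv"]


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-module seeds from one global seed (< 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    names = ["simulate", "fit", "classify", "spare"]
    return {
        name: int(np.random.SeedSequence(global_seed, spawn_key=(i,)).generate_state(1)[0] % 2**31)
        for i, name in enumerate(names)
    } | {"global": int(global_seed) % 2**31 if global_seed >= 0 else 0, "_entropy": int(ss.entropy)}


@dataclass(frozen=True)
class PipelineConfig:
    """Global configuration bundling every module's knobs plus one seed."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prior: PriorConfig = field(default_factory=PriorConfig)
    quadrature: QuadratureConfig = field(default_factory=QuadratureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if seed is not None:
            kwargs["seed"] = int(seed)
        for key, cls_ in (("cohort", CohortConfig), ("prior", PriorConfig),
                          ("quadrature", QuadratureConfig), ("cv", CVConfig)):
            if key in raw:
                sub = dict(raw[key])
                if key == "cohort" and "trials_per_stage" in sub:
                    sub["trials_per_stage"] = tuple(sub["trials_per_stage"])
                if key == "cv" and "c_grid" in sub:
                    sub["c_grid"] = tuple(float(c) for c in sub["c_grid"])
                kwargs[key] = cls_(**sub)
        kwargs["verbose"] = bool(raw.get("verbose", False))
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# gglearn seed={config.seed} config_sha={config.config_hash()}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping manifest comment lines."""
    return pd.read_csv(path, comment="#")


def _write_manifest(out: Path, config: PipelineConfig, files: list[str]) -> None:
    manifest = {
        "seed": config.seed,
        "config_sha": config.config_hash(),
        "derived_seeds": {k: v for k, v in derive_seeds(config.seed).items()
                          if not k.startswith("_")},
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write trials / clinical / truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    cohort = generate_cohort(config.cohort, seed=seeds["simulate"])
    paths = {}
    for name, df in (("trials", cohort.trials), ("clinical", cohort.clinical),
                     ("truth", cohort.truth)):
        p = out / f"{name}.csv"
        _write_csv(df, p, config)
        paths[name] = p
    _write_manifest(out, config, [p.name for p in paths.values()])
    return paths


def run_fit(trials_path: str | Path, config: PipelineConfig,
            out_dir: str | Path) -> dict[str, Path]:
    """Fit the learning-curve model for every patient in a trials CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = read_csv(trials_path)
    features, diagnostics = fit_cohort(trials, config.prior, config.quadrature)
    paths = {"features": out / "features.csv",
             "fit_diagnostics": out / "fit_diagnostics.csv"}
    _write_csv(features, paths["features"], config)
    _write_csv(diagnostics, paths["fit_diagnostics"], config)
    return paths


def _check_keys(features: pd.DataFrame, clinical: pd.DataFrame) -> None:
    f_ids = set(features["patient_id"])
    c_ids = set(clinical["patient_id"])
    orphans_f = sorted(f_ids - c_ids)
    orphans_c = sorted(c_ids - f_ids)
    if orphans_f or orphans_c:
        raise DataError(
            "patient key mismatch between feature and clinical tables; "
            f"only in features: {orphans_f[:10]}; only in clinical: {orphans_c[:10]}"
        )


def run_analyze(features_path: str | Path, clinical_path: str | Path,
                config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Association tables, ordinal models and the classifier comparison."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = read_csv(features_path)
    clinical = read_csv(clinical_path)
    _check_keys(features, clinical)
    merged = features.merge(clinical, on="patient_id", how="inner")
    merged = merged.dropna(subset=FEATURE_COLUMNS + ["moca_total", "dgi_total"])

    assoc = association_table(features, clinical)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gg_fit = proportional_odds_fit(
            merged[FEATURE_COLUMNS], merged["dgi_total"].to_numpy()
        )
        moca_fit = proportional_odds_fit(
            merged[["moca_total"]], merged["dgi_total"].to_numpy()
        )
    ord_gg = pd.DataFrame({
        "variable": gg_fit.coefficients.index,
        "coefficient": gg_fit.coefficients.to_numpy(),
        "p_value": gg_fit.p_values.to_numpy(),
        "converged": gg_fit.converged,
    })
    ord_moca = pd.DataFrame({
        "variable": moca_fit.coefficients.index,
        "coefficient": moca_fit.coefficients.to_numpy(),
        "p_value": moca_fit.p_values.to_numpy(),
        "converged": moca_fit.converged,
    })

    seeds = derive_seeds(config.seed)
    cv = dataclasses.replace(config.cv, seed=seeds["classify"])
    report = compare_predictors(
        merged[FEATURE_COLUMNS], merged["moca_total"].to_numpy(),
        merged["dgi_total"].to_numpy(), cv,
    )

    oof = pd.DataFrame({
        "patient_id": merged["patient_id"],
        "label": report.labels,
        "gg_score": report.gg.scores,
        "moca_score": report.moca.scores,
    })
    roc_gg = pd.DataFrame({"fpr": report.gg.fpr, "tpr": report.gg.tpr})
    roc_moca = pd.DataFrame({"fpr": report.moca.fpr, "tpr": report.moca.tpr})

    summary = {
        "n_patients": int(len(merged)),
        "dgi_median": report.median,
        "gg_accuracy": report.gg.accuracy,
        "moca_accuracy": report.moca.accuracy,
        "gg_binomial_p": report.gg.binomial_p,
        "moca_binomial_p": report.moca.binomial_p,
        "gg_auc": report.gg.auc,
        "moca_auc": report.moca.auc,
        "delong_p_one_sided": report.delong.p_value,
        "top_correlated_variable": assoc.loc[assoc["estimate"].abs().idxmax(), "variable"],
    }

    paths = {}
    for name, df in (("association", assoc), ("ordinal_gg", ord_gg),
                     ("ordinal_moca", ord_moca), ("oof_scores", oof),
                     ("roc_gg", roc_gg), ("roc_moca", roc_moca)):
        p = out / f"{name}.csv"
        _write_csv(df, p, config)
        paths[name] = p

    lines = [
        f"# gglearn analysis summary (seed={config.seed}, "
        f"config_sha={config.config_hash()})",
        f"patients analyzed: {summary['n_patients']}",
        f"DGI median: {summary['dgi_median']:.1f}",
        "",
        "strongest DGI association: "
        f"{summary['top_correlated_variable']} "
        f"(estimate {assoc['estimate'].abs().max():.3f})",
        "",
        "classification of DGI above/below median:",
        f"  game-features arm: accuracy {summary['gg_accuracy']:.3f} "
        f"(binomial p vs chance {summary['gg_binomial_p']:.4f}), "
        f"AUC {summary['gg_auc']:.3f}",
        f"  MoCA arm:          accuracy {summary['moca_accuracy']:.3f} "
        f"(binomial p vs chance {summary['moca_binomial_p']:.4f}), "
        f"AUC {summary['moca_auc']:.3f}",
        f"  DeLong one-sided p (game AUC > MoCA AUC): "
        f"{summary['delong_p_one_sided']:.4f}",
        "",
    ]
    (out / "summary.txt").write_text("\n".join(lines))
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    paths["summary"] = out / "summary.txt"
    paths["summary_json"] = out / "summary.json"
    return paths


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """simulate -> fit -> analyze in one deterministic pass."""
    out = Path(out_dir)
    sim = run_simulate(config, out)
    fit = run_fit(sim["trials"], config, out)
    ana = run_analyze(fit["features"], sim["clinical"], config, out)
    return {**sim, **fit, **ana}
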