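"""End-to-end pipeline: simulate -> count model -> Monte Carlo dose-response
-> predictions -> stranding presence model.

Every stage writes plain-text artifacts (CSV/JSON) under one output
directory; the run manifest records the configuration, per-stage status and
SHA-256 digests of every artifact, so a rerun with the same configuration
reproduces every output bit-identically.  The manifest deliberately carries
no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import counts, doseresp, intervals, simulate, strandnet
from .contrasts import contrasts_frame
from .records import write_necropsy, write_strandnet


@dataclass
class PipelineConfig:
    seed: int = 0
    n_reps: int = 1000
    out_dir: str = "results/pipeline"
    alpha: float = 0.05
    conservative: bool = False   # which variant drives the headline curve
    n_strandnet: int = 706
    generator: simulate.GeneratorParams = field(
        default_factory=simulate.GeneratorParams)
    prediction: doseresp.PredictionContext = field(
        default_factory=doseresp.PredictionContext)

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        pred = d.pop("prediction", {})
        cfg = cls(**d)
        if gen:
            cfg.generator = cfg.generator.with_(**gen)
        if pred:
            cfg.prediction = doseresp.PredictionContext(**pred)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    A stage failure stops the pipeline; the manifest then records the failed
    stage and a machine-readable error entry instead of raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "versions": _versions(),
        "stages": {},
        "artifacts": {},
        "status": "ok",
    }

    def artifact(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)}

    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("count_model", _stage_count_model),
        ("dose_mc", _stage_dose_mc),
        ("predictions", _stage_predictions),
        ("strandnet", _stage_strandnet),
    ]
    for name, fn in stages:
        try:
            info = fn(config, out, state, artifact)
            manifest["stages"][name] = {"status": "ok", **(info or {})}
        except Exception as exc:  # recorded, not propagated
            manifest["stages"][name] = {
                "status": "failed", "error_type": type(exc).__name__,
                "error": str(exc)}
            manifest["status"] = "failed"
            manifest["failed_stage"] = name
            break

    _write_json(manifest, out / "manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["generator"]["nb_mu_by_age_species"] = {
        f"{a}|{s}": v
        for (a, s), v in config.generator.nb_mu_by_age_species.items()}
    return d


def _versions() -> dict:
    vers = {}
    for pkg in ("turtledose", "numpy", "scipy", "pandas", "statsmodels"):
        try:
            vers[pkg] = metadata.version(pkg)
        except metadata.PackageNotFoundError:
            vers[pkg] = "unknown"
    return vers


def _stage_simulate(config, out, state, artifact):
    gen = config.generator.with_(seed=config.seed)
    records = simulate.generate_necropsy_cohort(gen)
    path = out / "necropsy.csv"
    write_necropsy(records, path)
    artifact("necropsy_csv", path)
    state["necropsy"] = records
    return {"n_animals": len(records), "seed": config.seed}


def _stage_count_model(config, out, state, artifact):
    records = state["necropsy"]
    specs = [counts.CountModelSpec(c) for c in counts.MODEL_CODES]
    table, fits = counts.select_by_aic(records, specs)
    table.to_csv(out / "count_model_aic.csv", index=False)
    artifact("count_model_aic_csv", out / "count_model_aic.csv")

    best_code = table[table["converged"]]["code"].iloc[0]
    best = fits[best_code]
    coef = pd.DataFrame({
        "term": best.coefficients.index,
        "estimate": best.coefficients.to_numpy(),
        "se": best.std_errors.to_numpy()})
    coef["z"] = coef["estimate"] / coef["se"]
    from scipy import stats as _st
    coef["p"] = 2 * _st.norm.sf(np.abs(coef["z"]))
    coef.to_csv(out / "count_model_coefficients.csv", index=False)
    artifact("count_model_coefficients_csv",
             out / "count_model_coefficients.csv")

    info = {"best_model": best_code,
            "dispersion": best.dispersion,
            "separation_flags": list(best.separation_flags)}
    if best.cause_ref is not None:
        results, letters = counts.pairwise_cause_contrasts(
            best, alpha=config.alpha)
        contrasts_frame(results, letters).to_csv(
            out / "count_cause_contrasts.csv", index=False)
        artifact("count_cause_contrasts_csv",
                 out / "count_cause_contrasts.csv")
        info["cause_letters"] = letters
    state["count_best"] = best
    return info


def _stage_dose_mc(config, out, state, artifact):
    records = state["necropsy"]
    specs = [intervals.DoseModelSpec(code, cons)
             for cons in (False, True)
             for code in intervals.DOSE_MODEL_CODES]
    table, ensembles = intervals.mc_model_selection(
        records, specs, n_reps=config.n_reps, seed=config.seed + 2)
    table.to_csv(out / "dose_model_aic.csv", index=False)
    artifact("dose_model_aic_csv", out / "dose_model_aic.csv")

    by_label = {e.spec.label: e for e in ensembles}
    # headline model: count/CCL + age class — it carries the ecological
    # covariates predictions need; the AIC table is emitted for comparison
    best_label = "3b" if config.conservative else "3a"
    best = by_label[best_label]
    state["dose_ensembles"] = by_label
    state["dose_best"] = best

    reps = best.replicate_stats[~best.replicate_stats["failed"]]
    reps[["rep", "slope_estimate", "slope_se", "slope_p_value",
          "log_likelihood", "aic"]].to_csv(
        out / "dose_mc_replicates.csv", index=False)
    artifact("dose_mc_replicates_csv", out / "dose_mc_replicates.csv")
    _write_json(best.summary_dict(), out / "dose_ensemble.json")
    artifact("dose_ensemble_json", out / "dose_ensemble.json")
    return {"prediction_model": best_label,
            "aic_best_model": table[
                table["conservative"] == config.conservative].iloc[0][
                "model"],
            "share_slope_significant": best.share_slope_significant,
            "mc_seed": config.seed + 2}


def _stage_predictions(config, out, state, artifact):
    best = state["dose_best"]
    records = state["necropsy"]
    ctx = config.prediction
    curve = doseresp.predict_curve(best, ctx)
    curve.frame().to_csv(out / "dose_response_curve.csv", index=False)
    artifact("dose_response_curve_csv", out / "dose_response_curve.csv")

    # rug of observed loads split into control (KNP) vs plastic-implicated
    df = intervals._as_frame(records)
    rug = pd.DataFrame({
        "load": df["debris_count"],
        "group": np.where(df["cod"] == "KNP", "known_non_plastic",
                          np.where(df["cod"].isin(["Ind", "KP"]),
                                   "plastic_implicated", "unknown"))})
    rug.to_csv(out / "dose_response_rug.csv", index=False)
    artifact("dose_response_rug_csv", out / "dose_response_rug.csv")

    coefs = best.median_coefficients
    summary = {
        "model": best.spec.label,
        "context": {"ccl_cm": ctx.ccl_cm, "age_class": ctx.age_class},
        "p_at_single_item": doseresp.mortality_at_load(coefs, ctx, 1.0),
        "ed50_reference_animal": doseresp.invert_for_probability(
            coefs, ctx, 0.5),
        "ed50_population": doseresp.population_ed50(best, records),
        "load_at_near_certain_death": doseresp.load_at_near_certain_death(
            coefs, ctx),
    }
    _write_json(summary, out / "dose_predictions.json")
    artifact("dose_predictions_json", out / "dose_predictions.json")
    return {k: v for k, v in summary.items() if k != "context"}


def _stage_strandnet(config, out, state, artifact):
    gen = config.generator.with_(seed=config.seed + 1)
    records = simulate.generate_strandnet_records(gen, config.n_strandnet)
    path = out / "strandnet.csv"
    write_strandnet(records, path)
    artifact("strandnet_csv", path)

    table, fits = strandnet.presence_model_selection(records)
    table.to_csv(out / "strandnet_aic.csv", index=False)
    artifact("strandnet_aic_csv", out / "strandnet_aic.csv")

    full = fits[frozenset(strandnet.TERMS)]
    coef = pd.DataFrame({"term": full.coefficients.index,
                         "estimate": full.coefficients.to_numpy(),
                         "se": full.std_errors.to_numpy()})
    coef.to_csv(out / "strandnet_coefficients.csv", index=False)
    artifact("strandnet_coefficients_csv", out / "strandnet_coefficients.csv")

    results, letters = strandnet.pairwise_cause_comparisons(
        full, alpha=config.alpha)
    contrasts_frame(results, letters).to_csv(
        out / "strandnet_cause_contrasts.csv", index=False)
    artifact("strandnet_cause_contrasts_csv",
             out / "strandnet_cause_contrasts.csv")
    return {"best_terms": table["terms"].iloc[0], "cause_letters": letters,
            "strandnet_seed": config.seed + 1}


# ---------------------------------------------------------------------------
# report rendering

_SECTIONS = [
    ("Count model selection", ["count_model_aic_csv",
                               "count_model_coefficients_csv"]),
    ("Cause-of-death contrasts (debris counts)",
     ["count_cause_contrasts_csv"]),
    ("Dose-response model selection and slope distribution",
     ["dose_model_aic_csv", "dose_mc_replicates_csv", "dose_ensemble_json"]),
    ("Mortality curve and headline predictions",
     ["dose_response_curve_csv", "dose_response_rug_csv",
      "dose_predictions_json"]),
    ("Stranding-register presence/absence model",
     ["strandnet_aic_csv", "strandnet_coefficients_csv",
      "strandnet_cause_contrasts_csv"]),
]


def render_report(manifest: dict) -> str:
    """One markdown document embedding the pipeline's tables.

    Sections whose artifacts are missing are rendered as unavailable; the
    report always renders.
    """
    lines = ["# Plastic-ingestion mortality pipeline report", ""]
    lines.append(f"Run status: **{manifest.get('status', 'unknown')}**"
                 + (f" (failed at stage `{manifest['failed_stage']}`)"
                    if manifest.get("failed_stage") else ""))
    lines.append("")
    for title, keys in _SECTIONS:
        lines.append(f"## {title}")
        lines.append("")
        available = [k for k in keys if k in manifest.get("artifacts", {})]
        missing = [k for k in keys if k not in manifest.get("artifacts", {})]
        for key in available:
            path = Path(manifest["artifacts"][key]["path"])
            lines.append(f"Artifact `{key}`: `{path}`")
            lines.append("")
            if path.suffix == ".csv" and path.exists():
                lines.extend(_markdown_table(path))
            elif path.suffix == ".json" and path.exists():
                lines.append("```json")
                lines.append(path.read_text().strip())
                lines.append("```")
            lines.append("")
        for key in missing:
            lines.append(f"Artifact `{key}`: **unavailable**")
            lines.append("")
    return "\n".join(lines) + "\n"


def _markdown_table(path: Path, max_rows: int = 25) -> list[str]:
    df = pd.read_csv(path)
    shown = df.head(max_rows)
    header = "| " + " | ".join(map(str, shown.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(shown.columns)) + "|"
    rows = ["| " + " | ".join(_fmt(v) for v in row) + " |"
            for row in shown.itertuples(index=False)]
    note = ([f"({len(df) - max_rows} further rows omitted)"]
            if len(df) > max_rows else [])
    return [header, sep, *rows, *note]


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
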