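"""End-to-end pipeline: simulate -> fit -> coefficients -> discriminate ->
predict -> report.

``run_pipeline`` produces, under ``output_dir``: the cohort CSV, a fit
report JSON (one row per inter-endpoint law), the coefficient/audit JSON,
a discrimination JSON (per-endpoint grade comparisons and the binary
grouping), a per-record predictions CSV, and a human-readable summary.
Every artifact embeds the master seed and a hash of the configuration, and
the whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .cohort import Cohort, patmmax, read_cohort_csv, write_cohort_csv
from .coefficients import (
    audit_internal_consistency,
    check_ode_consistency,
    default_coefficients,
)
from .discrimination import (
    ENDPOINTS,
    binary_discrimination,
    grade_discrimination,
)
from .exceptions import ParameterError
from .laws import fit_endpoint_laws
from .predict import classify_phenotype, grade_from_patmmax, grade_from_sf2
from .simulate import GroundTruthParams, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("radiosens")

_STAGES = ("survival", "laws", "coefficients", "discrimination", "prediction")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    cohort_size: int = 200
    output_dir: Path = Path("radiosens_out")
    ground_truth: GroundTruthParams = field(default_factory=GroundTruthParams)
    cohort_csv: Optional[Path] = None  # load instead of simulating
    stages: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ParameterError("cohort_size must be >= 1")
        self.output_dir = Path(self.output_dir)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ParameterError(f"unknown pipeline stages: {sorted(unknown)}")
        self.stages = {s: self.stages.get(s, True) for s in _STAGES}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohort_size": self.cohort_size,
            "output_dir": str(self.output_dir),
            "ground_truth": dataclasses.asdict(self.ground_truth),
            "cohort_csv": None if self.cohort_csv is None else str(self.cohort_csv),
            "stages": dict(self.stages),
        }

    def config_hash(self) -> str:
        # output_dir is excluded: it does not affect the results
        payload = {k: v for k, v in self.to_dict().items()
                   if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        gt = raw.pop("ground_truth", None)
        if isinstance(gt, dict):
            from .simulate import GradeDistribution
            gt = dict(gt)
            dist = gt.pop("grade_distribution", None)
            if isinstance(dist, dict):
                dist = GradeDistribution(tuple(dist["probs"]))
            elif isinstance(dist, (list, tuple)):
                dist = GradeDistribution(tuple(dist))
            kwargs = {}
            if dist is not None:
                kwargs["grade_distribution"] = dist
            targets = gt.pop("sf2_subset_targets", "unset")
            if targets != "unset":
                kwargs["sf2_subset_targets"] = (
                    None if targets is None else tuple(targets))
            gt = GroundTruthParams(**gt, **kwargs)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if gt is not None:
            raw["ground_truth"] = gt
        return cls(**raw)


def _json_dump(path: Path, payload: dict, meta: dict) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump({"meta": meta, **payload}, handle, indent=2, default=float)
        handle.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns a dict of artifact paths/results."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    artifacts: dict = {"meta": meta}
    params = config.ground_truth

    # --- cohort --------------------------------------------------------
    logger.info("stage cohort: %s",
                "loading" if config.cohort_csv else "simulating")
    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
    else:
        cohort = simulate_cohort(config.cohort_size, params, seed=config.seed)
    cohort_path = out / "cohort.csv"
    write_cohort_csv(
        cohort, cohort_path,
        header_comment=f"seed={config.seed} config_hash={meta['config_hash']}",
    )
    artifacts["cohort_csv"] = cohort_path
    artifacts["cohort"] = cohort

    with_sf2 = config.stages["survival"]

    # --- laws ----------------------------------------------------------
    fits = {}
    if config.stages["laws"]:
        logger.info("stage laws: fitting inter-endpoint laws")
        include = None
        if not with_sf2:
            include = ("patmmax_vs_grade",)
        fits = fit_endpoint_laws(cohort, include=include)
        _json_dump(out / "laws.json",
                   {"laws": {k: v.to_dict() for k, v in fits.items()}}, meta)
        artifacts["laws_json"] = out / "laws.json"
        artifacts["laws"] = fits

    # --- coefficients --------------------------------------------------
    if config.stages["coefficients"]:
        logger.info("stage coefficients: deriving k0..k4 and auditing")
        coeffs = default_coefficients()
        audit = audit_internal_consistency(coeffs, fits) if fits else {}
        residuals = check_ode_consistency(coeffs)
        _json_dump(out / "coefficients.json", {
            "coefficients": coeffs.to_dict(),
            "audit": audit,
            "ode_max_residuals": residuals,
        }, meta)
        artifacts["coefficients_json"] = out / "coefficients.json"
        artifacts["coefficients"] = coeffs

    # --- discrimination ------------------------------------------------
    if config.stages["discrimination"]:
        logger.info("stage discrimination: one-way ANOVA per endpoint")
        endpoints = [e for e in ENDPOINTS if with_sf2 or e != "sf2"]
        grades_block, binary_block = {}, {}
        for endpoint in endpoints:
            try:
                grades_block[endpoint] = grade_discrimination(
                    cohort, endpoint).to_dict()
            except Exception as exc:
                grades_block[endpoint] = {"error": str(exc)}
            try:
                f_stat, p = binary_discrimination(cohort, endpoint)
                binary_block[endpoint] = {"F": f_stat, "p": p}
            except Exception as exc:
                binary_block[endpoint] = {"error": str(exc)}
        _json_dump(out / "discrimination.json", {
            "grade_comparisons": grades_block,
            "binary": binary_block,
        }, meta)
        artifacts["discrimination_json"] = out / "discrimination.json"
        artifacts["discrimination"] = {"grade_comparisons": grades_block,
                                       "binary": binary_block}

    # --- predictions ---------------------------------------------------
    if config.stages["prediction"]:
        logger.info("stage prediction: inverting laws per record")
        rows = []
        sf2_fit = fits.get("sf2_vs_grade")
        patm_fit = fits.get("patmmax_vs_grade")
        for rec in cohort:
            row = {"id": rec.id, "ctcae_grade": rec.ctcae_grade,
                   "genotype": rec.genotype.value}
            if sf2_fit is not None and rec.sf2 is not None:
                pred = grade_from_sf2(rec.sf2, sf2_fit)
                row["grade_from_sf2"] = pred.continuous_grade
                row["grade_from_sf2_rounded"] = pred.rounded_grade
            if patm_fit is not None and (rec.patm_10min is not None
                                         or rec.patm_1h is not None):
                pred = grade_from_patmmax(patmmax(rec), patm_fit)
                row["grade_from_patmmax"] = pred.continuous_grade
                row["grade_from_patmmax_rounded"] = pred.rounded_grade
            try:
                row["phenotype"] = classify_phenotype(rec, params,
                                                      fit=patm_fit)
            except Exception:
                row["phenotype"] = None
            rows.append(row)
        frame = pd.DataFrame(rows)
        pred_path = out / "predictions.csv"
        with open(pred_path, "w", encoding="utf-8", newline="") as handle:
            handle.write(f"# seed={config.seed} "
                         f"config_hash={meta['config_hash']}\n")
            frame.to_csv(handle, index=False)
        artifacts["predictions_csv"] = pred_path
        artifacts["predictions"] = frame

    # --- summary -------------------------------------------------------
    summary = _render_summary(config, artifacts)
    summary_path = out / "summary.txt"
    summary_path.write_text(summary, encoding="utf-8")
    artifacts["summary_txt"] = summary_path
    return artifacts


def _render_summary(config: PipelineConfig, artifacts: dict) -> str:
    meta = artifacts["meta"]
    lines = [
        "radiosens pipeline summary",
        f"seed={meta['seed']} config_hash={meta['config_hash']}",
        f"cohort: {len(artifacts['cohort'])} records",
        "",
    ]
    grades = [r.ctcae_grade for r in artifacts["cohort"]]
    counts = {g: grades.count(g) for g in range(6)}
    lines.append("CTCAE grade counts: "
                 + " ".join(f"{g}:{counts[g]}" for g in range(6)))
    fits = artifacts.get("laws", {})
    if fits:
        lines.append("")
        lines.append("fitted inter-endpoint laws:")
        for name, fit in fits.items():
            pars = " ".join(f"{k}={v:.4g}" for k, v in fit.params.items())
            lines.append(f"  {name}: {fit.law} {pars} "
                         f"r2_adj={fit.r2_adjusted:.4f} rmse={fit.rmse:.4g} "
                         f"n={fit.n}")
    disc = artifacts.get("discrimination")
    if disc:
        lines.append("")
        lines.append("binary discrimination (grades 0-2 vs 3-5):")
        for endpoint, block in disc["binary"].items():
            if "p" in block:
                lines.append(f"  {endpoint}: F={block['F']:.4g} "
                             f"p={block['p']:.4g}")
            else:
                lines.append(f"  {endpoint}: {block['error']}")
    preds = artifacts.get("predictions")
    if preds is not None and "phenotype" in preds:
        lines.append("")
        counts = preds["phenotype"].value_counts(dropna=True).to_dict()
        lines.append("phenotype counts: "
                     + " ".join(f"{k}:{v}" for k, v in sorted(counts.items())))
    lines.append("")
    return "\n".join(lines)
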