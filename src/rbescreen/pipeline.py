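"""End-to-end orchestration: screen -> cutoff -> dichotomize -> survival.

The pipeline mirrors the biomarker-discovery workflow the package supports:
(1) rank-based differential screen of a two-condition expression matrix;
(2) ROC/cutoff evaluation of a candidate transcript against control levels;
(3) dichotomization of the clinical cohort (median by default);
(4) relapse-free survival, cumulative incidence of relapse with competing
    death in remission, group tests, and a multivariate Cox model with
    backward elimination.

Outputs are deterministic given the configuration (including its seed): the
same config written twice produces byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, RBEScreenError
from .io import read_clinical, read_expression
from .rank import collapse_probes, rank_transform, rbe_curve, score_genes, screen_genes
from .roc import dichotomize_median, roc_auc
from .survival import (
    backward_eliminate,
    cif_fit,
    gray_test,
    km_fit,
    logrank,
    point_estimate_at,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    expression_path: str | None = None
    annotation_path: str | None = None
    conditions_path: str | None = None
    case_label: str = "case"
    control_label: str = "control"
    delta_min: float = 45.0
    ars_min: float = 80.0
    rbe_bandwidth: float = 3.0

    clinical_path: str | None = None
    level_column: str = "level"
    control_levels_path: str | None = None  # CSV with a `level` column (normals)
    dichotomize: str = "median"  # "median" | "youden" | "fixed"
    fixed_cutoff: float | None = None
    covariates: list[str] = field(default_factory=list)
    landmark_months: float = 60.0
    tie_method: str = "efron"
    keep_alpha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_min", "ars_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigurationError(f"{name}={v} outside [0, 100]")
        if not 0 < self.keep_alpha < 1:
            raise ConfigurationError(f"keep_alpha={self.keep_alpha} outside (0, 1)")
        if self.dichotomize not in ("median", "youden", "fixed"):
            raise ConfigurationError(f"unknown dichotomization mode {self.dichotomize!r}")
        if self.dichotomize == "fixed" and self.fixed_cutoff is None:
            raise ConfigurationError("dichotomize='fixed' needs fixed_cutoff")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages, writing TSV/JSON artifacts into ``outdir``.

    Stages without configured inputs are skipped.  Any stage failure is
    re-raised annotated with the stage name.  Returns a report dict
    (mirrored to ``run_log.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(config), "stages": {}}
    stage = "configure"
    try:
        if config.expression_path:
            stage = "screen"
            em = read_expression(
                config.expression_path, config.annotation_path, config.conditions_path
            )
            rm = collapse_probes(rank_transform(em))
            table = score_genes(rm, config.case_label, config.control_label)
            hits = screen_genes(table, config.delta_min, config.ars_min)
            table.rename_axis("gene").to_csv(outdir / "gene_scores.tsv", sep="\t")
            hits.rename_axis("gene").to_csv(outdir / "screen_hits.tsv", sep="\t")
            if len(hits):
                top = hits.index[0]
                rbe_curve(rm, top, bandwidth=config.rbe_bandwidth).to_csv(
                    outdir / "rbe_top_gene.tsv", sep="\t"
                )
                report["stages"]["screen"] = {"n_scored": int(len(table)), "n_hits": int(len(hits)), "top_gene": str(top)}
            else:
                report["stages"]["screen"] = {"n_scored": int(len(table)), "n_hits": 0}

        roc = None
        if config.clinical_path:
            stage = "clinical"
            cohort = read_clinical(config.clinical_path)
            levels = cohort[config.level_column]

            if config.control_levels_path:
                stage = "roc"
                controls = pd.read_csv(config.control_levels_path)["level"]
                roc = roc_auc(levels, controls)
                roc.points.to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
                roc_summary = {
                    "auc": roc.auc,
                    "auc_ci": list(roc.auc_ci),
                    "youden_cutoff": roc.cutoff,
                    "youden_j": roc.j,
                }
                _write_json(roc_summary, outdir / "roc_summary.json")
                report["stages"]["roc"] = roc_summary

            stage = "dichotomize"
            if config.dichotomize == "median":
                group = dichotomize_median(levels)
            else:
                if config.dichotomize == "youden":
                    if roc is None:
                        raise ConfigurationError(
                            "dichotomize='youden' needs control_levels_path"
                        )
                    cutoff = roc.cutoff
                else:
                    cutoff = float(config.fixed_cutoff)
                group = pd.Series(
                    pd.array(["high" if v > cutoff else "low" for v in levels]),
                    index=levels.index,
                    name="group",
                )
            cohort = cohort.assign(group=group)
            report["stages"]["dichotomize"] = {
                "mode": config.dichotomize,
                "n_high": int((group == "high").sum()),
                "n_low": int((group == "low").sum()),
            }

            stage = "survival"
            surv_report: dict = {}
            curves = []
            for g, sub in cohort.groupby("group", sort=True):
                km = km_fit(sub, label=str(g))
                cif = cif_fit(sub)
                rfs = point_estimate_at(km, config.landmark_months)
                cir = point_estimate_at(
                    cif, config.landmark_months, seed=config.seed
                )
                surv_report[str(g)] = {
                    "n": int(len(sub)),
                    "rfs_at_landmark": [rfs.value, rfs.lower, rfs.upper],
                    "cir_at_landmark": [cir.value, cir.lower, cir.upper],
                }
                curves.append(
                    pd.DataFrame(
                        {
                            "group": str(g),
                            "time": cif.times,
                            "cif_relapse": cif.cif_relapse,
                            "cif_death": cif.cif_death,
                            "event_free": cif.event_free,
                        }
                    )
                )
            chi2, p_lr = logrank(cohort, "group")
            g_stat, p_gray = gray_test(cohort, "group", seed=config.seed)
            surv_report["logrank"] = {"chi_square": chi2, "p": p_lr}
            surv_report["gray"] = {"statistic": g_stat, "p": p_gray}
            pd.concat(curves).to_csv(outdir / "cif_curves.tsv", sep="\t", index=False)
            _write_json(surv_report, outdir / "survival_summary.json")
            report["stages"]["survival"] = surv_report

            if config.covariates:
                stage = "cox"
                covs = list(config.covariates)
                if "group" not in covs:
                    cohort = cohort.assign(group_high=(cohort["group"] == "high").astype(int))
                    covs = ["group_high"] + covs
                elim = backward_eliminate(
                    cohort, covs, keep_alpha=config.keep_alpha, ties=config.tie_method
                )
                cox_report = {
                    "kept": elim.kept,
                    "trace": elim.trace,
                    "model": (
                        elim.final.summary.round(6).to_dict(orient="index")
                        if elim.final is not None
                        else {}
                    ),
                }
                _write_json(cox_report, outdir / "cox_model.json")
                report["stages"]["cox"] = cox_report
    except RBEScreenError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    _write_json(report, outdir / "run_log.json")
    return report
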