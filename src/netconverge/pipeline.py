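"""End-to-end orchestration of the four analysis stages.

Stage order: RWR prioritization for each disease -> shared-neighborhood
intersection and union-seeded ranking -> per-study differential expression,
BH adjustment and signature intersection -> network/signature overlap ->
qPCR ddCt quantification, covariate screen/adjustment and ROC evaluation.

Every intermediate table is written as plain TSV, the consolidated report
as JSON, and a run log records the configuration, package version and
seeds, so any stage can be re-run independently and a rerun with identical
configuration is bitwise identical (the log carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fln import FunctionalLinkageNetwork, read_gene_list
from .rwr import RwrParameters, prioritize
from .convergence import rank_shared, shared_neighborhood
from .expression import (ExpressionStudy, differential_expression,
                         intersect_signatures, network_overlap)
from .biomarker import (adjust_covariates, covariate_screen, delta_delta_ct,
                        group_difference, load_qpcr_table, roc_analysis)

logger = logging.getLogger(__name__)


@dataclass
class ExpressionStudyConfig:
    label: str
    expression: Path
    annotation: Path
    control_group: str = "HC"


@dataclass
class QpcrConfig:
    label: str
    path: Path
    calibrator_group: str = "HC"
    case_group: str = "PD"
    covariates: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    network: Path
    seeds_a: Path
    seeds_b: Path
    out_dir: Path
    expression_studies: list[ExpressionStudyConfig] = field(default_factory=list)
    qpcr_cohorts: list[QpcrConfig] = field(default_factory=list)
    alpha: float = 0.5
    fdr: float = 0.05
    tolerance: float = 1e-10
    max_iterations: int = 10000
    rank_mode: str = "union"
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("network", "seeds_a", "seeds_b", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        self.expression_studies = [
            s if isinstance(s, ExpressionStudyConfig)
            else ExpressionStudyConfig(**{**s, "expression": Path(s["expression"]),
                                          "annotation": Path(s["annotation"])})
            for s in self.expression_studies]
        self.qpcr_cohorts = [
            q if isinstance(q, QpcrConfig)
            else QpcrConfig(**{**q, "path": Path(q["path"])})
            for q in self.qpcr_cohorts]

    def validate(self) -> None:
        required = [self.network, self.seeds_a, self.seeds_b]
        required += [s.expression for s in self.expression_studies]
        required += [s.annotation for s in self.expression_studies]
        for p in required:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha {self.alpha} outside (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr {self.fdr} outside (0, 1)")

    @property
    def rwr_params(self) -> RwrParameters:
        return RwrParameters(alpha=self.alpha, tolerance=self.tolerance,
                             max_iterations=self.max_iterations)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, list):
                return [convert(v) for v in obj]
            return obj
        return {f.name: convert(getattr(self, f.name))
                for f in dataclasses.fields(self)}


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs remain in the output directory."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the consolidated report dict.

    A missing/unconfigured qPCR table skips the biomarker stage with a
    notice rather than failing; any stage error aborts the run naming the
    stage, leaving earlier outputs on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {"alpha": config.alpha, "fdr": config.fdr,
                                   "rank_mode": config.rank_mode,
                                   "seed": config.seed}}
    stage = "load_inputs"
    try:
        network = FunctionalLinkageNetwork.from_edge_table(config.network)
        seeds_a = read_gene_list(config.seeds_a)
        seeds_b = read_gene_list(config.seeds_b)
        report["network"] = {"n_genes": network.n_nodes, "n_edges": network.n_edges,
                             "n_seeds_a": len(seeds_a), "n_seeds_b": len(seeds_b)}

        stage = "prioritize"
        params = config.rwr_params
        pri_a = prioritize(network, seeds_a, params)
        pri_b = prioritize(network, seeds_b, params)
        _write_tsv(pri_a.candidate_table, out / "ranked_a.tsv")
        _write_tsv(pri_b.candidate_table, out / "ranked_b.tsv")
        _write_tsv(pri_a.full_table, out / "ranked_a_full.tsv")
        _write_tsv(pri_b.full_table, out / "ranked_b_full.tsv")

        stage = "converge"
        shared = shared_neighborhood(pri_a.candidate_table, pri_b.candidate_table)
        ranked_shared = rank_shared(network, seeds_a, seeds_b, shared,
                                    params, mode=config.rank_mode)
        _write_tsv(ranked_shared, out / "shared_ranked.tsv")
        _write_json(shared.summary(), out / "venn.json")
        report["convergence"] = {**shared.summary(), "rank_mode": config.rank_mode}

        signature = None
        if config.expression_studies:
            stage = "expression_signature"
            tables = {}
            for sc in config.expression_studies:
                study = ExpressionStudy.from_files(sc.expression, sc.annotation,
                                                   label=sc.label)
                for case in [g for g in study.group_names if g != sc.control_group]:
                    de = differential_expression(study, case, sc.control_group,
                                                 fdr=config.fdr)
                    key = f"{sc.label}:{case}_vs_{sc.control_group}"
                    tables[key] = de
                    _write_tsv(de, out / f"de_{sc.label}_{case}_vs_{sc.control_group}.tsv")
            signature = intersect_signatures(tables)
            _write_json(signature.summary(), out / "signature.json")
            report["signature"] = signature.summary()

            stage = "network_overlap"
            overlap = network_overlap(signature.intersection, shared.shared)
            candidates = sorted(overlap & signature.concordant_up)
            report["network_overlap"] = {
                "signature_in_network": sorted(overlap),
                "concordant_up_in_network": candidates,
            }
        else:
            report["signature"] = "skipped: no expression studies configured"

        if config.qpcr_cohorts:
            stage = "biomarker"
            report["biomarker"] = {}
            for qc in config.qpcr_cohorts:
                if not Path(qc.path).exists():
                    report["biomarker"][qc.label] = f"skipped: {qc.path} not found"
                    logger.warning("biomarker stage: %s not found, skipping "
                                   "cohort %s", qc.path, qc.label)
                    continue
                data = load_qpcr_table(qc.path)
                ddct = delta_delta_ct(data, calibrator_group=qc.calibrator_group)
                _write_tsv(ddct.per_sample, out / f"ddct_{qc.label}.tsv")
                _write_tsv(ddct.group_summary, out / f"ddct_summary_{qc.label}.tsv")
                t, p = group_difference(data, qc.case_group, qc.calibrator_group)

                expression_score = -ddct.per_sample["delta_ct"]
                roc = roc_analysis(expression_score, ddct.per_sample["group"],
                                   case_label=qc.case_group)
                _write_tsv(roc.points, out / f"roc_{qc.label}.tsv")

                cov_cols = qc.covariates or [c for c in data.columns
                                             if c not in ("sample", "group",
                                                          "target_ct", "reference_ct")]
                screen = covariate_screen(expression_score, data[cov_cols]) \
                    if cov_cols else pd.DataFrame()
                if len(screen):
                    _write_tsv(screen, out / f"covariates_{qc.label}.tsv")
                adjusted = None
                adj_cols = [c for c in cov_cols
                            if data[c].notna().all() and
                            (pd.api.types.is_numeric_dtype(data[c])
                             or data[c].nunique() == 2)]
                if adj_cols:
                    eff = adjust_covariates(data["target_ct"] - data["reference_ct"],
                                            data["group"], data[adj_cols],
                                            case_group=qc.case_group)
                    adjusted = {"coefficient": eff.coefficient,
                                "std_error": eff.std_error, "p_value": eff.p_value,
                                "covariates": eff.covariates}

                case_row = ddct.group_summary.set_index("group").loc[qc.case_group]
                report["biomarker"][qc.label] = {
                    "n": {qc.case_group: int(roc.n_case),
                          qc.calibrator_group: int(roc.n_control)},
                    "case_mean_fold_change": float(case_row["mean_fold_change"]),
                    "case_sem_fold_change": float(case_row["sem_fold_change"]),
                    "case_fold_change_group": float(case_row["fold_change_group"]),
                    "t_statistic": t, "p_value": p,
                    "auc": roc.auc, "auc_ci": [roc.ci_low, roc.ci_high],
                    "auc_p_value": roc.p_value,
                    "covariate_screen": screen.drop(columns=["note"])
                        .astype(object).where(screen.drop(columns=["note"]).notna(), None)
                        .to_dict("records") if len(screen) else [],
                    "adjusted_group_effect": adjusted,
                }
        else:
            report["biomarker"] = "skipped: no qPCR table configured"
            logger.info("biomarker stage skipped: no qPCR table configured")

        stage = "report"
        _write_json(report, out / "report.json")
        _write_json({"package": "netconverge", "version": __version__,
                     "config": config.to_dict(), "seed": config.seed},
                    out / "run_log.json")
        return report
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, exc) from exc
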