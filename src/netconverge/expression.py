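"""Cross-cohort blood expression signature.

Per-study differential expression (pooled-variance two-tailed t-tests on
log2-scale matrices), Benjamini–Hochberg adjustment at FDR 0.05 within each
comparison, and direction-annotated intersection of the significant gene
sets across studies.  Genes up-regulated in every study ("concordant up")
are the pattern of interest for blood biomarkers of co-occurring disease.

Expression matrices are assumed already log2-transformed and normalized;
raw microarray preprocessing is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.05


@dataclass
class ExpressionStudy:
    """A genes x samples log2 expression matrix with sample group labels."""

    expression: pd.DataFrame        # index: gene, columns: sample
    groups: pd.Series               # index: sample, value: group label
    label: str = "study"

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            dupes = self.expression.index[self.expression.index.duplicated()]
            raise ValueError(f"{self.label}: duplicate gene identifiers {list(dupes[:5])}")
        missing = set(self.expression.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"{self.label}: samples without group labels: "
                             f"{sorted(missing)[:5]}")
        self.groups = self.groups.loc[list(self.expression.columns)]
        if self.groups.isna().any():
            raise ValueError(f"{self.label}: missing group labels")

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @classmethod
    def from_files(cls, expression_path: str | Path, annotation_path: str | Path,
                   label: str | None = None) -> "ExpressionStudy":
        """Read a matrix TSV (first column gene) and a (sample, group) TSV."""
        expr = pd.read_csv(expression_path, sep="\t", index_col=0,
                           float_precision="round_trip")
        ann = pd.read_csv(annotation_path, sep="\t")
        if not {"sample", "group"} <= set(ann.columns):
            raise ValueError(f"{annotation_path}: needs 'sample' and 'group' columns")
        groups = ann.set_index("sample")["group"]
        return cls(expression=expr, groups=groups,
                   label=label or Path(expression_path).stem)

    def to_files(self, expression_path: str | Path, annotation_path: str | Path) -> None:
        self.expression.to_csv(expression_path, sep="\t", index_label="gene")
        ann = pd.DataFrame({"sample": self.groups.index, "group": self.groups.values})
        ann.to_csv(annotation_path, sep="\t", index=False)


def bh_adjust(p_values: np.ndarray, fdr: float = DEFAULT_FDR
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns (q_values, reject) where q_(i) = min_{j >= i} m * p_(j) / j
    capped at 1, and reject marks q <= fdr.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, q <= fdr


def differential_expression(
    study: ExpressionStudy,
    case_group: str,
    control_group: str,
    fdr: float = DEFAULT_FDR,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test of ``case_group`` against ``control_group``.

    Pooled-variance Student t by default (``welch=True`` switches to the
    unequal-variance form); two-tailed p from the t distribution with
    n1 + n2 - 2 degrees of freedom; log2 fold change is the difference of
    group means on the log2 scale.  A gene constant and equal across both
    groups gets t = 0, p = 1 (logged).  BH adjustment is applied within the
    comparison.

    Columns: gene, comparison, log2_fold_change, t_statistic, p_value,
    q_value, significant.
    """
    for g in (case_group, control_group):
        if g not in set(study.groups):
            raise ValueError(f"{study.label}: group {g!r} absent")
        if len(study.samples_in(g)) < 2:
            raise ValueError(f"{study.label}: group {g!r} has < 2 samples")

    case = study.expression[study.samples_in(case_group)].to_numpy(float)
    ctrl = study.expression[study.samples_in(control_group)].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=not welch)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)

    degenerate = ~np.isfinite(t)
    if degenerate.any():
        flat = degenerate & np.isclose(log2fc, 0.0)
        with np.errstate(invalid="ignore"):
            t = np.where(flat, 0.0, t)
            p = np.where(flat, 1.0, p)
            # zero pooled variance with distinct means: infinitely strong evidence
            t = np.where(degenerate & ~flat, np.sign(log2fc) * np.inf, t)
            p = np.where(degenerate & ~flat, 0.0, p)
        logger.info("%s %s_vs_%s: %d zero-variance gene(s) handled",
                    study.label, case_group, control_group, int(degenerate.sum()))

    q, reject = bh_adjust(p, fdr=fdr)
    out = pd.DataFrame({
        "gene": study.expression.index,
        "comparison": f"{case_group}_vs_{control_group}",
        "log2_fold_change": log2fc,
        "t_statistic": t,
        "p_value": p,
        "q_value": q,
        "significant": reject,
    }).reset_index(drop=True)
    out.attrs["study"] = study.label
    out.attrs["fdr"] = fdr
    return out


def pairwise_comparisons(study: ExpressionStudy, fdr: float = DEFAULT_FDR,
                         welch: bool = False) -> dict[str, pd.DataFrame]:
    """One independently BH-adjusted table per unordered group pair.

    For each pair the lexicographically later group is treated as the case
    (so comparisons against a control group named e.g. ``HC`` read
    ``T2D_vs_HC``).  Requires at least two groups.
    """
    names = study.group_names
    if len(names) < 2:
        raise ValueError(f"{study.label}: need >= 2 groups, found {names}")
    tables: dict[str, pd.DataFrame] = {}
    for earlier, later in combinations(names, 2):
        table = differential_expression(study, case_group=later,
                                        control_group=earlier, fdr=fdr, welch=welch)
        tables[f"{later}_vs_{earlier}"] = table
    return tables


@dataclass
class SignatureComparison:
    """Cross-study intersection of significant genes with direction flags."""

    per_study_significant: dict[str, set[str]]
    intersection: set[str]
    directions: pd.DataFrame   # index: intersection genes, columns: study labels
    concordant_up: set[str]
    concordant_down: set[str] = field(default_factory=set)

    def summary(self) -> dict:
        return {
            "per_study_sizes": {k: len(v) for k, v in
                                sorted(self.per_study_significant.items())},
            "intersection": sorted(self.intersection),
            "concordant_up": sorted(self.concordant_up),
            "concordant_down": sorted(self.concordant_down),
            "directions": {g: dict(self.directions.loc[g])
                           for g in sorted(self.intersection)},
        }


def intersect_signatures(tables: Mapping[str, pd.DataFrame]) -> SignatureComparison:
    """Intersect per-study significant gene sets and annotate directions.

    ``tables`` maps a study/comparison label to a differential-expression
    table.  The signature is the intersection of the ``significant`` gene
    sets; each intersection gene is flagged up/down per study by the sign of
    its log2 fold change, and ``concordant_up`` collects genes up-regulated
    in every study.
    """
    if len(tables) < 2:
        raise ValueError("need at least two studies to intersect signatures")
    sig_sets: dict[str, set[str]] = {}
    direction_maps: dict[str, pd.Series] = {}
    for label, table in tables.items():
        sig = table[table["significant"]]
        sig_sets[label] = set(sig["gene"])
        direction_maps[label] = pd.Series(
            np.where(sig["log2_fold_change"].to_numpy() >= 0, "up", "down"),
            index=sig["gene"])

    labels = sorted(tables)
    inter = set.intersection(*(sig_sets[l] for l in labels))
    genes = sorted(inter)
    directions = pd.DataFrame(
        {l: [direction_maps[l].get(g) for g in genes] for l in labels},
        index=pd.Index(genes, name="gene"))
    up = {g for g in genes if all(directions.loc[g] == "up")}
    down = {g for g in genes if all(directions.loc[g] == "down")}
    logger.info("intersect_signatures: %d studies, intersection %d, "
                "concordant up %d", len(labels), len(inter), len(up))
    return SignatureComparison(per_study_significant=sig_sets, intersection=inter,
                               directions=directions, concordant_up=up,
                               concordant_down=down)


def network_overlap(signature: Iterable[str],
                    network_genes: Iterable[str] | pd.DataFrame) -> set[str]:
    """Blood-signature genes that also lie in the shared network gene set.

    ``network_genes`` may be a ranked score table (its ``gene`` column is
    used) or any gene collection.  The result is the route from a
    multi-study expression signature to a network-supported biomarker.
    """
    if isinstance(network_genes, pd.DataFrame):
        network_genes = network_genes["gene"]
    return set(signature) & set(network_genes)
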