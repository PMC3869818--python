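"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of the real inputs the analysis is
designed for, at desk scale:

* a scale-heterogeneous weighted gene network with two partially
  overlapping planted disease modules (functional linkage networks cluster
  genes of a shared phenotype, which is the premise network propagation
  exploits);
* GWAS-style training (seed) gene lists sampled from each planted module;
* log2-scale blood expression studies — one three-group
  (HC/IFG/T2D) metabolic study and two two-group (HC/PD) studies — with a
  planted shared dysregulated gene set of declared directions;
* qPCR Ct tables for two case-control cohorts with a planted dCt shift on
  the target gene and a stable reference gene.

All generators are deterministic under ``rng_seed``.  The ``paperlike``
preset bundles the defaults into one reproducible study-set whose planted
"APP analog" gene sits in the module overlap and is up-regulated in every
expression study, so the full pipeline has a unique known answer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .fln import FunctionalLinkageNetwork, write_gene_list
from .rwr import RwrParameters, prioritize
from .convergence import SharedGeneSet, shared_neighborhood

logger = logging.getLogger(__name__)

MAX_SEED = 2**31 - 1


def _subseeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, MAX_SEED, size=n)]


# -- network ----------------------------------------------------------------

@dataclass
class ModuleTruth:
    """Planted module assignment and the generator parameters that made it."""

    module_a: set[str]
    module_b: set[str]
    assignment: dict[str, str]     # gene -> "A" | "B" | "both" | "background"
    params: dict = field(default_factory=dict)

    @property
    def overlap(self) -> set[str]:
        return self.module_a & self.module_b

    @property
    def background(self) -> set[str]:
        return {g for g, a in self.assignment.items() if a == "background"}


def simulate_fln(
    n_genes: int = 500,
    module_a_size: int = 40,
    module_b_size: int = 40,
    overlap_size: int = 20,
    p_intra: float = 0.3,
    p_background: float = 0.01,
    w_intra: tuple[float, float] = (0.5, 1.0),
    w_background: tuple[float, float] = (0.05, 0.2),
    rng_seed: int = 17,
    gene_prefix: str = "G",
) -> tuple[FunctionalLinkageNetwork, ModuleTruth]:
    """Planted-partition weighted network with two overlapping disease modules.

    Within-module gene pairs (module A = the first ``module_a_size`` genes,
    module B starting ``overlap_size`` genes before A's end) connect with
    probability ``p_intra`` and weights from the high-weight uniform range;
    all other pairs with ``p_background`` and low weights.  Every gene is a
    node even if isolated.
    """
    if not (0 <= overlap_size <= min(module_a_size, module_b_size)):
        raise ValueError("overlap_size must be <= both module sizes")
    if module_a_size + module_b_size - overlap_size > n_genes:
        raise ValueError("modules do not fit in n_genes")
    for p in (p_intra, p_background):
        if not 0 <= p <= 1:
            raise ValueError(f"edge probability {p} outside [0, 1]")

    width = max(4, len(str(n_genes - 1)))
    genes = [f"{gene_prefix}{i:0{width}d}" for i in range(n_genes)]
    a_idx = np.zeros(n_genes, bool)
    a_idx[:module_a_size] = True
    b_idx = np.zeros(n_genes, bool)
    b_start = module_a_size - overlap_size
    b_idx[b_start:b_start + module_b_size] = True

    rng = np.random.default_rng(rng_seed)
    iu, ju = np.triu_indices(n_genes, k=1)
    intra = (a_idx[iu] & a_idx[ju]) | (b_idx[iu] & b_idx[ju])
    p_edge = np.where(intra, p_intra, p_background)
    keep = rng.random(len(iu)) < p_edge
    w_hi = rng.uniform(*w_intra, size=len(iu))
    w_lo = rng.uniform(*w_background, size=len(iu))
    weights = np.where(intra, w_hi, w_lo)

    net = FunctionalLinkageNetwork()
    for g in genes:
        net.add_gene(g)
    for i, j, w in zip(iu[keep], ju[keep], weights[keep]):
        net.add_edge(genes[i], genes[j], float(w))

    assignment = {}
    for i, g in enumerate(genes):
        if a_idx[i] and b_idx[i]:
            assignment[g] = "both"
        elif a_idx[i]:
            assignment[g] = "A"
        elif b_idx[i]:
            assignment[g] = "B"
        else:
            assignment[g] = "background"
    truth = ModuleTruth(
        module_a={g for i, g in enumerate(genes) if a_idx[i]},
        module_b={g for i, g in enumerate(genes) if b_idx[i]},
        assignment=assignment,
        params={"n_genes": n_genes, "module_a_size": module_a_size,
                "module_b_size": module_b_size, "overlap_size": overlap_size,
                "p_intra": p_intra, "p_background": p_background,
                "w_intra": list(w_intra), "w_background": list(w_background),
                "rng_seed": rng_seed},
    )
    logger.info("simulate_fln: %d genes, %d edges", net.n_nodes, net.n_edges)
    return net, truth


def simulate_training_sets(
    truth: ModuleTruth,
    k_per_disease: int = 10,
    rng_seed: int = 17,
    exclude: set[str] = frozenset(),
) -> tuple[list[str], list[str]]:
    """Sample k seed genes per disease from each planted module.

    Stands in for GWAS-confirmed training genes.  Overlap genes are
    eligible for both diseases; ``exclude`` reserves genes (e.g. a
    designated candidate biomarker) from seed duty.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    for module in (truth.module_a, truth.module_b):
        pool = sorted(module - set(exclude))
        if k_per_disease > len(pool):
            raise ValueError(f"k_per_disease={k_per_disease} exceeds eligible "
                             f"module size {len(pool)}")
        out.append(sorted(rng.choice(pool, size=k_per_disease, replace=False)))
    return out[0], out[1]


# -- expression -------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted differential-expression truth for one study."""

    label: str
    planted: dict[str, dict[str, float]]   # case group -> {gene: log2 effect}
    sigma: float
    group_sizes: dict[str, int]

    def planted_genes(self) -> set[str]:
        return set().union(*(set(v) for v in self.planted.values())) \
            if self.planted else set()


def simulate_expression_study(
    genes: list[str],
    group_sizes: Mapping[str, int],
    planted: Mapping[str, Mapping[str, float]] | None = None,
    sigma: float = 1.0,
    rng_seed: int = 17,
    label: str = "study",
):
    """Log2-scale expression matrix with planted group shifts.

    Background expression is Normal(0, sigma^2) everywhere; a planted gene
    is shifted by its signed log2 effect in the named case group.  Returns
    ``(ExpressionStudy, ExpressionTruth)``.
    """
    from .expression import ExpressionStudy  # local import avoids a cycle

    planted = {g: dict(v) for g, v in (planted or {}).items()}
    unknown_groups = set(planted) - set(group_sizes)
    if unknown_groups:
        raise ValueError(f"planted groups not in group_sizes: {sorted(unknown_groups)}")
    gene_index = {g: i for i, g in enumerate(genes)}
    for group, effects in planted.items():
        missing = set(effects) - set(gene_index)
        if missing:
            raise ValueError(f"planted genes absent from gene list: {sorted(missing)[:5]}")

    rng = np.random.default_rng(rng_seed)
    samples, cols = [], []
    for group in sorted(group_sizes):
        n = group_sizes[group]
        block = rng.normal(0.0, sigma, size=(len(genes), n))
        for gene, effect in planted.get(group, {}).items():
            block[gene_index[gene], :] += effect
        cols.append(block)
        samples.extend(f"{label}_{group}_{i + 1}" for i in range(n))
    matrix = pd.DataFrame(np.hstack(cols), index=pd.Index(genes, name="gene"),
                          columns=samples)
    groups = pd.Series(
        [g for g in sorted(group_sizes) for _ in range(group_sizes[g])],
        index=samples)
    study = ExpressionStudy(expression=matrix, groups=groups, label=label)
    truth = ExpressionTruth(label=label, planted=planted, sigma=sigma,
                            group_sizes=dict(group_sizes))
    return study, truth


# -- qPCR -------------------------------------------------------------------

def simulate_qpcr_cohort(
    n_case: int = 50,
    n_control: int = 46,
    delta_ct_shift: float = -2.32,
    sd_ct: float = 1.0,
    reference_sd: float = 0.25,
    mu_delta_ct: float = 5.0,
    reference_mean_ct: float = 20.0,
    case_label: str = "PD",
    control_label: str = "HC",
    with_covariates: bool = True,
    confounder: tuple[str, float, float] | None = None,
    rng_seed: int = 17,
    cohort_label: str = "cohort",
) -> pd.DataFrame:
    """Ct table for a case-control qPCR cohort with a planted dCt shift.

    Control dCt ~ Normal(mu_delta_ct, sd_ct^2); case dCt is shifted by
    ``delta_ct_shift`` (negative shift = target up-regulated in cases, e.g.
    -log2(5) for a five-fold increase).  Reference Ct ~
    Normal(reference_mean_ct, reference_sd^2) independent of group; target
    Ct = reference Ct + dCt.  Covariates (age, sex, BMI; disease-severity
    stage for cases) are drawn independently of group unless ``confounder =
    (name, group_gap, dct_effect_per_unit)`` plants one.
    """
    if min(n_case, n_control) < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(rng_seed)
    n = n_case + n_control
    is_case = np.r_[np.ones(n_case, bool), np.zeros(n_control, bool)]
    dct = rng.normal(mu_delta_ct, sd_ct, size=n) + delta_ct_shift * is_case

    df = pd.DataFrame({
        "sample": [f"{cohort_label}_{'case' if c else 'ctrl'}_{i + 1}"
                   for i, c in enumerate(is_case)],
        "group": np.where(is_case, case_label, control_label),
    })
    if with_covariates:
        df["age"] = np.round(np.clip(rng.normal(64, 9, n), 40, 90), 1)
        df["sex"] = rng.choice(["F", "M"], size=n)
        df["bmi"] = np.round(np.clip(rng.normal(28, 4, n), 17, 45), 1)
        hy = np.round(np.clip(rng.normal(2.0, 0.5, n), 1, 4) * 2) / 2
        df["hoehn_yahr"] = np.where(is_case, hy, np.nan)
    if confounder is not None:
        name, group_gap, dct_effect = confounder
        z = rng.normal(0.0, 1.0, n) + group_gap * is_case
        df[name] = np.round(z, 3)
        dct = dct + dct_effect * z

    ref = rng.normal(reference_mean_ct, reference_sd, size=n)
    df["reference_ct"] = np.round(ref, 4)
    df["target_ct"] = np.round(ref + dct, 4)
    return df[["sample", "group", "target_ct", "reference_ct"]
              + [c for c in df.columns if c not in
                 ("sample", "group", "target_ct", "reference_ct")]]


# -- evaluation against planted truth ---------------------------------------

def evaluate_shared_recovery(
    network: FunctionalLinkageNetwork,
    truth: ModuleTruth,
    seeds_a: list[str],
    seeds_b: list[str],
    params: RwrParameters | None = None,
):
    """Score how well the convergence stage recovers the planted overlap.

    Runs both prioritizations and the neighborhood intersection, then
    measures (a) the fraction of non-seed overlap genes recovered inside
    the shared neighborhood and (b) the AUC with which the union-seeded RWR
    scores separate non-seed overlap genes from background genes.
    """
    params = params or RwrParameters()
    pri_a = prioritize(network, seeds_a, params)
    pri_b = prioritize(network, seeds_b, params)
    shared = shared_neighborhood(pri_a.candidate_table, pri_b.candidate_table)

    seeds_union = set(seeds_a) | set(seeds_b)
    target = truth.overlap - seeds_union
    background = truth.background - seeds_union
    membership = (len(target & shared.shared) / len(target)) if target else float("nan")

    union_pri = prioritize(network, sorted(seeds_union), params)
    scores = union_pri.rwr.scores
    eval_genes = sorted(target) + sorted(background)
    y = np.r_[np.ones(len(target), bool), np.zeros(len(background), bool)]
    auc = float(roc_auc_score(y, scores.loc[eval_genes].to_numpy()))
    return {
        "recovery_auc": auc,
        "membership_fraction": membership,
        "n_target": len(target),
        "n_background": len(background),
        "venn": shared.summary(),
        "shared": shared,
        "prioritization_a": pri_a,
        "prioritization_b": pri_b,
    }


# -- paperlike preset --------------------------------------------------------

@dataclass
class SyntheticBundle:
    """One reproducible study-set covering every pipeline stage."""

    seed: int
    network: FunctionalLinkageNetwork
    module_truth: ModuleTruth
    seeds_a: list[str]
    seeds_b: list[str]
    analog_gene: str
    studies: dict[str, "object"]                # label -> ExpressionStudy
    expression_truth: dict[str, ExpressionTruth]
    shared_signature_truth: dict[str, dict[str, str]]  # gene -> {set label: up/down}
    qpcr: dict[str, pd.DataFrame]
    qpcr_truth: dict[str, dict]


def make_paperlike_bundle(seed: int = 17) -> SyntheticBundle:
    """Default synthetic study-set: network + seeds + 3 expression studies
    + 2 qPCR cohorts, with one planted concordant-up biomarker gene
    ("APP analog") sitting inside the network module overlap.
    """
    s_net, s_seeds, s_glu, s_pd1, s_pd2, s_q1, s_q2 = _subseeds(seed, 7)

    network, module_truth = simulate_fln(rng_seed=s_net)
    genes = network.genes
    overlap_sorted = sorted(module_truth.overlap)
    analog = overlap_sorted[len(overlap_sorted) // 2]
    seeds_a, seeds_b = simulate_training_sets(module_truth, k_per_disease=10,
                                              rng_seed=s_seeds, exclude={analog})

    # Shared dysregulated genes across all studies: the analog (up
    # everywhere) plus four background genes with mixed/down directions, so
    # the concordant-up set is exactly {analog}.
    bg = sorted(module_truth.background)
    shared_genes = [analog, bg[330], bg[331], bg[332], bg[333]]
    eff = 2.0
    shared_dirs = {
        analog:  {"IFG": +eff, "T2D": +eff, "PD1": +eff, "PD2": +eff},
        bg[330]: {"IFG": -eff, "T2D": -eff, "PD1": -eff, "PD2": -eff},
        bg[331]: {"IFG": +eff, "T2D": +eff, "PD1": -eff, "PD2": -eff},
        bg[332]: {"IFG": -eff, "T2D": +eff, "PD1": +eff, "PD2": +eff},
        bg[333]: {"IFG": +eff, "T2D": -eff, "PD1": +eff, "PD2": -eff},
    }
    extras = {"glucose": bg[340:365], "pd_blood_1": bg[365:390],
              "pd_blood_2": bg[390:415]}

    def extra_effects(gene_list):
        return {g: eff if i % 2 == 0 else -eff for i, g in enumerate(gene_list)}

    glucose_planted = {
        "IFG": {g: d["IFG"] for g, d in shared_dirs.items()} | extra_effects(extras["glucose"]),
        "T2D": {g: d["T2D"] for g, d in shared_dirs.items()} | extra_effects(extras["glucose"]),
    }
    pd1_planted = {"PD": {g: d["PD1"] for g, d in shared_dirs.items()}
                   | extra_effects(extras["pd_blood_1"])}
    pd2_planted = {"PD": {g: d["PD2"] for g, d in shared_dirs.items()}
                   | extra_effects(extras["pd_blood_2"])}

    studies, expr_truth = {}, {}
    studies["glucose"], expr_truth["glucose"] = simulate_expression_study(
        genes, {"HC": 10, "IFG": 10, "T2D": 10}, glucose_planted,
        sigma=1.0, rng_seed=s_glu, label="glucose")
    studies["pd_blood_1"], expr_truth["pd_blood_1"] = simulate_expression_study(
        genes, {"HC": 10, "PD": 10}, pd1_planted, sigma=1.0, rng_seed=s_pd1,
        label="pd_blood_1")
    studies["pd_blood_2"], expr_truth["pd_blood_2"] = simulate_expression_study(
        genes, {"HC": 10, "PD": 10}, pd2_planted, sigma=1.0, rng_seed=s_pd2,
        label="pd_blood_2")

    qpcr = {
        "discovery": simulate_qpcr_cohort(n_case=50, n_control=46,
                                          rng_seed=s_q1, cohort_label="discovery"),
        "replication": simulate_qpcr_cohort(n_case=51, n_control=45,
                                            rng_seed=s_q2, cohort_label="replication"),
    }
    qpcr_truth = {name: {"delta_ct_shift": -2.32, "sd_ct": 1.0,
                         "fold_change": 2.0 ** 2.32}
                  for name in qpcr}

    signature_truth = {g: {k: ("up" if v > 0 else "down") for k, v in d.items()}
                       for g, d in shared_dirs.items()}
    return SyntheticBundle(seed=seed, network=network, module_truth=module_truth,
                           seeds_a=seeds_a, seeds_b=seeds_b, analog_gene=analog,
                           studies=studies, expression_truth=expr_truth,
                           shared_signature_truth=signature_truth,
                           qpcr=qpcr, qpcr_truth=qpcr_truth)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle to plain-text files plus a ``truth.json``; returns the
    path map used to build a pipeline configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["network"] = out / "fln.tsv"
    bundle.network.to_edge_table(paths["network"])
    paths["seeds_a"] = out / "seeds_a.txt"
    paths["seeds_b"] = out / "seeds_b.txt"
    write_gene_list(bundle.seeds_a, paths["seeds_a"])
    write_gene_list(bundle.seeds_b, paths["seeds_b"])

    for label, study in bundle.studies.items():
        e = out / f"expr_{label}.tsv"
        a = out / f"groups_{label}.tsv"
        study.to_files(e, a)
        paths[f"expr_{label}"] = e
        paths[f"groups_{label}"] = a
    for name, table in bundle.qpcr.items():
        p = out / f"qpcr_{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"qpcr_{name}"] = p

    truth = {
        "seed": bundle.seed,
        "analog_gene": bundle.analog_gene,
        "module_a": sorted(bundle.module_truth.module_a),
        "module_b": sorted(bundle.module_truth.module_b),
        "module_overlap": sorted(bundle.module_truth.overlap),
        "seeds_a": bundle.seeds_a,
        "seeds_b": bundle.seeds_b,
        "shared_signature": bundle.shared_signature_truth,
        "expression_planted": {
            label: {grp: dict(sorted(effects.items()))
                    for grp, effects in t.planted.items()}
            for label, t in bundle.expression_truth.items()},
        "qpcr": bundle.qpcr_truth,
        "network_params": bundle.module_truth.params,
    }
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
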