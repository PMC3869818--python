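"""Cross-disease convergence: intersect two diseases' candidate neighborhoods.

Given RWR prioritizations for two diseases over the same functional linkage
network, the shared neighborhood is the exact intersection of the two
candidate sets (training genes excluded from both).  The shared genes are
then ranked by a walk seeded with the union of both training sets, the
presentation used when one combined list is reported for both diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .fln import FunctionalLinkageNetwork, normalize_transition
from .rwr import (PrioritizationResult, RwrParameters, prioritize, restart_vector,
                  run_rwr, score_table)

logger = logging.getLogger(__name__)


@dataclass
class SharedGeneSet:
    """Venn decomposition of two candidate neighborhoods."""

    disease_a_candidates: set[str]
    disease_b_candidates: set[str]
    shared: set[str]

    @property
    def venn_counts(self) -> tuple[int, int, int]:
        """(a-only, shared, b-only)."""
        return (len(self.disease_a_candidates - self.shared),
                len(self.shared),
                len(self.disease_b_candidates - self.shared))

    def summary(self) -> dict:
        a_only, shared, b_only = self.venn_counts
        return {"a_only": a_only, "shared": shared, "b_only": b_only,
                "a_total": len(self.disease_a_candidates),
                "b_total": len(self.disease_b_candidates)}


def _as_gene_set(table: pd.DataFrame | Iterable[str]) -> set[str]:
    if isinstance(table, pd.DataFrame):
        if "is_candidate" in table.columns:
            table = table[table["is_candidate"]]
        return set(table["gene"])
    return set(table)


def shared_neighborhood(
    table_a: pd.DataFrame | Iterable[str], table_b: pd.DataFrame | Iterable[str]
) -> SharedGeneSet:
    """Exact intersection of two candidate gene sets.

    Accepts candidate-restricted score tables (a ``gene`` column) or plain
    gene collections.  Commutative up to the a/b labels.
    """
    a = _as_gene_set(table_a)
    b = _as_gene_set(table_b)
    shared = a & b
    logger.info("shared_neighborhood: |A|=%d |B|=%d shared=%d", len(a), len(b),
                len(shared))
    return SharedGeneSet(disease_a_candidates=a, disease_b_candidates=b,
                         shared=shared)


def rank_shared(
    network: FunctionalLinkageNetwork,
    seeds_a: list[str],
    seeds_b: list[str],
    shared: SharedGeneSet,
    params: RwrParameters | None = None,
    mode: str = "union",
) -> pd.DataFrame:
    """Rank the shared genes by RWR proximity to both diseases' seeds.

    mode "union" (default): one walk seeded with the union of both training
    sets.  mode "mean": the average of the two per-disease score vectors,
    which is symmetric in the two inputs by construction.  The mode is
    recorded in ``DataFrame.attrs['mode']``.
    """
    params = params or RwrParameters()
    if mode not in ("union", "mean"):
        raise ValueError(f"unknown mode {mode!r}; expected 'union' or 'mean'")
    if not shared.shared:
        logger.warning("rank_shared: shared gene set is empty")
        out = pd.DataFrame(columns=["rank", "gene", "score", "is_seed"])
        out.attrs["mode"] = mode
        return out

    transition = normalize_transition(network)
    union_seeds = sorted(set(seeds_a) | set(seeds_b))
    if mode == "union":
        restart = restart_vector(transition, union_seeds)
        result = run_rwr(transition, restart, params)
        scores = result.scores
    else:
        per_disease = []
        for seeds in (seeds_a, seeds_b):
            restart = restart_vector(transition, seeds)
            per_disease.append(run_rwr(transition, restart, params).scores)
        scores = (per_disease[0] + per_disease[1]) / 2.0

    df = pd.DataFrame({"gene": scores.index, "score": scores.values})
    df["is_seed"] = df["gene"].isin(set(union_seeds))
    df = df[df["gene"].isin(shared.shared)]
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.attrs["mode"] = mode
    return df


def shared_enrichment_pvalue(
    shared: SharedGeneSet, target_genes: set[str], universe: set[str]
) -> float:
    """Hypergeometric upper-tail p for over-representation of ``target_genes``
    (e.g. a planted both-module set) inside the shared neighborhood, drawn
    from ``universe``."""
    M = len(universe)
    n_draws = len(shared.shared & universe)
    K = len(target_genes & universe)
    k = len(shared.shared & target_genes & universe)
    return float(hypergeom.sf(k - 1, M, K, n_draws))
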