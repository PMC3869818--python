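"""Random walk with restart (RWR) gene prioritization.

The walker starts on a seed (training) set of confirmed disease genes and at
each step either moves to a weight-proportional random neighbor with
probability ``1 - alpha`` or restarts at the seed distribution with
probability ``alpha``.  The stationary visiting probabilities

    p = (1 - alpha) * W @ p + alpha * p0

score every gene's proximity to the seed set; candidate genes (non-seed
first neighbors of the seeds) are then ranked by that score.

Two independent routes to the fixed point are provided: power iteration
(:func:`run_rwr`) and a dense linear solve (:func:`rwr_closed_form`), the
latter serving as an exact oracle on small networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fln import FunctionalLinkageNetwork, TransitionModel, normalize_transition

logger = logging.getLogger(__name__)

_CLOSED_FORM_MAX_N = 5000


@dataclass(frozen=True)
class RwrParameters:
    """Tunables of the walk.

    alpha
        Restart probability in (0, 1]; 0.5 by default (each step is a coin
        flip between diffusing and returning to the seeds).
    tolerance
        L1 convergence threshold on successive iterates.
    max_iterations
        Hard cap on power-iteration steps.
    """

    alpha: float = 0.5
    tolerance: float = 1e-10
    max_iterations: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RestartVector:
    """Uniform restart distribution over the seeds found in the network."""

    nodes: list[str]
    p0: np.ndarray
    seeds_in_network: list[str]
    seeds_missing: list[str]


class RwrConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class RwrResult:
    scores: pd.Series  # index: gene, value: stationary visiting probability
    iterations: int
    converged: bool
    residual: float
    params: RwrParameters


def restart_vector(
    network: FunctionalLinkageNetwork | TransitionModel, seeds: list[str]
) -> RestartVector:
    """Uniform mass 1/k on each of the k seeds present in the network.

    Seeds absent from the network are reported (and logged); if none of the
    seeds are present the walk is undefined and a ``ValueError`` is raised.
    """
    nodes = network.genes if isinstance(network, FunctionalLinkageNetwork) else network.nodes
    node_set = set(nodes)
    present = [s for s in seeds if s in node_set]
    missing = [s for s in seeds if s not in node_set]
    if missing:
        logger.warning("restart_vector: %d seed(s) not in network: %s",
                       len(missing), missing[:10])
    if not present:
        raise ValueError("no seed gene is present in the network")
    p0 = np.zeros(len(nodes))
    idx = {g: i for i, g in enumerate(nodes)}
    for s in set(present):
        p0[idx[s]] = 1.0
    p0 /= p0.sum()
    return RestartVector(nodes=list(nodes), p0=p0,
                         seeds_in_network=sorted(set(present)),
                         seeds_missing=missing)


def run_rwr(
    transition: TransitionModel,
    restart: RestartVector,
    params: RwrParameters | None = None,
) -> RwrResult:
    """Power iteration to the RWR fixed point, started at the restart vector.

    Dangling (isolated) genes have all-zero transition columns; their step
    mass is redirected to the restart distribution so total probability is
    conserved at every iterate.
    """
    params = params or RwrParameters()
    if restart.nodes != transition.nodes:
        raise ValueError("restart vector and transition model use different node orders")
    W, p0, a = transition.matrix, restart.p0, params.alpha
    dang = transition.dangling
    p = p0.copy()
    for it in range(1, params.max_iterations + 1):
        step = W @ p
        if dang.any():
            step = step + p[dang].sum() * p0
        p_new = (1 - a) * step + a * p0
        delta = float(np.abs(p_new - p).sum())
        p = p_new
        if delta < params.tolerance:
            return RwrResult(scores=pd.Series(p, index=transition.nodes),
                             iterations=it, converged=True, residual=delta,
                             params=params)
    raise RwrConvergenceError(
        f"RWR did not converge within {params.max_iterations} iterations "
        f"(last L1 change {delta:.3e})", last_iterate=p)


def rwr_closed_form(
    transition: TransitionModel, restart: RestartVector, alpha: float
) -> np.ndarray:
    """Direct solve of the RWR stationary equation (oracle for ``run_rwr``).

    Solves ``(I - (1 - alpha) * W_eff) p = alpha * p0`` densely, where
    ``W_eff`` equals the step kernel with dangling columns replaced by the
    restart distribution (the same teleport rule the iteration applies).
    For ``alpha > 0`` the system matrix is strictly diagonally dominant in
    the induced norm, hence nonsingular.
    """
    n = transition.n
    if n > _CLOSED_FORM_MAX_N:
        raise ValueError(f"closed form limited to n <= {_CLOSED_FORM_MAX_N}, got {n}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    W = transition.matrix.toarray()
    if transition.dangling.any():
        W = W + np.outer(restart.p0, transition.dangling.astype(float))
    A = np.eye(n) - (1 - alpha) * W
    return np.linalg.solve(A, alpha * restart.p0)


def candidate_set(network: FunctionalLinkageNetwork, seeds: list[str]) -> set[str]:
    """Non-seed genes at topological distance <= 1 from the seed set.

    Seeds themselves are excluded: prioritizing an already-confirmed disease
    gene is uninformative, so the ranked universe is the seeds' first
    neighborhood.
    """
    restart_vector(network, seeds)  # validates that >= 1 seed is present
    return network.neighbors(set(seeds))


def score_table(result: RwrResult, seeds: list[str],
                candidates: set[str] | None = None) -> pd.DataFrame:
    """Ranked gene score table (rank, gene, score, is_seed, is_candidate).

    Ranks are 1..n descending by score; ties broken lexicographically by
    gene identifier so the ranking is deterministic.
    """
    seeds = set(seeds)
    df = pd.DataFrame({"gene": result.scores.index, "score": result.scores.values})
    df["is_seed"] = df["gene"].isin(seeds)
    df["is_candidate"] = df["gene"].isin(candidates) if candidates is not None else False
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


@dataclass
class PrioritizationResult:
    """Full audit table plus the candidate-restricted ranking."""

    full_table: pd.DataFrame       # every network gene, ranked
    candidate_table: pd.DataFrame  # candidates only, re-ranked 1..k
    candidates: set[str]
    restart: RestartVector
    rwr: RwrResult


def prioritize(
    network: FunctionalLinkageNetwork,
    seeds: list[str],
    params: RwrParameters | None = None,
    transition: TransitionModel | None = None,
) -> PrioritizationResult:
    """Score the whole network by RWR from ``seeds`` and rank the candidates.

    The walk runs over the full network (scores sum to 1 across all genes);
    the reported ranking is restricted to the candidate set (non-seed first
    neighbors of the seeds), mirroring a rank/gene/score prioritization
    table.  The full table is retained for auditing.
    """
    params = params or RwrParameters()
    if transition is None:
        transition = normalize_transition(network)
    restart = restart_vector(transition, seeds)
    result = run_rwr(transition, restart, params)
    cands = network.neighbors(set(seeds))
    full = score_table(result, seeds, cands)
    cand = full[full["is_candidate"]].drop(columns=["is_candidate"]).copy()
    cand["rank"] = np.arange(1, len(cand) + 1)
    cand = cand.reset_index(drop=True)
    if not len(cand):
        logger.warning("prioritize: candidate set is empty (seeds cover all "
                       "reachable genes)")
    return PrioritizationResult(full_table=full, candidate_table=cand,
                                candidates=cands, restart=restart, rwr=result)
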