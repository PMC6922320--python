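"""Randomized controls and robustness variants.

Capability shuffles (degree-preserving double-edge swaps), species-label
shuffles, random uptake rates, Dirichlet secretion weights, an enzyme-budget
uptake variant, and cohort bootstrap resampling.  All generators are
seed-deterministic; consumption and production edge sets are randomized
separately and independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .flow import Cohort, FlowParameters
from .network import CrossFeedingNetwork


@dataclass
class NullSpec:
    kind: str  # capability_shuffle | label_shuffle | random_lambda | dirichlet_secretion | enzyme_budget | bootstrap
    seed: int = 0
    replicates: int = 100
    dirichlet_concentration: float = 1.0

    def __post_init__(self) -> None:
        kinds = {
            "capability_shuffle",
            "label_shuffle",
            "random_lambda",
            "dirichlet_secretion",
            "enzyme_budget",
            "bootstrap",
        }
        if self.kind not in kinds:
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("concentration must be positive")


def _double_edge_swap(edges: set, rng: np.random.Generator, n_attempts: int) -> set:
    """Degree-preserving shuffle of one bipartite edge set.

    Each attempt picks two edges (a, i), (b, j) and proposes the rewiring
    (a, j), (b, i); swaps that would duplicate an existing edge (or are
    no-ops) are rejected, with rejections counted as attempts.
    """
    edge_list = list(edges)
    if len(edge_list) < 2:
        return set(edge_list)
    if len({e[0] for e in edge_list}) < 2 or len({e[1] for e in edge_list}) < 2:
        warnings.warn("degenerate edge set (single species or metabolite); returned unchanged")
        return set(edge_list)
    edge_set = set(edge_list)
    n = len(edge_list)
    for _ in range(n_attempts):
        k1, k2 = rng.integers(0, n, size=2)
        if k1 == k2:
            continue
        a, i = edge_list[k1]
        b, j = edge_list[k2]
        if i == j or a == b:
            continue
        new1, new2 = (a, j), (b, i)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((a, i))
        edge_set.discard((b, j))
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[k1], edge_list[k2] = new1, new2
    return edge_set


def shuffle_capabilities(net: CrossFeedingNetwork, seed: int = 0) -> CrossFeedingNetwork:
    """Shuffle consumption and production capabilities independently with
    degree-preserving double-edge swaps (3x the edge count attempted per
    set), keeping every species' and metabolite's degree exactly."""
    root = np.random.default_rng(seed)
    rng_c, rng_p = root.spawn(2)
    ec = _double_edge_swap(net.consumption_edges, rng_c, 3 * len(net.consumption_edges))
    ep = _double_edge_swap(net.production_edges, rng_p, 3 * len(net.production_edges))
    return net.copy_with_edges(ec, ep)


def shuffle_species_labels(net: CrossFeedingNetwork, seed: int = 0) -> CrossFeedingNetwork:
    """Permute species identities: each species' full capability pair
    (consumables, byproducts) travels intact to a new name."""
    if net.n_species < 2:
        return net.copy_with_edges(net.consumption_edges, net.production_edges)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(net.n_species)
    relabel = {net.species[k]: net.species[perm[k]] for k in range(net.n_species)}
    ec = {(relabel[s], m) for s, m in net.consumption_edges}
    ep = {(relabel[s], m) for s, m in net.production_edges}
    return net.copy_with_edges(ec, ep)


def randomize_uptake_rates(
    params: FlowParameters, net: CrossFeedingNetwork, seed: int = 0
) -> FlowParameters:
    """Uptake rates lambda drawn i.i.d. uniform(0, 1) on consumption edges."""
    rng = np.random.default_rng(seed)
    rates = {edge: float(rng.uniform()) for edge in sorted(net.consumption_edges)}
    return FlowParameters(
        f=params.f,
        n_levels=params.n_levels,
        uptake_rates=rates,
        secretion_mode=params.secretion_mode,
        secretion_weights=params.secretion_weights,
    )


def dirichlet_secretion(
    net: CrossFeedingNetwork,
    seed: int = 0,
    concentration: float = 1.0,
    params: FlowParameters | None = None,
) -> FlowParameters:
    """Per-species secretion weights drawn from a symmetric Dirichlet over
    the species' byproducts (concentration -> infinity recovers equal split)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    base = params or FlowParameters()
    rng = np.random.default_rng(seed)
    weights: dict[tuple[str, str], float] = {}
    for sp in net.species:
        byps = sorted(net.byproducts(sp))
        if not byps:
            continue
        w = rng.dirichlet(np.full(len(byps), concentration))
        for m, v in zip(byps, w):
            weights[(sp, m)] = float(v)
    return FlowParameters(
        f=base.f,
        n_levels=base.n_levels,
        uptake_rates=base.uptake_rates,
        secretion_mode="explicit",
        secretion_weights=weights,
    )


def enzyme_budget_rates(
    net: CrossFeedingNetwork, params: FlowParameters | None = None
) -> FlowParameters:
    """Constant enzyme budget: lambda = 1/|consumables| on each consumption
    edge, so every species' total uptake capacity is 1 (generalists are
    penalized per nutrient)."""
    base = params or FlowParameters()
    rates: dict[tuple[str, str], float] = {}
    for sp in net.species:
        cons = net.consumables(sp)
        for m in cons:
            rates[(sp, m)] = 1.0 / len(cons)
    return FlowParameters(
        f=base.f,
        n_levels=base.n_levels,
        uptake_rates=rates,
        secretion_mode=base.secretion_mode,
        secretion_weights=base.secretion_weights,
    )


def bootstrap_cohort(cohort: Cohort, n_datasets: int, seed: int = 0) -> list[Cohort]:
    """Resample the cohort with replacement, each resample the original size
    (for re-running the calibration grid to get best-cell distributions)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    out = []
    n = len(cohort)
    for _ in range(n_datasets):
        idx = rng.integers(0, n, size=n)
        out.append(Cohort([cohort.samples[i] for i in idx], cohort.network))
    return out
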