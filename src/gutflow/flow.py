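"""Level-by-level trophic cascade.

The model treats gut metabolism as a finite cascade: an intake vector of
metabolites enters the gut; at each trophic step every consumable metabolite
is split across the species able to consume it in proportion to abundance
times uptake rate, a fraction ``1 - f`` of what each species consumes
becomes its biomass, and the remaining fraction ``f`` is secreted as
byproducts split across the species' producible metabolites.  After
``N_levels`` steps, whatever was never consumed — plus the final level's
byproducts — constitutes the predicted fecal metabolome.

All quantities are relative (the cascade is linear in the intake), and the
experimentally measured abundances are used inside the uptake matrix at
every level; abundances are not updated dynamically between levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network import CrossFeedingNetwork

EQUAL_SPLIT = "equal_split"
DIRICHLET = "dirichlet"
EXPLICIT = "explicit"


@dataclass
class FlowParameters:
    """Global knobs of the cascade.

    f : byproduct fraction in (0, 1); ``1 - f`` of consumed mass becomes
        biomass.
    n_levels : number of consumption steps (trophic levels), >= 1.
    uptake_rates : optional (species, metabolite) -> lambda >= 0; default 1
        on every consumption edge.
    secretion_mode : "equal_split" (each producible byproduct gets
        1/N_out), or "explicit" with per-edge ``secretion_weights``
        (normalized per species).  Dirichlet-drawn weights are produced by
        :func:`gutflow.nulls.dirichlet_secretion` and passed as explicit.
    """

    f: float = 0.9
    n_levels: int = 4
    uptake_rates: Mapping[tuple[str, str], float] | None = None
    secretion_mode: str = EQUAL_SPLIT
    secretion_weights: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"byproduct fraction f must lie in (0, 1), got {self.f}")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.uptake_rates is not None and any(v < 0 for v in self.uptake_rates.values()):
            raise ValueError("uptake rates must be non-negative")


@dataclass
class CommunitySample:
    """One individual's community: relative species abundances (sum 1 after
    renormalization) and, optionally, a measured metabolome."""

    sample_id: str
    abundances: dict[str, float]
    measured_metabolome: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        total = sum(self.abundances.values())
        if total > 0:
            self.abundances = {k: v / total for k, v in self.abundances.items()}

    def restrict_to(self, species: set[str]) -> "CommunitySample":
        """Drop species outside ``species`` and renormalize."""
        kept = {k: v for k, v in self.abundances.items() if k in species}
        return CommunitySample(self.sample_id, kept, self.measured_metabolome)


@dataclass
class IntakeProfile:
    """Amounts of the candidate intake metabolites entering the gut."""

    amounts: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.amounts.values()):
            raise ValueError("intake amounts must be non-negative")
        if not any(v > 0 for v in self.amounts.values()):
            raise ValueError("intake must have at least one positive entry")

    def normalized(self) -> "IntakeProfile":
        total = sum(self.amounts.values())
        return IntakeProfile({k: v / total for k, v in self.amounts.items()})

    @property
    def total(self) -> float:
        return sum(self.amounts.values())


@dataclass
class Cohort:
    """Samples sharing one capability network."""

    samples: list[CommunitySample]
    network: CrossFeedingNetwork | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


@dataclass
class UptakeMatrix:
    """Column-stochastic species x metabolite uptake split (A_in).

    Entry (alpha, i) = kappa_i * lambda_{alpha,i} * B_alpha on consumption
    edges, zero elsewhere; kappa_i normalizes each consumed column to 1.
    Columns of metabolites without a present positive-abundance consumer are
    all-zero ("effectively unconsumable" in this sample).
    """

    matrix: np.ndarray  # (n_species, n_metabolites)
    kappa: np.ndarray  # (n_metabolites,) normalizers; 0 where unconsumable
    consumable: np.ndarray  # (n_metabolites,) bool
    species: list[str]
    metabolites: list[str]


@dataclass
class SecretionMatrix:
    """Column-stochastic metabolite x species secretion split (A_out).

    Under equal split each nonzero entry of species alpha's column equals
    1/N_out(alpha); species without production edges have all-zero columns
    (their byproduct fraction is routed to the sink)."""

    matrix: np.ndarray  # (n_metabolites, n_species)
    n_out: np.ndarray  # (n_species,)
    species: list[str]
    metabolites: list[str]


def _abundance_vector(net: CrossFeedingNetwork, sample: CommunitySample) -> np.ndarray:
    b = np.zeros(net.n_species)
    for sp, v in sample.abundances.items():
        idx = net.species_index.get(sp)
        if idx is None:
            raise KeyError(f"sample species {sp!r} not present in network")
        b[idx] = v
    return b


def _rate_matrix(net: CrossFeedingNetwork, params: FlowParameters) -> np.ndarray:
    C, _ = net.masks()
    lam = C.astype(float)
    if params.uptake_rates is not None:
        lam = np.zeros_like(lam)
        for (sp, met), v in params.uptake_rates.items():
            si = net.species_index.get(sp)
            mi = net.metabolite_index.get(met)
            if si is not None and mi is not None and C[si, mi]:
                lam[si, mi] = v
    return lam


def build_uptake_matrix(
    net: CrossFeedingNetwork, sample: CommunitySample, params: FlowParameters
) -> UptakeMatrix:
    lam = _rate_matrix(net, params)
    b = _abundance_vector(net, sample)
    weighted = lam * b[:, None]
    col = weighted.sum(axis=0)
    consumable = col > 0
    kappa = np.zeros(net.n_metabolites)
    kappa[consumable] = 1.0 / col[consumable]
    A_in = weighted * kappa[None, :]
    return UptakeMatrix(A_in, kappa, consumable, net.species, net.metabolites)


def build_secretion_matrix(net: CrossFeedingNetwork, params: FlowParameters) -> SecretionMatrix:
    _, P = net.masks()
    n_out = P.sum(axis=1).astype(float)
    if params.secretion_mode == EQUAL_SPLIT:
        W = P.T.astype(float)
    elif params.secretion_mode in (EXPLICIT, DIRICHLET):
        if params.secretion_weights is None:
            raise ValueError(f"{params.secretion_mode} secretion requires secretion_weights")
        if any(v < 0 for v in params.secretion_weights.values()):
            raise ValueError("secretion weights must be non-negative")
        W = np.zeros((net.n_metabolites, net.n_species))
        for (sp, met), v in params.secretion_weights.items():
            si = net.species_index.get(sp)
            mi = net.metabolite_index.get(met)
            if si is not None and mi is not None and P[si, mi]:
                W[mi, si] = v
    else:
        raise ValueError(f"unknown secretion mode {params.secretion_mode!r}")
    col = W.sum(axis=0)
    A_out = np.divide(W, col[None, :], out=np.zeros_like(W), where=col > 0)
    return SecretionMatrix(A_out, n_out, net.species, net.metabolites)


@dataclass
class FlowResult:
    """Full record of one cascade run.

    Levels are indexed by consumption step (1..n_levels).  ``biomass_by_level``
    row ``l-1`` holds the per-species biomass increment of step ``l``;
    ``byproducts_by_level`` row ``l-1`` holds the byproduct vector the step
    emits; ``unconsumed_by_level`` row ``l-1`` the part of the step's input
    no present species could consume.  ``sink_by_level`` accumulates the
    byproduct fraction of mass consumed by species with no recorded
    byproducts (kept out of the metabolome, so mass is conserved).
    """

    species: list[str]
    metabolites: list[str]
    intake: np.ndarray
    biomass_by_level: np.ndarray  # (n_levels, n_species)
    byproducts_by_level: np.ndarray  # (n_levels, n_metabolites)
    consumable_by_level: np.ndarray  # (n_levels, n_metabolites) consumable input part
    unconsumed_by_level: np.ndarray  # (n_levels, n_metabolites)
    sink_by_level: np.ndarray  # (n_levels,)
    params: FlowParameters = field(repr=False, default=None)
    uptake: UptakeMatrix | None = field(repr=False, default=None)
    secretion: SecretionMatrix | None = field(repr=False, default=None)

    @property
    def n_levels(self) -> int:
        return self.biomass_by_level.shape[0]

    @property
    def total_biomass(self) -> np.ndarray:
        return self.biomass_by_level.sum(axis=0)

    @property
    def metabolome(self) -> np.ndarray:
        """Predicted fecal metabolome: unconsumed inputs of every level plus
        the final level's byproducts."""
        return self.byproducts_by_level[-1] + self.unconsumed_by_level.sum(axis=0)

    @property
    def sink_mass(self) -> float:
        return float(self.sink_by_level.sum())

    def mass_balance_error(self) -> float:
        """Relative deviation of biomass + metabolome + sink from intake."""
        total_in = self.intake.sum()
        total_out = self.total_biomass.sum() + self.metabolome.sum() + self.sink_mass
        return abs(total_out - total_in) / max(total_in, 1e-300)

    def biomass_series(self) -> pd.Series:
        return pd.Series(self.total_biomass, index=self.species, name="biomass")

    def metabolome_series(self) -> pd.Series:
        return pd.Series(self.metabolome, index=self.metabolites, name="metabolome")

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-level record (level, entity_id, entity_class, amount)."""
        rows = []
        for l in range(self.n_levels):
            for k, sp in enumerate(self.species):
                if self.biomass_by_level[l, k] > 0:
                    rows.append((l + 1, sp, "species", self.biomass_by_level[l, k]))
            for k, met in enumerate(self.metabolites):
                if self.byproducts_by_level[l, k] > 0:
                    rows.append((l + 1, met, "metabolite", self.byproducts_by_level[l, k]))
        return pd.DataFrame(rows, columns=["level", "entity_id", "entity_class", "amount"])


def _intake_vector(net: CrossFeedingNetwork, intake: IntakeProfile) -> tuple[np.ndarray, dict]:
    c = np.zeros(net.n_metabolites)
    outside = {}
    for met, v in intake.amounts.items():
        idx = net.metabolite_index.get(met)
        if idx is None:
            # metabolite unknown to the network: passes straight through
            outside[met] = v
        else:
            c[idx] += v
    return c, outside


def run_cascade(
    net: CrossFeedingNetwork,
    sample: CommunitySample,
    intake: IntakeProfile,
    params: FlowParameters,
    matrices: tuple[UptakeMatrix, SecretionMatrix] | None = None,
) -> FlowResult:
    """Run the trophic cascade (the canonical level-by-level recursion).

    At each step ``l`` the current metabolite vector ``d`` is split into a
    consumable part (metabolites with at least one present consumer) and an
    unconsumable part ``u_l`` (set aside for the metabolome); species gain
    ``(1 - f) * A_in @ d`` of biomass and emit ``f * A_out @ A_in @ d`` as
    the next vector.  Intake metabolites with no consumer in this sample
    fall into ``u_1``.
    """
    if matrices is None:
        up = build_uptake_matrix(net, sample, params)
        out = build_secretion_matrix(net, params)
    else:
        up, out = matrices
    c0, outside = _intake_vector(net, intake)
    if c0.sum() + sum(outside.values()) <= 0:
        raise ValueError("all-zero intake")

    n_l = params.n_levels
    S, M = net.n_species, net.n_metabolites
    biomass = np.zeros((n_l, S))
    byproducts = np.zeros((n_l, M))
    consumable_part = np.zeros((n_l, M))
    unconsumed = np.zeros((n_l, M))
    sink = np.zeros(n_l)

    no_byproducts = out.n_out == 0
    d = c0
    for l in range(n_l):
        e = np.where(up.consumable, d, 0.0)
        u = d - e
        consumed = up.matrix @ e  # per-species consumed mass
        biomass[l] = (1.0 - params.f) * consumed
        d_next = params.f * (out.matrix @ consumed)
        sink[l] = params.f * consumed[no_byproducts].sum()
        consumable_part[l] = e
        unconsumed[l] = u
        byproducts[l] = d_next
        d = d_next

    # intake metabolites outside the network vocabulary pass through at level 1
    if outside:
        metabolites = list(net.metabolites) + sorted(outside)
        pad = len(outside)
        byproducts = np.pad(byproducts, ((0, 0), (0, pad)))
        consumable_part = np.pad(consumable_part, ((0, 0), (0, pad)))
        unconsumed = np.pad(unconsumed, ((0, 0), (0, pad)))
        c0 = np.concatenate([c0, [outside[m] for m in sorted(outside)]])
        unconsumed[0, M:] = [outside[m] for m in sorted(outside)]
    else:
        metabolites = list(net.metabolites)

    return FlowResult(
        species=list(net.species),
        metabolites=metabolites,
        intake=c0,
        biomass_by_level=biomass,
        byproducts_by_level=byproducts,
        consumable_by_level=consumable_part,
        unconsumed_by_level=unconsumed,
        sink_by_level=sink,
        params=params,
        uptake=up,
        secretion=out,
    )


def cascade_operators(
    net: CrossFeedingNetwork,
    sample: CommunitySample,
    params: FlowParameters,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Linear operators mapping an intake vector to (biomass, metabolome).

    The cascade is linear in the intake at fixed abundances, so
    ``biomass = L_b @ c`` and ``metabolome = L_m @ c``; these operators make
    repeated evaluation (intake fitting, grids) cheap.  Exact, not an
    approximation.
    """
    up = build_uptake_matrix(net, sample, params)
    out = build_secretion_matrix(net, params)
    M = net.n_metabolites
    L_b = np.zeros((net.n_species, M))
    L_m = np.zeros((M, M))
    # propagate the identity through the recursion
    D = np.eye(M)
    f = params.f
    for _ in range(params.n_levels):
        E = np.where(up.consumable[:, None], D, 0.0)
        U = D - E
        consumed = up.matrix @ E
        L_b += (1.0 - f) * consumed
        D = f * (out.matrix @ consumed)
        L_m += U
    L_m += D
    return L_b, L_m, list(net.species), list(net.metabolites)


def predict_profiles(flow: FlowResult) -> tuple[pd.Series, pd.Series]:
    """Normalize biomass and metabolome separately to relative profiles."""
    b = flow.biomass_series()
    m = flow.metabolome_series()
    bt, mt = b.sum(), m.sum()
    if bt > 0:
        b = b / bt
    else:
        import warnings

        warnings.warn("zero total biomass; returning empty abundance profile")
        b = b.iloc[0:0]
    if mt > 0:
        m = m / mt
    else:
        import warnings

        warnings.warn("zero total metabolome; returning empty metabolome profile")
        m = m.iloc[0:0]
    return b, m


def flow_summary(flow: FlowResult) -> pd.DataFrame:
    """Per-level fractions of total intake: consumed, biomass, unconsumable,
    passed on to the next level, and sink."""
    total = flow.intake.sum()
    rows = []
    for l in range(flow.n_levels):
        consumed = flow.consumable_by_level[l].sum()
        rows.append(
            {
                "level": l + 1,
                "consumed_fraction": consumed / total,
                "biomass_fraction": flow.biomass_by_level[l].sum() / total,
                "unconsumable_fraction": flow.unconsumed_by_level[l].sum() / total,
                "passed_on_fraction": flow.byproducts_by_level[l].sum() / total,
                "sink_fraction": flow.sink_by_level[l] / total,
            }
        )
    return pd.DataFrame(rows)


def export_flow(flow: FlowResult, out_dir) -> None:
    """Write per-level TSVs, a layer-wise edge list and a JSON summary."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flow.to_frame().to_csv(out / "levels.tsv", sep="\t", index=False)
    flow_summary(flow).to_csv(out / "flow_summary.tsv", sep="\t", index=False)
    edges = layer_edge_list(flow)
    edges.to_csv(out / "layer_network.tsv", sep="\t", index=False)
    summary = {
        "total_biomass": float(flow.total_biomass.sum()),
        "total_metabolome": float(flow.metabolome.sum()),
        "sink_mass": flow.sink_mass,
        "mass_balance_error": flow.mass_balance_error(),
        "n_levels": flow.n_levels,
        "f": flow.params.f if flow.params else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def layer_edge_list(flow: FlowResult, threshold: float = 0.0) -> pd.DataFrame:
    """Level-resolved bipartite flow edges (level, source, target, flow).

    Consumption edges carry metabolite->species flow at each step; production
    edges carry species->metabolite flow into the next metabolite layer.
    """
    if flow.params is None or flow.uptake is None or flow.secretion is None:
        raise ValueError("flow lacks attached parameters/matrices")
    rows = []
    f = flow.params.f
    A_in = flow.uptake.matrix
    A_out = flow.secretion.matrix
    M = A_in.shape[1]
    for l in range(flow.n_levels):
        e = flow.consumable_by_level[l][:M]
        per_edge_in = A_in * e[None, :]  # species x metabolite consumed mass
        consumed = per_edge_in.sum(axis=1)
        per_edge_out = f * A_out * consumed[None, :]  # metabolite x species
        si, mi = np.nonzero(per_edge_in > threshold)
        for a, i in zip(si, mi):
            rows.append((l + 1, flow.metabolites[i], flow.species[a], per_edge_in[a, i]))
        mi, si = np.nonzero(per_edge_out > threshold)
        for i, a in zip(mi, si):
            rows.append((l + 1, flow.species[a], flow.metabolites[i], per_edge_out[i, a]))
    return pd.DataFrame(rows, columns=["level", "source", "target", "flow"])
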