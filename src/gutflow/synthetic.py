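"""Synthetic capability networks and cohorts with known ground truth.

Real calibration data pair 16S/WGS species abundances with a measured fecal
metabolome; neither is bundled here.  Instead this module generates random
bipartite capability networks, draws ground-truth intake vectors, runs the
forward cascade to produce self-consistent "noiseless" abundances and
metabolomes, and overlays multiplicative log-normal observation noise (in
dex, i.e. units of log10), so that every stage of the pipeline — intake
fitting, grid calibration, null comparisons, diversity — can be exercised
against a known truth.

The abundance circularity (the cascade weights uptake by the measured
abundances, but here the abundances are themselves model output) is resolved
by iterating the abundance map to its fixed point: at the stored abundances,
the cascade at the true intake reproduces those same abundances, which makes
noiseless intake recovery a well-posed inverse problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import Cohort, CommunitySample, FlowParameters, IntakeProfile, run_cascade, cascade_operators, predict_profiles
from .network import CrossFeedingNetwork


@dataclass
class SyntheticTruth:
    """Ground truth underlying a generated cohort."""

    network: CrossFeedingNetwork
    f: float
    n_levels: int
    intake_metabolites: list[str]
    true_intake: dict[str, dict[str, float]]  # sample_id -> metabolite -> amount
    noiseless_abundances: dict[str, dict[str, float]]
    noiseless_metabolome: dict[str, dict[str, float]]
    sigma_abund: float
    sigma_metab: float
    seed: int


def generate_network(
    n_species: int = 80,
    n_metabolites: int = 120,
    mean_in_degree: float = 2.0,
    mean_out_degree: float = 2.0,
    n_intake: int = 19,
    seed: int = 0,
    wiring: str = "random",
    genus_size: int = 4,
    ensure_all_consumable: bool = False,
    intake_specialists: bool = True,
) -> tuple[CrossFeedingNetwork, list[str]]:
    """Random bipartite capability network plus a designated intake list.

    Every species gets at least one consumable and one byproduct (so the
    sink stays empty by default), every intake metabolite at least one
    consumer.  Species are partitioned into genera of ``genus_size`` (the
    genus is the first name token).  ``wiring="chain"`` instead builds a
    linear food chain (species k consumes metabolite k, produces k+1).
    ``ensure_all_consumable`` gives every metabolite a consumer, making the
    network fully consumable (closed-form cascade limit applies).

    With ``intake_specialists`` (default), each intake metabolite is
    consumed by exactly one, distinct, dedicated species.  Because uptake
    columns are normalized, a sole consumer receives its metabolite's whole
    flux regardless of its abundance, so these gateway species persist in
    any community containing them and the map from intake amounts to
    biomass has full column rank — which is what makes intake inference on
    generated cohorts a well-posed inverse problem.  With the flag off,
    intake metabolites join the general consumption pool and recovery of a
    ground-truth intake is not guaranteed to be unique.
    """
    if n_species < 1 or n_metabolites < 1 or n_intake < 1:
        raise ValueError("sizes must be positive")
    if mean_in_degree < 1 or mean_out_degree < 1:
        raise ValueError("mean degrees must be >= 1")
    if n_intake > n_metabolites:
        raise ValueError("more intake metabolites than metabolites")
    if intake_specialists and n_intake > n_species:
        raise ValueError("intake specialists need n_species >= n_intake")

    metabolites = [f"met_{k:03d}" for k in range(n_metabolites)]
    species = [
        f"Genus{k // genus_size:03d} species{k:03d}" for k in range(n_species)
    ]

    if wiring == "chain":
        if n_metabolites < n_species + 1:
            raise ValueError("chain wiring needs n_metabolites >= n_species + 1")
        ec = {(species[k], metabolites[k]) for k in range(n_species)}
        ep = {(species[k], metabolites[k + 1]) for k in range(n_species)}
        return CrossFeedingNetwork(species, metabolites, ec, ep), [metabolites[0]]
    if wiring != "random":
        raise ValueError(f"unknown wiring {wiring!r}")

    rng = np.random.default_rng(seed)
    intake_idx = rng.choice(n_metabolites, size=n_intake, replace=False)
    intake = [metabolites[m] for m in intake_idx]
    if intake_specialists:
        pool = [m for m in range(n_metabolites) if m not in set(intake_idx)]
        gateways = rng.choice(n_species, size=n_intake, replace=False)
    else:
        pool = list(range(n_metabolites))
        gateways = []

    ec, ep = set(), set()
    for k, sp in enumerate(species):
        k_in = min(1 + rng.poisson(mean_in_degree - 1.0), len(pool))
        k_out = min(1 + rng.poisson(mean_out_degree - 1.0), n_metabolites)
        for m in rng.choice(pool, size=k_in, replace=False):
            ec.add((sp, metabolites[m]))
        for m in rng.choice(n_metabolites, size=k_out, replace=False):
            ep.add((sp, metabolites[m]))
    for g, m in zip(gateways, intake_idx):
        ec.add((species[g], metabolites[m]))

    consumed = {m for _, m in ec}
    targets = metabolites if ensure_all_consumable else intake
    for m in targets:
        if m not in consumed:
            if intake_specialists and m in intake:
                continue  # already has its gateway
            sp = species[int(rng.integers(n_species))]
            ec.add((sp, m))
            consumed.add(m)
    return CrossFeedingNetwork(species, metabolites, ec, ep), sorted(intake)


def _fixed_point_abundances(
    net: CrossFeedingNetwork,
    present: list[str],
    intake: IntakeProfile,
    params: FlowParameters,
    tol: float = 1e-15,
    prune: float = 1e-10,
    max_iter: int = 5000,
) -> dict[str, float] | None:
    """Iterate abundances -> normalized predicted biomass to a fixed point.

    The map acts like replicator dynamics: species sharing a nutrient pool
    with fitter competitors decay geometrically, so relative abundances
    below ``prune`` are treated as extinct (otherwise they linger as
    denormals without ever reaching zero).  Returns the converged
    positive-abundance map, or None if no present species ever receives
    biomass or the iteration fails to settle.
    """
    c = np.array([intake.amounts.get(m, 0.0) for m in net.metabolites])
    idx = [net.species_index[s] for s in present]
    x = np.zeros(net.n_species)
    x[idx] = 1.0 / len(idx)

    C, P = net.masks()
    Cf = C.astype(float)
    n_out = P.sum(axis=1).astype(float)
    A_out = np.divide(P.T, n_out[None, :], out=np.zeros((net.n_metabolites, net.n_species)), where=n_out > 0)
    f = params.f

    def biomass(x: np.ndarray) -> np.ndarray:
        weighted = Cf * x[:, None]
        col = weighted.sum(axis=0)
        A_in = np.divide(weighted, col[None, :], out=np.zeros_like(weighted), where=col > 0)
        consumable = col > 0
        b = np.zeros(net.n_species)
        d = c
        for _ in range(params.n_levels):
            consumed = A_in @ np.where(consumable, d, 0.0)
            b += (1.0 - f) * consumed
            d = f * (A_out @ consumed)
        return b

    for _ in range(max_iter):
        b = biomass(x)
        b[x == 0] = 0.0  # absent species stay absent
        total = b.sum()
        if total <= 0:
            return None
        b[b < prune * total] = 0.0
        x_new = b / b.sum()
        if np.max(np.abs(x_new - x)) < tol:
            return {net.species[k]: float(x_new[k]) for k in np.nonzero(x_new)[0]}
        x = x_new
    return None


def generate_cohort(
    network: CrossFeedingNetwork,
    intake_metabolites: list[str],
    f: float = 0.9,
    n_levels: int = 4,
    n_samples: int = 41,
    seed: int = 0,
    intake_concentration: float = 1.0,
    presence_prob: float = 0.8,
    sigma_abund: float = 0.0,
    sigma_metab: float = 0.0,
    max_retries: int = 20,
) -> tuple[Cohort, SyntheticTruth]:
    """Generate a cohort from the forward model with known truth.

    Per sample: a true intake is drawn from a symmetric Dirichlet over the
    intake metabolites; a species presence mask is drawn (each species
    present with ``presence_prob``); abundances are the fixed point of the
    forward cascade at the true intake; the noiseless metabolome is the
    cascade's prediction at those abundances; observed profiles multiply
    the noiseless ones by 10**N(0, sigma) and renormalize.
    """
    params = FlowParameters(f=f, n_levels=n_levels)
    # independent substreams: the community structure (intakes, masks) is
    # identical across noise settings at the same seed
    rng, rng_noise = np.random.default_rng(seed).spawn(2)
    samples: list[CommunitySample] = []
    truth = SyntheticTruth(
        network=network,
        f=f,
        n_levels=n_levels,
        intake_metabolites=list(intake_metabolites),
        true_intake={},
        noiseless_abundances={},
        noiseless_metabolome={},
        sigma_abund=sigma_abund,
        sigma_metab=sigma_metab,
        seed=seed,
    )
    K = len(intake_metabolites)
    for j in range(n_samples):
        sid = f"sample_{j:03d}"
        for _attempt in range(max_retries):
            w = rng.dirichlet(np.full(K, intake_concentration))
            intake = IntakeProfile(dict(zip(intake_metabolites, map(float, w))))
            mask = rng.uniform(size=network.n_species) < presence_prob
            present = {s for s, keep in zip(network.species, mask) if keep}
            # every intake metabolite needs a present consumer, else its
            # amount leaves no trace in the abundances and cannot be inferred
            for m in intake_metabolites:
                consumers = sorted(s for s, met in network.consumption_edges if met == m)
                if consumers and not (present & set(consumers)):
                    present.add(consumers[int(rng.integers(len(consumers)))])
            present = sorted(present)
            if not present:
                continue
            fixed = _fixed_point_abundances(network, present, intake, params)
            if fixed is None or len(fixed) < 2:
                continue
            break
        else:
            raise RuntimeError(f"could not generate a viable sample after {max_retries} tries")

        clean = CommunitySample(sid, fixed)
        flow = run_cascade(network, clean, intake, params)
        _, metabolome = predict_profiles(flow)
        met_clean = {m: float(v) for m, v in metabolome.items() if v > 0}

        truth.true_intake[sid] = dict(intake.amounts)
        truth.noiseless_abundances[sid] = dict(fixed)
        truth.noiseless_metabolome[sid] = met_clean

        obs_ab = {
            s: v * 10 ** rng_noise.normal(0.0, sigma_abund) if sigma_abund > 0 else v
            for s, v in fixed.items()
        }
        obs_met = {
            m: v * 10 ** rng_noise.normal(0.0, sigma_metab) if sigma_metab > 0 else v
            for m, v in met_clean.items()
        }
        tot = sum(obs_met.values())
        obs_met = {m: v / tot for m, v in obs_met.items()}
        samples.append(CommunitySample(sid, obs_ab, measured_metabolome=obs_met))

    return Cohort(samples, network), truth


# -- reference-shaped tables -------------------------------------------------

#: shapes of the curated capability database the model was built around
REFERENCE_SHAPE = {
    "n_microbes": 567,
    "n_metabolites": 235,
    "n_interactions": 4248,
    "n_host_cell_types": 3,
    "n_raw_species": 570,
    "n_raw_metabolites": 244,
    "n_intake_metabolites": 19,
}

_IONS = ["Na+", "Ca+", "K+", "Mg2+", "Cl-", "Fe2+", "Zn2+", "Mn2+", "Cu2+"]
_HOST_CELLS = ["host cell type A", "host cell type B", "host cell type C"]
_INTAKE_NAMES = [
    "arabinose", "raffinose", "xylose", "glucose", "fructose", "galactose",
    "sucrose", "maltose", "lactose", "mannose", "rhamnose", "fucose",
    "cellobiose", "ribose", "arabinan breakdown product", "pectin breakdown product",
    "starch breakdown product", "inulin breakdown product", "xylan breakdown product",
]


def generate_reference_tables(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write synthetic stand-ins for the curated capability table and the
    intake-metabolite list, with exactly the printed shapes (570 raw species
    of which 3 are host cell types, 244 raw metabolites of which 9 are ions,
    4,248 microbe-metabolite interactions after filtering, 19 intake
    metabolites).  The names and wiring are synthetic; only the shapes are
    meaningful.  Returns paths: capability_table, intake_list, ion_list,
    host_list.
    """
    shape = REFERENCE_SHAPE
    rng = np.random.default_rng(seed)
    n_sp = shape["n_microbes"]
    n_met = shape["n_metabolites"]
    species = [f"Synthgenus{k // 4:03d} synthspecies{k:03d}" for k in range(n_sp)]
    metabolites = _INTAKE_NAMES + [
        f"synthmet_{k:03d}" for k in range(n_met - len(_INTAKE_NAMES))
    ]
    assert len(metabolites) == n_met

    # cover every microbe and metabolite, then top up to the printed count
    triples: set[tuple[str, str, str]] = set()
    for k, sp in enumerate(species):
        triples.add((sp, metabolites[k % n_met], "consumption"))
        triples.add((sp, metabolites[(k + 1) % n_met], "production"))
    for m in metabolites:
        triples.add((species[int(rng.integers(n_sp))], m, "consumption"))
    while len(triples) < shape["n_interactions"]:
        sp = species[int(rng.integers(n_sp))]
        m = metabolites[int(rng.integers(n_met))]
        d = "consumption" if rng.uniform() < 0.5 else "production"
        triples.add((sp, m, d))

    rows = sorted(triples)
    # edges that the ion/host-cell filter must remove
    for ion in _IONS:
        for _ in range(3):
            rows.append((species[int(rng.integers(n_sp))], ion, "consumption"))
    for hc in _HOST_CELLS:
        for _ in range(4):
            rows.append((hc, metabolites[int(rng.integers(n_met))], "consumption"))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cap = out / "capabilities_synthetic.tsv"
    pd.DataFrame(rows, columns=["species", "metabolite", "direction"]).to_csv(
        cap, sep="\t", index=False
    )
    intake = out / "intake_metabolites_synthetic.txt"
    intake.write_text("\n".join(_INTAKE_NAMES) + "\n")
    ion_list = out / "excluded_metabolites_synthetic.txt"
    ion_list.write_text("\n".join(_IONS) + "\n")
    host_list = out / "excluded_species_synthetic.txt"
    host_list.write_text("\n".join(_HOST_CELLS) + "\n")
    return {
        "capability_table": cap,
        "intake_list": intake,
        "ion_list": ion_list,
        "host_list": host_list,
    }


# -- cohort IO ---------------------------------------------------------------

def write_cohort(cohort: Cohort, truth: SyntheticTruth, out_dir) -> None:
    """Write capability TSV, abundance TSV, metabolome TSV and truth JSON."""
    from .network import write_interactions

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort.network is not None:
        write_interactions(cohort.network, out / "capabilities.tsv")
    ab = pd.DataFrame(
        {s.sample_id: pd.Series(s.abundances) for s in cohort}
    ).fillna(0.0)
    ab.rename_axis("species").to_csv(out / "abundances.tsv", sep="\t")
    met = pd.DataFrame(
        {
            s.sample_id: pd.Series(s.measured_metabolome)
            for s in cohort
            if s.measured_metabolome
        }
    ).fillna(0.0)
    if not met.empty:
        met.rename_axis("metabolite").to_csv(out / "metabolome.tsv", sep="\t")
    payload = {
        "f": truth.f,
        "n_levels": truth.n_levels,
        "seed": truth.seed,
        "sigma_abund": truth.sigma_abund,
        "sigma_metab": truth.sigma_metab,
        "intake_metabolites": truth.intake_metabolites,
        "true_intake": truth.true_intake,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
    (out / "intake_metabolites.txt").write_text("\n".join(truth.intake_metabolites) + "\n")


def read_abundance_table(path) -> list[CommunitySample]:
    """Read a wide TSV (rows = species, columns = samples) into samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        CommunitySample(col, {sp: v for sp, v in df[col].items() if v > 0})
        for col in df.columns
    ]


def attach_metabolomes(samples: list[CommunitySample], path) -> list[CommunitySample]:
    """Attach measured metabolomes (wide TSV, rows = metabolites) by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = []
    for s in samples:
        met = None
        if s.sample_id in df.columns:
            met = {m: v for m, v in df[s.sample_id].items() if v > 0}
        out.append(CommunitySample(s.sample_id, s.abundances, met))
    return out
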