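"""Cross-feeding capability networks.

A capability network is a bipartite graph between microbial species and
metabolites with two edge classes: *consumption* (the species can take the
metabolite up as a nutrient) and *production* (the species can secrete it
as a metabolic byproduct).  Networks of this kind are distilled from
manually curated databases of gut microbial metabolism (NJS16-style
tables); this module reads, filters and summarizes such tables and maps
observed taxon names onto them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONSUMPTION = "consumption"
PRODUCTION = "production"

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonicalize a taxon or metabolite name.

    Case-folds, strips, maps underscores to spaces and collapses internal
    whitespace, so that MetaPhlAn-style labels (``Bacteroides_uniformis``)
    and curated labels (``Bacteroides uniformis``) compare equal.
    """
    return _WS.sub(" ", str(name).replace("_", " ").strip()).casefold()


class FormatError(ValueError):
    """A capability table is missing required structure."""


@dataclass(frozen=True)
class Interaction:
    """One capability record: a species can consume or produce a metabolite."""

    species_id: str
    metabolite_id: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (CONSUMPTION, PRODUCTION):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.species_id or not self.metabolite_id:
            raise ValueError("empty species or metabolite id")


@dataclass
class ExclusionList:
    """Ids to drop from a network (e.g. inorganic ions, host cell types)."""

    metabolite_ids: set[str] = field(default_factory=set)
    species_ids: set[str] = field(default_factory=set)

    @classmethod
    def from_files(cls, metabolite_file=None, species_file=None) -> "ExclusionList":
        def read(p):
            if p is None:
                return set()
            lines = Path(p).read_text().splitlines()
            return {ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")}

        return cls(metabolite_ids=read(metabolite_file), species_ids=read(species_file))


@dataclass
class FilterReport:
    n_species_removed: int = 0
    n_metabolites_removed: int = 0
    n_edges_removed: int = 0
    n_isolated_species_removed: int = 0
    n_isolated_metabolites_removed: int = 0
    absent_ids: list[str] = field(default_factory=list)


class CrossFeedingNetwork:
    """Bipartite species-metabolite capability structure.

    Parameters
    ----------
    species, metabolites : sequences of ids, first-appearance order.
    consumption_edges, production_edges : iterables of (species, metabolite)
        id pairs.  Duplicates are collapsed.
    genus_of : optional species -> genus map; when absent the genus is the
        first whitespace-delimited token of the species name.
    """

    def __init__(
        self,
        species: Sequence[str],
        metabolites: Sequence[str],
        consumption_edges: Iterable[tuple[str, str]],
        production_edges: Iterable[tuple[str, str]],
        genus_of: Mapping[str, str] | None = None,
    ):
        self.species = list(dict.fromkeys(species))
        self.metabolites = list(dict.fromkeys(metabolites))
        self.species_index = {s: k for k, s in enumerate(self.species)}
        self.metabolite_index = {m: k for k, m in enumerate(self.metabolites)}
        self.consumption_edges = set(map(tuple, consumption_edges))
        self.production_edges = set(map(tuple, production_edges))
        for sp, met in self.consumption_edges | self.production_edges:
            if sp not in self.species_index:
                raise ValueError(f"edge endpoint species {sp!r} not in species list")
            if met not in self.metabolite_index:
                raise ValueError(f"edge endpoint metabolite {met!r} not in metabolite list")
        self._genus_of = dict(genus_of) if genus_of else None
        self._masks: tuple[np.ndarray, np.ndarray] | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def genus(self, species_id: str) -> str:
        if self._genus_of and species_id in self._genus_of:
            return self._genus_of[species_id]
        return species_id.split()[0] if species_id.split() else species_id

    def consumables(self, species_id: str) -> set[str]:
        return {m for s, m in self.consumption_edges if s == species_id}

    def byproducts(self, species_id: str) -> set[str]:
        return {m for s, m in self.production_edges if s == species_id}

    def capability_sets(self, species_id: str) -> tuple[frozenset, frozenset]:
        return frozenset(self.consumables(species_id)), frozenset(self.byproducts(species_id))

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense boolean (consumption, production) masks, species x metabolite."""
        if self._masks is None:
            C = np.zeros((self.n_species, self.n_metabolites), dtype=bool)
            P = np.zeros_like(C)
            for sp, met in self.consumption_edges:
                C[self.species_index[sp], self.metabolite_index[met]] = True
            for sp, met in self.production_edges:
                P[self.species_index[sp], self.metabolite_index[met]] = True
            self._masks = (C, P)
        return self._masks

    def copy_with_edges(self, consumption_edges, production_edges) -> "CrossFeedingNetwork":
        return CrossFeedingNetwork(
            self.species, self.metabolites, consumption_edges, production_edges, self._genus_of
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CrossFeedingNetwork)
            and self.species == other.species
            and self.metabolites == other.metabolites
            and self.consumption_edges == other.consumption_edges
            and self.production_edges == other.production_edges
        )

    def __repr__(self) -> str:
        return (
            f"CrossFeedingNetwork({self.n_species} species, {self.n_metabolites} "
            f"metabolites, {len(self.consumption_edges)} consumption / "
            f"{len(self.production_edges)} production edges)"
        )


# -- IO ---------------------------------------------------------------------

_DEFAULT_COLUMNS = {"species": "species", "metabolite": "metabolite", "direction": "direction"}
_DEFAULT_TOKENS = {"consumption": CONSUMPTION, "production": PRODUCTION}


def load_interactions(
    table_path,
    dialect: str | None = None,
    columns: Mapping[str, str] | None = None,
    direction_tokens: Mapping[str, str] | None = None,
    genus_column: str | None = None,
) -> CrossFeedingNetwork:
    """Read a capability table (TSV/CSV or XLSX) into a network.

    ``columns`` maps the roles {"species", "metabolite", "direction"} to the
    actual column names; ``direction_tokens`` maps the table's direction
    labels onto {"consumption", "production"}.  Duplicate rows are dropped
    with a warning; unknown direction tokens raise listing the offending
    rows.  Species and metabolite order is first-appearance, so reloading a
    written table reproduces the network exactly.
    """
    path = Path(table_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "delimited"
    if dialect == "xlsx":
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)

    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    tokens = {k.casefold(): v for k, v in (direction_tokens or _DEFAULT_TOKENS).items()}

    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing}; found {list(df.columns)}")

    species_col = df[cols["species"]].astype(str).str.strip()
    met_col = df[cols["metabolite"]].astype(str).str.strip()
    dir_col = df[cols["direction"]].astype(str).str.strip().str.casefold()

    bad = ~dir_col.isin(tokens)
    if bad.any():
        rows = list(df.index[bad][:20])
        raise FormatError(
            f"unknown direction token(s) {sorted(dir_col[bad].unique())} in rows {rows}"
        )

    records = list(zip(species_col, met_col, dir_col.map(tokens)))
    seen: set = set()
    edges_c, edges_p = [], []
    species, metabolites = [], []
    n_dup = 0
    for sp, met, d in records:
        if not sp or not met:
            raise FormatError("empty species or metabolite id after stripping")
        key = (sp, met, d)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        species.append(sp)
        metabolites.append(met)
        (edges_c if d == CONSUMPTION else edges_p).append((sp, met))
    if n_dup:
        logger.warning("dropped %d duplicate interaction rows from %s", n_dup, path.name)

    genus_of = None
    if genus_column and genus_column in df.columns:
        genus_of = dict(zip(species_col, df[genus_column].astype(str).str.strip()))

    return CrossFeedingNetwork(species, metabolites, edges_c, edges_p, genus_of)


def write_interactions(net: CrossFeedingNetwork, table_path) -> None:
    """Write a network back to a delimited capability table (round-trips)."""
    rows = [(s, m, CONSUMPTION) for s, m in sorted(net.consumption_edges)]
    rows += [(s, m, PRODUCTION) for s, m in sorted(net.production_edges)]
    df = pd.DataFrame(rows, columns=["species", "metabolite", "direction"])
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    df.to_csv(table_path, sep=sep, index=False)


def filter_network(
    net: CrossFeedingNetwork,
    excl: ExclusionList | None = None,
    drop_isolated: bool = False,
) -> tuple[CrossFeedingNetwork, FilterReport]:
    """Remove excluded species/metabolites (and their edges); optionally prune
    entities left without any edge.  Excluding an absent id is a logged no-op."""
    excl = excl or ExclusionList()
    report = FilterReport()
    report.absent_ids = sorted(
        (excl.species_ids - set(net.species)) | (excl.metabolite_ids - set(net.metabolites))
    )
    if report.absent_ids:
        logger.info("exclusion ids not present in network: %s", report.absent_ids)

    keep_sp = [s for s in net.species if s not in excl.species_ids]
    keep_met = [m for m in net.metabolites if m not in excl.metabolite_ids]
    report.n_species_removed = net.n_species - len(keep_sp)
    report.n_metabolites_removed = net.n_metabolites - len(keep_met)

    sp_set, met_set = set(keep_sp), set(keep_met)
    ec = {(s, m) for s, m in net.consumption_edges if s in sp_set and m in met_set}
    ep = {(s, m) for s, m in net.production_edges if s in sp_set and m in met_set}
    report.n_edges_removed = (
        len(net.consumption_edges) + len(net.production_edges) - len(ec) - len(ep)
    )

    if drop_isolated:
        touched_sp = {s for s, _ in ec} | {s for s, _ in ep}
        touched_met = {m for _, m in ec} | {m for _, m in ep}
        report.n_isolated_species_removed = sum(1 for s in keep_sp if s not in touched_sp)
        report.n_isolated_metabolites_removed = sum(1 for m in keep_met if m not in touched_met)
        keep_sp = [s for s in keep_sp if s in touched_sp]
        keep_met = [m for m in keep_met if m in touched_met]

    genus_of = {s: net.genus(s) for s in keep_sp} if net._genus_of else None
    return CrossFeedingNetwork(keep_sp, keep_met, ec, ep, genus_of), report


# -- taxon mapping ----------------------------------------------------------

@dataclass
class MappingRecord:
    observed_name: str
    mapped_id: str | None
    stage: str  # "exact" | "genus" | "genus-core" | "unmapped"
    n_capabilities: int = 0


@dataclass
class MappingReport:
    records: list[MappingRecord]
    #: species added to the network by the genus fallback, with their edges
    added_edges_c: list[tuple[str, str]] = field(default_factory=list)
    added_edges_p: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mapped(self) -> dict[str, str]:
        return {r.observed_name: r.mapped_id for r in self.records if r.mapped_id}

    @property
    def unmapped(self) -> list[str]:
        return [r.observed_name for r in self.records if r.mapped_id is None]

    def coverage(self, abundances: Mapping[str, float]) -> float:
        """Fraction of total abundance carried by mapped names (in [0, 1])."""
        total = sum(abundances.values())
        if total <= 0:
            return 0.0
        mapped = self.mapped
        return sum(v for k, v in abundances.items() if k in mapped) / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.observed_name, r.mapped_id or "", r.stage, r.n_capabilities) for r in self.records],
            columns=["observed_name", "mapped_id", "stage", "n_capabilities"],
        )


def map_taxa(
    observed_names: Sequence[str],
    net: CrossFeedingNetwork,
    genus_fallback: bool = True,
    core_capability_genera: Iterable[str] = (),
) -> MappingReport:
    """Map observed taxon names onto network species.

    Stage 1 is an exact match after name normalization.  Stage 2 (genus
    fallback) assigns an unmapped species the shared capability set of its
    in-network congeners when all congeners have identical capabilities; for
    genera explicitly listed in ``core_capability_genera`` the *intersection*
    ("core") of the congeners' capabilities is used instead.  Everything else
    is reported unmapped.
    """
    norm_to_id = {normalize_name(s): s for s in net.species}
    by_genus: dict[str, list[str]] = {}
    for s in net.species:
        by_genus.setdefault(normalize_name(net.genus(s)), []).append(s)
    core_genera = {normalize_name(g) for g in core_capability_genera}

    records: list[MappingRecord] = []
    added_c: list[tuple[str, str]] = []
    added_p: list[tuple[str, str]] = []
    for name in observed_names:
        norm = normalize_name(name)
        if norm in norm_to_id:
            sid = norm_to_id[norm]
            ncap = len(net.consumables(sid)) + len(net.byproducts(sid))
            records.append(MappingRecord(name, sid, "exact", ncap))
            continue
        if genus_fallback:
            genus = norm.split()[0] if norm.split() else norm
            congeners = by_genus.get(genus, [])
            if congeners:
                caps = [net.capability_sets(s) for s in congeners]
                if all(c == caps[0] for c in caps[1:]):
                    cons, prod = caps[0]
                    stage = "genus"
                elif genus in core_genera:
                    cons = frozenset.intersection(*(c for c, _ in caps))
                    prod = frozenset.intersection(*(p for _, p in caps))
                    stage = "genus-core"
                else:
                    records.append(MappingRecord(name, None, "unmapped"))
                    continue
                new_id = name.strip()
                added_c.extend((new_id, m) for m in sorted(cons))
                added_p.extend((new_id, m) for m in sorted(prod))
                records.append(MappingRecord(name, new_id, stage, len(cons) + len(prod)))
                continue
        records.append(MappingRecord(name, None, "unmapped"))
    return MappingReport(records, added_c, added_p)


def extend_network(net: CrossFeedingNetwork, report: MappingReport) -> CrossFeedingNetwork:
    """Return a network augmented with the species the genus fallback added."""
    if not (report.added_edges_c or report.added_edges_p):
        return net
    new_species = list(net.species)
    for sp, _ in report.added_edges_c + report.added_edges_p:
        if sp not in new_species:
            new_species.append(sp)
    return CrossFeedingNetwork(
        new_species,
        net.metabolites,
        net.consumption_edges | set(report.added_edges_c),
        net.production_edges | set(report.added_edges_p),
        net._genus_of,
    )


# -- summary ----------------------------------------------------------------

def network_summary(net: CrossFeedingNetwork) -> dict:
    """Counts and degree distributions for a capability network."""
    C, P = net.masks()
    return {
        "n_species": net.n_species,
        "n_metabolites": net.n_metabolites,
        "n_consumption_edges": len(net.consumption_edges),
        "n_production_edges": len(net.production_edges),
        "n_interactions": len(net.consumption_edges) + len(net.production_edges),
        "species_in_degree": C.sum(axis=1).tolist(),
        "species_out_degree": P.sum(axis=1).tolist(),
        "metabolite_consumer_degree": C.sum(axis=0).tolist(),
        "metabolite_producer_degree": P.sum(axis=0).tolist(),
    }
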