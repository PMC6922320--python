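"""Level-resolved effective diversity.

At each trophic step, each species' (or genus', or metabolite's) relative
contribution to that level's activity is computed per sample; inverse-
Simpson diversity is then taken within samples (alpha), on the cohort-mean
profile (gamma), and as their ratio (beta).  Microbial contributions are
indexed internally by consumption step l = 1.. and reported by default at
figure-level l + 1, so that metabolites occupy level 1 (the intake) and
microbes first appear at level 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .flow import FlowResult
from .network import CrossFeedingNetwork

ENTERING = "entering"  # metabolite vector entering a level (level 1 = intake)
PRODUCED = "produced"  # byproduct vector a level emits
UNCONSUMED = "unconsumed"  # part of a level's input nothing present consumes


@dataclass
class LevelContribution:
    """Per-level, per-sample relative contributions of entities.

    ``values[l, j, i]`` is the contribution of entity ``i`` at level index
    ``l`` in sample ``j``; each (l, j) slice sums to 1 where any activity
    exists, else is all-zero.
    """

    entity_class: str  # species | genus | metabolite
    entities: list[str]
    values: np.ndarray  # (n_levels, n_samples, n_entities)
    level_labels: list[int]  # reported level numbers

    @property
    def n_levels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _normalize_slices(raw: np.ndarray) -> np.ndarray:
    totals = raw.sum(axis=2, keepdims=True)
    return np.divide(raw, totals, out=np.zeros_like(raw), where=totals > 0)


def level_contributions(
    flows: Sequence[FlowResult],
    entity_class: str = "species",
    level_profile_mode: str = ENTERING,
    network: CrossFeedingNetwork | None = None,
    microbe_level_offset: int = 1,
) -> LevelContribution:
    """Relative per-level contributions across a cohort of cascade runs.

    species/genus: biomass increments per consumption step, normalized within
    each (level, sample); genus sums congeners first.  metabolite: the
    per-level metabolite profile selected by ``level_profile_mode``
    ("entering" prepends the intake as level 1).
    """
    if not flows:
        raise ValueError("no flows given")
    n_steps = flows[0].n_levels
    if any(f.n_levels != n_steps for f in flows):
        raise ValueError("flows have differing level counts")

    if entity_class in ("species", "genus"):
        entities = list(flows[0].species)
        raw = np.stack([f.biomass_by_level for f in flows], axis=1)  # (L, J, S)
        if entity_class == "genus":
            def genus_of(s: str) -> str:
                if network is not None:
                    return network.genus(s)
                parts = s.split()
                return parts[0] if parts else s

            genera = sorted({genus_of(s) for s in entities})
            gidx = {g: k for k, g in enumerate(genera)}
            agg = np.zeros(raw.shape[:2] + (len(genera),))
            for k, s in enumerate(entities):
                agg[:, :, gidx[genus_of(s)]] += raw[:, :, k]
            entities, raw = genera, agg
        labels = [l + microbe_level_offset for l in range(1, n_steps + 1)]
        return LevelContribution(entity_class, entities, _normalize_slices(raw), labels)

    if entity_class != "metabolite":
        raise ValueError(f"unknown entity class {entity_class!r}")

    n_mets = min(len(f.metabolites) for f in flows)
    entities = list(flows[0].metabolites[:n_mets])
    if level_profile_mode == ENTERING:
        mats = []
        for f in flows:
            inputs = np.vstack([f.intake[None, :n_mets], f.byproducts_by_level[:-1, :n_mets]])
            mats.append(inputs)
        raw = np.stack(mats, axis=1)
        labels = list(range(1, n_steps + 1))
    elif level_profile_mode == PRODUCED:
        raw = np.stack([f.byproducts_by_level[:, :n_mets] for f in flows], axis=1)
        labels = list(range(2, n_steps + 2))
    elif level_profile_mode == UNCONSUMED:
        raw = np.stack([f.unconsumed_by_level[:, :n_mets] for f in flows], axis=1)
        labels = list(range(1, n_steps + 1))
    else:
        raise ValueError(f"unknown level profile mode {level_profile_mode!r}")
    return LevelContribution("metabolite", entities, _normalize_slices(raw), labels)


@dataclass
class DiversitySummary:
    """Per-level inverse-Simpson alpha, gamma and beta diversity."""

    table: pd.DataFrame  # columns: level, D_alpha, D_gamma, D_beta, n_samples

    def __getitem__(self, level: int) -> pd.Series:
        return self.table.set_index("level").loc[level]


def diversity_summary(contrib: LevelContribution) -> DiversitySummary:
    """D_alpha(l) = 1/<sum_i p_i^2>_j, D_gamma(l) = 1/sum_i mean_j(p_i)^2,
    D_beta = D_gamma / D_alpha; samples without activity at a level are
    excluded from that level's averages, and levels with no activity at all
    are reported as missing (NaN)."""
    rows = []
    for l in range(contrib.n_levels):
        slc = contrib.values[l]  # (J, S)
        active = slc.sum(axis=1) > 0
        if not active.any():
            rows.append((contrib.level_labels[l], np.nan, np.nan, np.nan, 0))
            continue
        p = slc[active]
        simpson = (p**2).sum(axis=1)
        d_alpha = 1.0 / simpson.mean()
        pbar = p.mean(axis=0)
        d_gamma = 1.0 / (pbar**2).sum()
        rows.append((contrib.level_labels[l], d_alpha, d_gamma, d_gamma / d_alpha, int(active.sum())))
    return DiversitySummary(
        pd.DataFrame(rows, columns=["level", "D_alpha", "D_gamma", "D_beta", "n_samples"])
    )


def assign_dominant_level(contrib: LevelContribution) -> pd.DataFrame:
    """Assign each entity the level where its cross-sample mean contribution
    peaks (ties break toward the earlier level and are flagged)."""
    mean_contrib = contrib.values.mean(axis=1)  # (L, S)
    rows = []
    for i, ent in enumerate(contrib.entities):
        col = mean_contrib[:, i]
        if col.sum() == 0:
            continue
        best = int(np.argmax(col))
        tie = bool(np.sum(col == col[best]) > 1)
        rows.append(
            (ent, contrib.entity_class, contrib.level_labels[best], float(col[best]), tie)
        )
    return pd.DataFrame(
        rows, columns=["entity", "entity_class", "level", "mean_contribution", "tied"]
    )
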