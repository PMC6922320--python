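"""Model/Results facade over the trophic cascade.

`TrophicModel` binds a capability network, one community sample and the
candidate intake metabolites; `fit()` infers the sample's nutrient intake
and returns a `TrophicFitResults` carrying the fitted intake, the misfit,
the predicted profiles and metabolome diagnostics, with a `summary()`
table.  `simulate()` runs the cascade at a given intake without fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import MetabolomeComparison, compare_metabolome
from .fitting import DEFAULT_FLOOR, FitResult, abundance_log_error, fit_intake
from .flow import (
    CommunitySample,
    FlowParameters,
    FlowResult,
    IntakeProfile,
    predict_profiles,
    run_cascade,
)
from .network import CrossFeedingNetwork


class TrophicModel:
    """Trophic cascade model for one individual's gut community.

    Parameters
    ----------
    network : capability network the sample's species are mapped onto.
    sample : community sample (relative abundances; species outside the
        network are dropped and the rest renormalized, as in practice
        unmapped taxa are excluded before fitting).
    intake_metabolites : the candidate nutrient-intake metabolites.
    params : cascade parameters (byproduct fraction f, level count, rates).
    """

    def __init__(
        self,
        network: CrossFeedingNetwork,
        sample: CommunitySample,
        intake_metabolites: Sequence[str],
        params: FlowParameters | None = None,
    ):
        self.network = network
        self.sample_full = sample
        self.sample = sample.restrict_to(set(network.species))
        if not self.sample.abundances:
            raise ValueError("no sample species map into the network")
        self.intake_metabolites = list(intake_metabolites)
        self.params = params or FlowParameters()

    @classmethod
    def from_dataframe(
        cls,
        network: CrossFeedingNetwork,
        abundances: pd.DataFrame,
        sample_id: str,
        intake_metabolites: Sequence[str],
        params: FlowParameters | None = None,
        metabolome: pd.DataFrame | None = None,
    ) -> "TrophicModel":
        """Build from wide tables (rows = species / metabolites, columns =
        sample ids)."""
        ab = {sp: float(v) for sp, v in abundances[sample_id].items() if v > 0}
        met = None
        if metabolome is not None and sample_id in metabolome.columns:
            met = {m: float(v) for m, v in metabolome[sample_id].items() if v > 0}
        return cls(network, CommunitySample(sample_id, ab, met), intake_metabolites, params)

    def simulate(self, intake: IntakeProfile) -> FlowResult:
        """Run the cascade at a fixed intake (no fitting)."""
        return run_cascade(self.network, self.sample, intake, self.params)

    def fit(
        self,
        n_restarts: int = 10,
        seed: int = 0,
        floor: float = DEFAULT_FLOOR,
        tol: float = 1e-10,
    ) -> "TrophicFitResults":
        fit = fit_intake(
            self.network,
            self.sample,
            self.intake_metabolites,
            self.params,
            n_restarts=n_restarts,
            seed=seed,
            floor=floor,
            tol=tol,
        )
        flow = self.simulate(fit.intake)
        return TrophicFitResults(self, fit, flow, floor)


@dataclass
class TrophicFitResults:
    """Fitted intake plus derived predictions for one sample."""

    model: TrophicModel
    fit: FitResult
    flow: FlowResult
    floor: float = DEFAULT_FLOOR

    @property
    def intake(self) -> IntakeProfile:
        return self.fit.intake

    @property
    def objective(self) -> float:
        return self.fit.objective

    @property
    def predicted_abundances(self) -> pd.Series:
        p, _ = predict_profiles(self.flow)
        return p

    @property
    def predicted_metabolome(self) -> pd.Series:
        _, m = predict_profiles(self.flow)
        return m

    def abundance_correlations(self) -> dict[str, float]:
        """Pearson r between predicted and observed abundances, on both the
        linear and the log10 scale (over the fitted species)."""
        obs = self.model.sample.abundances
        pred = self.predicted_abundances
        keys = [s for s in pred.index if obs.get(s, 0.0) > 0]
        p = np.array([pred[s] for s in keys])
        m = np.array([obs[s] for s in keys])
        lp = np.log10(np.maximum(p, self.floor))
        lm = np.log10(np.maximum(m, self.floor))
        out = {}
        out["linear"] = float(np.corrcoef(p, m)[0, 1]) if p.size > 2 else float("nan")
        out["log10"] = float(np.corrcoef(lp, lm)[0, 1]) if p.size > 2 else float("nan")
        return out

    def compare_metabolome(self, measured: dict | None = None) -> MetabolomeComparison:
        measured = measured or self.model.sample.measured_metabolome
        if not measured:
            raise ValueError("no measured metabolome available")
        return compare_metabolome(self.predicted_metabolome.to_dict(), measured, self.floor)

    def summary(self) -> str:
        lines = [
            "Trophic cascade intake fit",
            "=" * 44,
            f"sample:              {self.model.sample.sample_id}",
            f"species fitted:      {self.fit.n_species}",
            f"intake metabolites:  {len(self.model.intake_metabolites)}",
            f"f (byproduct frac):  {self.model.params.f}",
            f"trophic levels:      {self.model.params.n_levels}",
            f"restarts:            {len(self.fit.restart_objectives)} (seed {self.fit.seed})",
            f"converged:           {self.fit.converged}",
            f"objective (dex):     {self.objective:.4f}",
        ]
        corr = self.abundance_correlations()
        lines.append(f"abundance r (log10): {corr['log10']:.3f}")
        lines.append(f"abundance r (linear):{corr['linear']:.3f}")
        bal = self.flow.mass_balance_error()
        lines.append(f"mass balance error:  {bal:.2e}")
        if self.model.sample.measured_metabolome:
            cmp_ = self.compare_metabolome()
            lines.append(
                f"metabolome: n={cmp_.n} matched, r(log10)={cmp_.pearson_r:.3f}, "
                f"adjusted P={cmp_.adjusted_p:.3g}, log accuracy={cmp_.log_accuracy:.3f} dex"
            )
        lines.append("-" * 44)
        lines.append("fitted intake (top 10):")
        top = sorted(self.intake.amounts.items(), key=lambda kv: -kv[1])[:10]
        for m, v in top:
            lines.append(f"  {m:<32s} {v:.4f}")
        return "\n".join(lines)

    def intake_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.intake.amounts.items()),
            columns=["metabolite", "fitted_amount"],
        ).assign(sample_id=self.model.sample.sample_id)
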