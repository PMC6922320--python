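"""Metabolome scoring and (f, N_levels) calibration.

The predicted fecal metabolome is an independent output of the cascade
(only the intake was fitted, and only against abundances), so agreement
between predicted and measured metabolomes scores the model.  Agreement is
quantified on the log10 scale by the Pearson correlation (with a P-value
whose degrees of freedom are reduced by the two fitted global parameters)
and by the logarithmic accuracy, the mean order-of-magnitude error.  A grid
search over the byproduct fraction f and the level count selects the cell
that best matches a cohort's measured metabolomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import DEFAULT_FLOOR, fit_intake
from .flow import Cohort, FlowParameters, run_cascade, predict_profiles
from .network import CrossFeedingNetwork

N_FITTED_PARAMS = 2  # f and the level count

DEFAULT_F_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)
DEFAULT_N_GRID = tuple(range(2, 11))


def _match_and_floor(predicted: dict, measured: dict, floor: float, renormalize: bool):
    ids = sorted(set(predicted) & set(measured))
    p = np.array([predicted[i] for i in ids], dtype=float)
    m = np.array([measured[i] for i in ids], dtype=float)
    if renormalize:
        if p.sum() > 0:
            p = p / p.sum()
        if m.sum() > 0:
            m = m / m.sum()
    return ids, np.maximum(p, floor), np.maximum(m, floor)


def log_accuracy(
    predicted: dict[str, float],
    measured: dict[str, float],
    floor: float = DEFAULT_FLOOR,
    renormalize: bool = True,
) -> float:
    """Mean |log10 p_i - log10 m_i| over matched metabolites.

    Both profiles are renormalized over the matched subset by default
    (predictions are relative while measured units are instrument-specific).
    """
    ids, p, m = _match_and_floor(predicted, measured, floor, renormalize)
    if not ids:
        raise ValueError("no matched metabolites")
    return float(np.mean(np.abs(np.log10(p) - np.log10(m))))


def pearson_log(
    predicted: dict[str, float],
    measured: dict[str, float],
    floor: float = DEFAULT_FLOOR,
    renormalize: bool = True,
) -> float:
    """Pearson correlation of log10-floored matched profiles (NaN when a
    side has zero variance or fewer than 3 metabolites match)."""
    ids, p, m = _match_and_floor(predicted, measured, floor, renormalize)
    if len(ids) < 3:
        warnings.warn(f"only {len(ids)} matched metabolites; correlation undefined")
        return float("nan")
    lp, lm = np.log10(p), np.log10(m)
    if np.ptp(lp) == 0 or np.ptp(lm) == 0:
        warnings.warn("zero variance on one side; correlation undefined")
        return float("nan")
    return float(np.corrcoef(lp, lm)[0, 1])


def adjusted_pvalue(r: float, n: int, p_adj: int = N_FITTED_PARAMS) -> tuple[float, float, float]:
    """One-tailed P-value for a Pearson r with parameter-adjusted df.

    t = r sqrt((n-2)/(1-r^2)); the adjusted statistic divides t by
    sqrt((n-2)/(n-2-p_adj)) and is referred to a Student-t with
    n - 2 - p_adj degrees of freedom (upper tail), accounting for the
    p_adj fitted global parameters.
    Returns (t, adjusted_t, adjusted_p).
    """
    if n <= p_adj + 2:
        raise ValueError(f"need n > {p_adj + 2} for df = n - 2 - {p_adj} > 0, got n = {n}")
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    df = n - 2 - p_adj
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    t_adj = t * np.sqrt(df / (n - 2))
    p = float(stats.t.sf(t_adj, df))
    return float(t), float(t_adj), p


@dataclass
class MetabolomeComparison:
    """Scores for one sample's predicted vs measured metabolome."""

    metabolite_ids: list[str]
    predicted: np.ndarray
    measured: np.ndarray
    n: int
    pearson_r: float
    t_statistic: float
    adjusted_t: float
    adjusted_p: float
    log_accuracy: float


def compare_metabolome(
    predicted: dict[str, float],
    measured: dict[str, float],
    floor: float = DEFAULT_FLOOR,
    renormalize: bool = True,
    p_adj: int = N_FITTED_PARAMS,
) -> MetabolomeComparison:
    ids, p, m = _match_and_floor(predicted, measured, floor, renormalize)
    r = pearson_log(predicted, measured, floor, renormalize)
    n = len(ids)
    if np.isfinite(r) and n > p_adj + 2 and abs(r) < 1:
        t, t_adj, pv = adjusted_pvalue(r, n, p_adj)
    elif np.isfinite(r) and n > p_adj + 2:
        # perfect correlation: the t statistic diverges
        t = t_adj = float("inf") * np.sign(r)
        pv = 0.0 if r > 0 else 1.0
    else:
        t = t_adj = pv = float("nan")
    acc = log_accuracy(predicted, measured, floor, renormalize)
    return MetabolomeComparison(ids, p, m, n, r, t, t_adj, pv, acc)


@dataclass
class CalibrationResult:
    """Grid of cohort-aggregated scores over (f, N_levels)."""

    table: pd.DataFrame  # columns: f, n_levels, mean_r, median_adjusted_p, mean_log_accuracy, n_samples
    best_by_r: tuple[float, int]
    best_by_log_accuracy: tuple[float, int]

    def summary(self) -> str:
        lines = ["Calibration grid (cohort-aggregated)", "=" * 38]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append(f"best cell by mean Pearson r:      f={self.best_by_r[0]}, N={self.best_by_r[1]}")
        lines.append(
            f"best cell by mean log accuracy:   f={self.best_by_log_accuracy[0]}, "
            f"N={self.best_by_log_accuracy[1]}"
        )
        return "\n".join(lines)


def calibrate_grid(
    cohort: Cohort,
    intake_metabolites: Sequence[str],
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    n_restarts: int = 3,
    seed: int = 0,
    floor: float = DEFAULT_FLOOR,
    renormalize: bool = True,
    network: CrossFeedingNetwork | None = None,
) -> CalibrationResult:
    """Grid-search (f, N_levels): per cell, fit each sample's intake, predict
    its metabolome, score against the measured one, and aggregate (mean r,
    median adjusted P, mean log accuracy).  Best cell = argmax mean r; the
    argmin-log-accuracy cell is reported alongside."""
    net = network or cohort.network
    if net is None:
        raise ValueError("no network attached to cohort or passed explicitly")
    for s in cohort:
        if s.measured_metabolome is None:
            raise ValueError(f"sample {s.sample_id} lacks a measured metabolome")

    rows = []
    for f in f_grid:
        for n_levels in n_grid:
            params = FlowParameters(f=f, n_levels=n_levels)
            rs, ps, accs = [], [], []
            for k, sample in enumerate(sorted(cohort.samples, key=lambda s: s.sample_id)):
                fit = fit_intake(
                    net,
                    sample,
                    intake_metabolites,
                    params,
                    n_restarts=n_restarts,
                    seed=seed + 1000 * k,
                    floor=floor,
                )
                flow = run_cascade(net, sample.restrict_to(set(net.species)), fit.intake, params)
                _, pm = predict_profiles(flow)
                cmp_ = compare_metabolome(
                    pm.to_dict(), sample.measured_metabolome, floor, renormalize
                )
                if np.isfinite(cmp_.pearson_r):
                    rs.append(cmp_.pearson_r)
                    ps.append(cmp_.adjusted_p)
                accs.append(cmp_.log_accuracy)
            rows.append(
                {
                    "f": f,
                    "n_levels": n_levels,
                    "mean_r": float(np.mean(rs)) if rs else float("nan"),
                    "median_adjusted_p": float(np.nanmedian(ps)) if ps else float("nan"),
                    "mean_log_accuracy": float(np.mean(accs)) if accs else float("nan"),
                    "n_samples": len(rs),
                }
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_r"])
    if valid.empty:
        raise ValueError("all grid cells failed (too few matched metabolites)")
    ir = valid["mean_r"].idxmax()
    ia = table.dropna(subset=["mean_log_accuracy"])["mean_log_accuracy"].idxmin()
    best_r = (float(table.loc[ir, "f"]), int(table.loc[ir, "n_levels"]))
    best_a = (float(table.loc[ia, "f"]), int(table.loc[ia, "n_levels"]))
    return CalibrationResult(table, best_r, best_a)
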