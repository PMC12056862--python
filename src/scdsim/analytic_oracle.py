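"""Exact expected trajectories by enumeration over the finite profile space.

The patient state at baseline is discrete: each modifiable factor is
absent, present-and-modified, or present-and-unmodified (in scaled mode
the last two collapse into one deterministic "present" state), and the
adherence tier takes three values.  Because factors are assigned
independently, the joint distribution is a product measure and the full
mixture of per-patient hazards can be enumerated exactly — about
3^10 x 3 weighted Markov chains under the default 12-factor table,
which is desk-scale.  Each chain evolves in closed form:

    stable(t) = (1 - h - d)^t
    mci(t)    = h / (h + d) * (1 - (1 - h - d)^t)

with h the patient hazard and d the annual dropout probability.  The
probability-weighted mixture is the exact expectation of the Monte
Carlo engine's cumulative fractions, making this module the
verification oracle for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .cohort_engine import SimulationConfig
from .risk_model import AdherenceTier, ModificationMode, adherence_multiplier

__all__ = [
    "ExpectedTrajectory",
    "StateSpaceError",
    "closed_form_no_intervention",
    "binomial_se",
    "hazard_mixture",
    "enumerate_expected_outcomes",
    "stratified_expected_progression",
]

#: Refuse to enumerate beyond this many factor states (3^15 ≈ 14M).
MAX_STATES = 20_000_000


class StateSpaceError(ValueError):
    """Raised when the profile space is too large to enumerate."""


@dataclass(frozen=True)
class ExpectedTrajectory:
    """Exact per-year expected cumulative fractions (stable, mci, dropped)."""

    stable: np.ndarray
    mci: np.ndarray
    dropped: np.ndarray

    def __post_init__(self) -> None:
        for name in ("stable", "mci", "dropped"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        totals = self.stable + self.mci + self.dropped
        if not np.allclose(totals, 1.0, atol=1e-9):
            raise ValueError("expected fractions must sum to 1 each year")

    @property
    def years(self) -> int:
        return len(self.stable)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(1, self.years + 1),
                "stable": self.stable,
                "mci": self.mci,
                "dropped": self.dropped,
                "method": "analytic",
            }
        )


def closed_form_no_intervention(base: float, years: int, dropout: float = 0.0) -> float:
    """Cumulative progression fraction for a homogeneous untreated cohort.

    With no dropout this is ``1 - (1 - base)^years``; with dropout as a
    competing event the progression share of the absorbed mass is
    ``base / (base + dropout)``.
    """
    if not (0.0 <= base <= 1.0 and 0.0 <= dropout <= 1.0 and base + dropout <= 1.0):
        raise ValueError(f"invalid probabilities: base={base}, dropout={dropout}")
    if years < 0:
        raise ValueError(f"years={years} must be >= 0")
    if base == 0.0:
        return 0.0
    absorbed = 1.0 - (1.0 - base - dropout) ** years
    return base / (base + dropout) * absorbed


def binomial_se(p: float, n: int) -> float:
    """Standard error of a binomial fraction, sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError(f"n={n} must be >= 1")
    return sqrt(p * (1.0 - p) / n)


# ---------------------------------------------------------------------------
# Enumeration


def _factor_state_distribution(config: SimulationConfig, benefit: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint distribution of (multiplier product, modified count).

    Iterates the product measure factor by factor.  Per modifiable
    factor the states are: absent (weight 1-prev, multiplier 1);
    present-modified (prev*eff, 1-benefit*rrr) and present-unmodified
    (prev*(1-eff), 1) in bernoulli mode, collapsing to a single present
    state (prev, 1-benefit*rrr*eff) in scaled mode.  Non-modifiable
    factors never change the multiplier and are skipped.
    """
    mode = config.mode
    mults = np.array([1.0])
    weights = np.array([1.0])
    counts = np.array([0])
    for factor in config.table.modifiable:
        prev, rrr, eff = factor.prevalence, factor.rrr, factor.effectiveness
        if mode is ModificationMode.SCALED:
            branch_w = np.array([1.0 - prev, prev])
            branch_m = np.array([1.0, 1.0 - benefit * rrr * eff])
            branch_c = np.array([0, 1])
        else:
            branch_w = np.array([1.0 - prev, prev * eff, prev * (1.0 - eff)])
            branch_m = np.array([1.0, 1.0 - benefit * rrr, 1.0])
            branch_c = np.array([0, 1, 0])
        if len(weights) * len(branch_w) > MAX_STATES:
            raise StateSpaceError(
                "profile space too large to enumerate exactly; "
                "use the Monte Carlo engine instead"
            )
        weights = np.outer(weights, branch_w).ravel()
        mults = np.outer(mults, branch_m).ravel()
        counts = (counts[:, None] + branch_c[None, :]).ravel()
    return mults, weights, counts


def hazard_mixture(config: SimulationConfig) -> pd.DataFrame:
    """Exact distribution of per-patient annual hazards.

    Returns one row per (adherence tier, factor state) with columns
    ``tier, n_modified, multiplier, hazard, weight``; weights sum to 1.
    The combined multiplier is floored at ``1 - max_total_reduction``
    exactly as in the engine.
    """
    params = config.params
    frames = []
    cached = None
    for tier in AdherenceTier:
        benefit = params.tier_benefit(tier) if params.gate_factors_by_adherence else 1.0
        if params.gate_factors_by_adherence or cached is None:
            cached = _factor_state_distribution(config, benefit)
        mults, weights, counts = cached
        combined = np.maximum(
            adherence_multiplier(tier, params) * mults,
            1.0 - params.max_total_reduction,
        )
        frames.append(
            pd.DataFrame(
                {
                    "tier": tier.value,
                    "n_modified": counts,
                    "multiplier": combined,
                    "hazard": params.baseline_annual_risk * combined,
                    "weight": params.tier_probability(tier) * weights,
                }
            )
        )
    mixture = pd.concat(frames, ignore_index=True)
    total = mixture["weight"].sum()
    if abs(total - 1.0) > 1e-12:
        raise AssertionError(f"mixture weights sum to {total}, not 1")
    return mixture


def _evolve(hazards: np.ndarray, weights: np.ndarray, dropout: float, years: int) -> ExpectedTrajectory:
    """Closed-form evolution of each weighted chain, then the mixture."""
    h = np.asarray(hazards, dtype=float)
    w = np.asarray(weights, dtype=float)
    t = np.arange(1, years + 1)
    exit_rate = h + dropout
    surv = (1.0 - exit_rate[:, None]) ** t[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        mci_share = np.where(exit_rate > 0.0, h / np.where(exit_rate > 0, exit_rate, 1.0), 0.0)
    absorbed = 1.0 - surv
    mci = mci_share[:, None] * absorbed
    dropped = absorbed - mci
    return ExpectedTrajectory(
        stable=w @ surv,
        mci=w @ mci,
        dropped=w @ dropped,
    )


def enumerate_expected_outcomes(config: SimulationConfig) -> ExpectedTrajectory:
    """Exact expected cumulative trajectory for a configuration.

    Scaled and bernoulli modes yield identical expectations to floating
    precision at the year-1 hazard level (per factor,
    ``eff*(1-rrr) + (1-eff) = 1 - rrr*eff``); over multiple years they
    differ only through the convexity of the survival curve across the
    success mixture, which the enumeration captures exactly per mode.
    """
    mixture = hazard_mixture(config)
    return _evolve(
        mixture["hazard"].to_numpy(),
        mixture["weight"].to_numpy(),
        config.dropout_rate,
        config.years,
    )


def stratified_expected_progression(
    config: SimulationConfig,
    bins: tuple[int, ...] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Exact conditional progression by (tier, modified-count bin).

    ``bins`` gives lower bin edges; the last bin is open-ended (default
    0, 1, 2, 3+).  Returns columns ``tier, modified_bin, weight,
    progression`` where ``progression`` is the expected cumulative MCI
    fraction at the horizon *conditional* on the stratum and ``weight``
    the stratum probability.
    """
    mixture = hazard_mixture(config)
    t = config.years
    d = config.dropout_rate
    h = mixture["hazard"].to_numpy()
    exit_rate = h + d
    with np.errstate(invalid="ignore", divide="ignore"):
        mci_t = np.where(
            exit_rate > 0.0,
            h / np.where(exit_rate > 0, exit_rate, 1.0) * (1.0 - (1.0 - exit_rate) ** t),
            0.0,
        )
    mixture = mixture.assign(progression=mci_t)
    edges = list(bins)
    labels = [
        (f"{lo}" if hi - lo == 1 else f"{lo}-{hi - 1}")
        for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f"{edges[-1]}+"]

    def _bin(count: int) -> str:
        for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
            if lo <= count < hi:
                return lab
        return labels[-1]

    mixture["modified_bin"] = mixture["n_modified"].map(_bin)
    grouped = mixture.groupby(["tier", "modified_bin"], sort=False)
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "weight": g["weight"].sum(),
                "progression": float(np.average(g["progression"], weights=g["weight"])),
            }
        ),
        include_groups=False,
    ).reset_index()
    return out
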