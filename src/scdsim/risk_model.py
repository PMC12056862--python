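"""Risk-factor parameters and hazard algebra.

The intervention model is multiplicative on the annual hazard of
progression from subjective cognitive decline (SCD) to mild cognitive
impairment (MCI).  A digital therapeutic confers a relative risk
reduction (RRR) scaled by the patient's adherence tier, and each present
*modifiable* risk factor contributes a further multiplier.  Two
bookkeeping modes are supported:

* ``scaled`` — every present modifiable factor contributes the
  deterministic multiplier ``1 - rrr * effectiveness`` (the literal
  reading of "reduced by a factor equal to (1 - RRR x effectiveness)").
* ``bernoulli`` — modification of each present modifiable factor
  succeeds with probability ``effectiveness``; a success contributes
  ``1 - rrr``, a failure contributes 1.  In expectation the two modes
  are identical per factor: ``eff*(1-rrr) + (1-eff) = 1 - rrr*eff``.

Non-modifiable factors (low education, traumatic brain injury) carry an
RRR for documentation only; they never change the hazard and stay in
patient profiles purely for reporting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

__all__ = [
    "AdherenceTier",
    "ModificationMode",
    "RiskFactor",
    "RiskFactorTable",
    "InterventionParams",
    "TableValidationError",
    "load_risk_table",
    "default_risk_table",
    "adherence_multiplier",
    "factor_multiplier",
    "combined_multiplier",
    "effective_annual_hazard",
    "factor_contribution_table",
]

RISK_TABLE_COLUMNS = ("name", "prevalence", "rrr", "modifiable", "effectiveness")


class TableValidationError(ValueError):
    """Raised when a risk-factor table fails validation."""


class ModificationMode(str, enum.Enum):
    """How risk-factor modification enters the hazard (see module docs)."""

    SCALED = "scaled"
    BERNOULLI = "bernoulli"


class AdherenceTier(str, enum.Enum):
    """Engagement level with the digital therapeutic."""

    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


_TIER_ORDER = (AdherenceTier.FULL, AdherenceTier.PARTIAL, AdherenceTier.NONE)


@dataclass(frozen=True)
class RiskFactor:
    """One dementia risk factor with its modelling parameters.

    Parameters
    ----------
    name : str
        Unique label within a table.
    prevalence : float
        Carriage probability in the cohort, in [0, 1].
    rrr : float
        Relative risk reduction attainable by modifying the factor,
        in [0, 1].  For non-modifiable factors this is documentation
        only and never enters the hazard.
    modifiable : bool
        Whether the digital therapeutic can act on the factor.
    effectiveness : float or None
        Probability (bernoulli mode) or fraction (scaled mode) with
        which the RRR is realised.  ``None`` for non-modifiable factors.
    """

    name: str
    prevalence: float
    rrr: float
    modifiable: bool
    effectiveness: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise TableValidationError("risk factor name must be non-empty")
        for fld in ("prevalence", "rrr"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                raise TableValidationError(
                    f"{self.name}: {fld}={v!r} outside [0, 1]"
                )
        if self.modifiable:
            if self.effectiveness is None:
                raise TableValidationError(
                    f"{self.name}: modifiable factor requires an effectiveness"
                )
            if not (0.0 <= self.effectiveness <= 1.0):
                raise TableValidationError(
                    f"{self.name}: effectiveness={self.effectiveness!r} outside [0, 1]"
                )
        elif self.effectiveness is not None:
            # effectiveness is meaningless without modifiability; drop it
            object.__setattr__(self, "effectiveness", None)


@dataclass(frozen=True)
class RiskFactorTable:
    """Ordered, validated collection of :class:`RiskFactor` rows."""

    factors: tuple[RiskFactor, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise TableValidationError("risk-factor table must be non-empty")
        names = [f.name for f in self.factors]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TableValidationError(f"duplicate factor names: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def __getitem__(self, name: str) -> RiskFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def modifiable(self) -> tuple[RiskFactor, ...]:
        return tuple(f for f in self.factors if f.modifiable)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": f.name,
                    "prevalence": f.prevalence,
                    "rrr": f.rrr,
                    "modifiable": f.modifiable,
                    "effectiveness": f.effectiveness,
                }
                for f in self.factors
            ]
        )


@dataclass(frozen=True)
class InterventionParams:
    """Scalar parameters of the intervention model.

    Defaults follow the published model: 10% baseline annual hazard of
    SCD-to-MCI progression, a 30% relative risk reduction from the
    digital therapeutic, an adherence mix of 70/20/10% (full / partial /
    none) receiving 100/50/0% of that benefit, and a cap limiting the
    total relative reduction to 80% (a floor of 0.20 on the combined
    hazard multiplier; provably non-binding under the default table).
    ``gate_factors_by_adherence`` is an exploratory switch that scales
    the per-factor effects by the tier's benefit fraction; by default
    only the therapeutic's own RRR is adherence-modulated.
    """

    baseline_annual_risk: float = 0.10
    pdt_rrr: float = 0.30
    adherence_mix: tuple[float, float, float] = (0.70, 0.20, 0.10)
    adherence_benefit: tuple[float, float, float] = (1.0, 0.5, 0.0)
    max_total_reduction: float = 0.80
    gate_factors_by_adherence: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_annual_risk < 1.0):
            raise ValueError(
                f"baseline_annual_risk={self.baseline_annual_risk} outside (0, 1)"
            )
        if not (0.0 <= self.pdt_rrr <= 1.0):
            raise ValueError(f"pdt_rrr={self.pdt_rrr} outside [0, 1]")
        if len(self.adherence_mix) != 3 or len(self.adherence_benefit) != 3:
            raise ValueError("adherence_mix and adherence_benefit need 3 entries")
        for p in (*self.adherence_mix, *self.adherence_benefit):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"adherence probability {p} outside [0, 1]")
        if abs(sum(self.adherence_mix) - 1.0) > 1e-12:
            raise ValueError(
                f"adherence_mix must sum to 1 (got {sum(self.adherence_mix)})"
            )
        if not (0.0 < self.max_total_reduction <= 1.0):
            raise ValueError(
                f"max_total_reduction={self.max_total_reduction} outside (0, 1]"
            )

    def tier_probability(self, tier: AdherenceTier) -> float:
        return self.adherence_mix[_TIER_ORDER.index(AdherenceTier(tier))]

    def tier_benefit(self, tier: AdherenceTier) -> float:
        return self.adherence_benefit[_TIER_ORDER.index(AdherenceTier(tier))]


# ---------------------------------------------------------------------------
# Table loading


def _parse_fraction(value, *, row: str, field_name: str) -> Optional[float]:
    """Parse '30%', '0.3' or 0.3 into a fraction; N/A-like values -> None."""
    if value is None:
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "" or s.upper() in {"N/A", "NA", "NONE", "-"}:
            return None
        try:
            frac = float(s[:-1]) / 100.0 if s.endswith("%") else float(s)
        except ValueError as exc:
            raise TableValidationError(
                f"row {row!r}, field {field_name!r}: cannot parse {value!r}"
            ) from exc
    else:
        frac = float(value)
        if math.isnan(frac):
            return None
    if not (0.0 <= frac <= 1.0):
        raise TableValidationError(
            f"row {row!r}, field {field_name!r}: {value!r} outside [0, 1]"
        )
    return frac


def _parse_bool(value, *, row: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"yes", "true", "1", "y"}:
        return True
    if s in {"no", "false", "0", "n"}:
        return False
    raise TableValidationError(f"row {row!r}, field 'modifiable': cannot parse {value!r}")


def load_risk_table(
    rows: Union[str, Path, pd.DataFrame, Iterable[Mapping]],
) -> RiskFactorTable:
    """Build a validated :class:`RiskFactorTable`.

    ``rows`` may be a TSV/CSV path, a DataFrame, or an iterable of
    mappings; in each case the five columns ``name, prevalence, rrr,
    modifiable, effectiveness`` are required.  Percentages are accepted
    both as strings like ``"30%"`` and as fractions like ``0.30``.
    """
    if isinstance(rows, (str, Path)):
        df = pd.read_csv(rows, sep=None, engine="python", dtype=str)
    elif isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows))
        if df.empty:
            raise TableValidationError("risk-factor table must be non-empty")

    missing = [c for c in RISK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing column(s): {missing}")

    factors = []
    for _, rec in df.iterrows():
        name = str(rec["name"]).strip()
        modifiable = _parse_bool(rec["modifiable"], row=name)
        factors.append(
            RiskFactor(
                name=name,
                prevalence=_parse_fraction(rec["prevalence"], row=name, field_name="prevalence"),
                rrr=_parse_fraction(rec["rrr"], row=name, field_name="rrr"),
                modifiable=modifiable,
                effectiveness=_parse_fraction(
                    rec["effectiveness"], row=name, field_name="effectiveness"
                ),
            )
        )
    return RiskFactorTable(tuple(factors))


def default_risk_table() -> RiskFactorTable:
    """The packaged 12-factor parameter table (2024 Lancet Commission set).

    The Commission's 2024 update names 14 factors; parameters are
    published for 12 of them (the two newest additions, high LDL
    cholesterol and untreated vision loss, lack printed parameters).
    Users can append rows to a copy of the packaged file to extend it.
    """
    with resources.as_file(
        resources.files("scdsim.data").joinpath("risk_factors.tsv")
    ) as path:
        return load_risk_table(path)


# ---------------------------------------------------------------------------
# Hazard algebra


def adherence_multiplier(tier: AdherenceTier, params: InterventionParams) -> float:
    """Hazard multiplier from the therapeutic itself: 1 - RRR * benefit(tier)."""
    return 1.0 - params.pdt_rrr * params.tier_benefit(tier)


def factor_multiplier(
    factor: RiskFactor,
    mode: ModificationMode,
    success: Optional[bool] = None,
    benefit: float = 1.0,
) -> float:
    """Hazard multiplier contributed by one *present* risk factor.

    Non-modifiable factors contribute 1 in every mode.  ``benefit``
    scales the effect (used only when factor effects are gated by
    adherence); ``success`` is the per-patient modification draw and is
    consulted only in bernoulli mode.
    """
    if not factor.modifiable:
        return 1.0
    mode = ModificationMode(mode)
    if mode is ModificationMode.SCALED:
        return 1.0 - benefit * factor.rrr * factor.effectiveness
    return 1.0 - benefit * factor.rrr if success else 1.0


def combined_multiplier(
    profile: "PatientProfile",
    table: RiskFactorTable,
    params: InterventionParams,
    mode: ModificationMode,
) -> float:
    """Capped product of the adherence and per-factor multipliers.

    The combined relative reduction is capped at
    ``params.max_total_reduction``, i.e. the multiplier is floored at
    ``1 - max_total_reduction``.
    """
    unknown = set(profile.factors_present) - set(table.names)
    if unknown:
        raise KeyError(f"profile contains unknown factor(s): {sorted(unknown)}")
    benefit = params.tier_benefit(profile.adherence_tier) if params.gate_factors_by_adherence else 1.0
    mult = adherence_multiplier(profile.adherence_tier, params)
    for name in table.names:  # table order keeps the product deterministic
        if name not in profile.factors_present:
            continue
        factor = table[name]
        mult *= factor_multiplier(
            factor, mode, success=profile.modification_success.get(name), benefit=benefit
        )
    return max(mult, 1.0 - params.max_total_reduction)


def effective_annual_hazard(
    profile: "PatientProfile",
    table: RiskFactorTable,
    params: InterventionParams,
    mode: ModificationMode,
) -> float:
    """Annual SCD-to-MCI progression probability for one patient."""
    return params.baseline_annual_risk * combined_multiplier(profile, table, params, mode)


def factor_contribution_table(table: RiskFactorTable) -> pd.DataFrame:
    """Per-factor effective risk-reduction contribution, rrr * effectiveness.

    Modifiable factors are sorted by descending contribution;
    non-modifiable factors follow with contribution 0 and are flagged by
    the ``modifiable`` column.
    """
    rows = []
    for f in table:
        contribution = f.rrr * f.effectiveness if f.modifiable else 0.0
        rows.append(
            {
                "name": f.name,
                "rrr": f.rrr,
                "effectiveness": f.effectiveness if f.modifiable else float("nan"),
                "contribution": contribution,
                "modifiable": f.modifiable,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["modifiable", "contribution", "name"], ascending=[False, False, True]
    ).reset_index(drop=True)
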