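"""Hazard algebra and risk-table validation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scdsim import (
    AdherenceTier,
    InterventionParams,
    ModificationMode,
    PatientProfile,
    RiskFactor,
    RiskFactorTable,
    TableValidationError,
    adherence_multiplier,
    combined_multiplier,
    effective_annual_hazard,
    factor_contribution_table,
    factor_multiplier,
    load_risk_table,
)

from conftest import PUBLISHED_ROWS


def _profile(factors, tier=AdherenceTier.FULL, success=None):
    success = success if success is not None else {}
    return PatientProfile(
        factors_present=frozenset(factors),
        modification_success=success,
        adherence_tier=tier,
    )


class TestLoadRiskTable:
    def test_percent_strings_parse_to_fractions(self):
        tbl = load_risk_table(
            [
                {"name": "Hearing loss", "prevalence": "30%", "rrr": "8%",
                 "modifiable": "Yes", "effectiveness": "50%"},
            ]
        )
        f = tbl["Hearing loss"]
        assert (f.prevalence, f.rrr, f.effectiveness) == (0.30, 0.08, 0.50)
        assert f.modifiable

    def test_non_modifiable_row_drops_effectiveness(self):
        tbl = load_risk_table(
            [{"name": "Low education", "prevalence": "20%", "rrr": "7%",
              "modifiable": "No", "effectiveness": "N/A"}]
        )
        f = tbl["Low education"]
        assert not f.modifiable and f.effectiveness is None

    def test_packaged_default_matches_published_parameters(self, table):
        assert len(table) == 12
        for name, prev, rrr, modifiable, eff in PUBLISHED_ROWS:
            f = table[name]
            assert f.prevalence == pytest.approx(prev)
            assert f.rrr == pytest.approx(rrr)
            assert f.modifiable is modifiable
            if modifiable:
                assert f.effectiveness == pytest.approx(eff)
            else:
                assert f.effectiveness is None

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([], "non-empty"),
            ([{"name": "x", "prevalence": "30%"}], "missing column"),
            (
                [{"name": "x", "prevalence": "150%", "rrr": "5%",
                  "modifiable": "Yes", "effectiveness": "50%"}],
                "outside",
            ),
            (
                [{"name": "x", "prevalence": "10%", "rrr": "5%",
                  "modifiable": "Yes", "effectiveness": "50%"}] * 2,
                "duplicate",
            ),
        ],
    )
    def test_validation_errors(self, rows, match):
        with pytest.raises(TableValidationError, match=match):
            load_risk_table(rows)

    def test_roundtrip_through_file(self, table, tmp_path):
        path = tmp_path / "table.csv"
        table.to_dataframe().to_csv(path, index=False)
        assert load_risk_table(path) == table


class TestAdherenceMultiplier:
    @pytest.mark.parametrize(
        "tier, expected",
        [(AdherenceTier.FULL, 0.70), (AdherenceTier.PARTIAL, 0.85), (AdherenceTier.NONE, 1.0)],
    )
    def test_default_tiers(self, tier, expected, params):
        assert adherence_multiplier(tier, params) == pytest.approx(expected)

    def test_unknown_tier_rejected(self, params):
        with pytest.raises(ValueError):
            adherence_multiplier("sometimes", params)


class TestFactorMultiplier:
    def test_scaled_mode_uses_fractional_effect(self, table):
        assert factor_multiplier(
            table["Hearing loss"], ModificationMode.SCALED
        ) == pytest.approx(0.96)

    def test_non_modifiable_always_neutral(self, table):
        for mode in ModificationMode:
            assert factor_multiplier(table["Low education"], mode, success=True) == 1.0

    def test_bernoulli_success_gets_full_rrr(self, table):
        f = table["Social isolation"]
        assert factor_multiplier(f, ModificationMode.BERNOULLI, success=True) == pytest.approx(0.96)
        assert factor_multiplier(f, ModificationMode.BERNOULLI, success=False) == 1.0

    @given(
        rrr=st.floats(0, 1),
        eff=st.floats(0, 1),
        success=st.booleans(),
        mode=st.sampled_from(list(ModificationMode)),
    )
    @settings(max_examples=200, deadline=None)
    def test_multiplier_bounded_by_full_rrr(self, rrr, eff, success, mode):
        f = RiskFactor("x", prevalence=0.5, rrr=rrr, modifiable=True, effectiveness=eff)
        m = factor_multiplier(f, mode, success=success)
        assert 1.0 - rrr - 1e-12 <= m <= 1.0 + 1e-12

    @given(rrr=st.floats(0, 1), eff=st.floats(0.001, 1))
    @settings(max_examples=100, deadline=None)
    def test_per_factor_expectation_equivalence(self, rrr, eff):
        """eff*(1-rrr) + (1-eff) == 1 - rrr*eff, the mode-equivalence identity."""
        f = RiskFactor("x", prevalence=0.5, rrr=rrr, modifiable=True, effectiveness=eff)
        scaled = factor_multiplier(f, ModificationMode.SCALED)
        bern = eff * factor_multiplier(f, ModificationMode.BERNOULLI, success=True) + (
            1 - eff
        ) * factor_multiplier(f, ModificationMode.BERNOULLI, success=False)
        assert bern == pytest.approx(scaled, abs=1e-12)

    def test_zero_effectiveness_equals_non_modifiable(self):
        inert = RiskFactor("x", prevalence=0.5, rrr=0.3, modifiable=True, effectiveness=0.0)
        fixed = RiskFactor("x", prevalence=0.5, rrr=0.3, modifiable=False)
        assert factor_multiplier(inert, ModificationMode.SCALED) == factor_multiplier(
            fixed, ModificationMode.SCALED
        ) == 1.0
        # with effectiveness 0 the success draw can never succeed, so the
        # only reachable bernoulli state also contributes 1
        assert factor_multiplier(
            inert, ModificationMode.BERNOULLI, success=False
        ) == factor_multiplier(fixed, ModificationMode.BERNOULLI, success=False) == 1.0


class TestCombinedMultiplier:
    def test_hand_product_two_factors(self, table, params):
        profile = _profile({"Hearing loss", "Physical inactivity"})
        m = combined_multiplier(profile, table, params, ModificationMode.SCALED)
        assert m == pytest.approx(0.70 * 0.96 * 0.985)  # 0.66192

    def test_no_factors_no_adherence_is_neutral(self, table, params):
        profile = _profile(set(), tier=AdherenceTier.NONE)
        assert combined_multiplier(profile, table, params, ModificationMode.SCALED) == 1.0

    def test_cap_floors_extreme_products(self, params):
        strong = RiskFactorTable(
            tuple(
                RiskFactor(f"f{i}", prevalence=1.0, rrr=0.9, modifiable=True, effectiveness=1.0)
                for i in range(3)
            )
        )
        profile = _profile({"f0", "f1", "f2"})
        m = combined_multiplier(profile, strong, params, ModificationMode.SCALED)
        assert m == pytest.approx(1.0 - params.max_total_reduction)  # 0.20 floor

    def test_unknown_factor_rejected(self, table, params):
        with pytest.raises(KeyError):
            combined_multiplier(_profile({"Bad sleep"}), table, params, ModificationMode.SCALED)

    def test_monotone_in_effectiveness_and_benefit(self):
        def multiplier(eff, benefit):
            tbl = RiskFactorTable(
                (RiskFactor("f", prevalence=1.0, rrr=0.4, modifiable=True, effectiveness=eff),)
            )
            p = InterventionParams(adherence_benefit=(benefit, 0.5, 0.0))
            return combined_multiplier(
                _profile({"f"}), tbl, p, ModificationMode.SCALED
            )

        effs = [0.0, 0.3, 0.7, 1.0]
        assert all(
            multiplier(a, 1.0) >= multiplier(b, 1.0) for a, b in zip(effs, effs[1:])
        )
        benefits = [0.0, 0.5, 1.0]
        assert all(
            multiplier(0.5, a) >= multiplier(0.5, b) for a, b in zip(benefits, benefits[1:])
        )

    def test_default_cap_never_binds(self, table, params):
        """Even all-success full adherence stays above the 0.20 floor."""
        worst = 1.0 - params.pdt_rrr
        for f in table.modifiable:
            worst *= 1.0 - f.rrr  # bernoulli all-success is the extreme case
        assert worst > 1.0 - params.max_total_reduction
        profile = _profile(
            set(table.names),
            success={f.name: True for f in table.modifiable},
        )
        m = combined_multiplier(profile, table, params, ModificationMode.BERNOULLI)
        assert m == pytest.approx(worst) and m > 0.20


class TestEffectiveAnnualHazard:
    @pytest.mark.parametrize(
        "tier, factors, expected",
        [
            (AdherenceTier.FULL, set(), 0.07),
            (AdherenceTier.PARTIAL, set(), 0.085),
            (AdherenceTier.FULL, {"Hearing loss"}, 0.0672),
        ],
    )
    def test_known_hazards(self, table, params, tier, factors, expected):
        profile = _profile(factors, tier=tier)
        h = effective_annual_hazard(profile, table, params, ModificationMode.SCALED)
        assert h == pytest.approx(expected)


class TestContributionTable:
    def test_contributions_and_ordering(self, table):
        df = factor_contribution_table(table)
        contrib = df.set_index("name")["contribution"]
        assert contrib["Hearing loss"] == pytest.approx(0.040)
        assert contrib["Social isolation"] == pytest.approx(0.024)
        assert contrib["Low education"] == 0.0
        assert not df.loc[df["name"] == "Low education", "modifiable"].iloc[0]
        mod = df[df["modifiable"]]
        assert list(mod["contribution"]) == sorted(mod["contribution"], reverse=True)
        # non-modifiable rows sort after all modifiable ones
        assert list(df["modifiable"]) == sorted(df["modifiable"], reverse=True)
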