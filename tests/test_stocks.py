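"""Quota-prioritization suite: PSA, Froese indicators, SEASALT, screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corridorplan import fixtures as fx
from corridorplan.stocks import (
    FroeseResult,
    LengthSample,
    PsaAttribute,
    StockToolError,
    derive_l_opt,
    feasibility_screen,
    froese_indicators,
    froese_status,
    psa_axis_score,
    psa_score,
    quota_priority_table,
    seasalt_evaluate,
    vulnerability,
)


class TestFeasibilityScreen:
    def test_multispecific_fishery_excluded(self):
        v = feasibility_screen({"species_id": "flatfish", "multispecies": True})
        assert not v.include
        assert "multispecies fishery" in v.reasons

    def test_long_lived_late_maturing_excluded(self):
        v = feasibility_screen({"species_id": "gulf_coney", "max_age": 28, "age_first_maturity": 7})
        assert not v.include
        assert "long life history / late maturity" in v.reasons

    def test_sedentary_short_lived_included_with_note(self):
        v = feasibility_screen({
            "species_id": "pink_murex_snail", "max_age": 5,
            "age_first_maturity": 3, "movement": "sedentary",
        })
        assert v.include
        assert any("sedentary" in n for n in v.notes)

    def test_all_fields_missing_is_indeterminate(self):
        v = feasibility_screen({"species_id": "ghost"})
        assert v.indeterminate and not v.include

    def test_bundled_life_history_excludes_exactly_flatfish_and_coney(self):
        verdicts = [feasibility_screen(r) for r in fx.life_history_table().to_dict("records")]
        excluded = {v.species_id for v in verdicts if not v.include}
        assert excluded == {"flatfish", "gulf_coney"}


class TestPsa:
    def test_uniform_weights_give_plain_mean(self):
        attrs = [PsaAttribute(f"a{i}", "productivity", s, 2) for i, s in enumerate((1, 2, 3))]
        assert psa_axis_score(attrs) == pytest.approx(2.0)

    def test_single_attribute_identity(self):
        assert psa_axis_score([PsaAttribute("a", "susceptibility", 3, 4)]) == 3.0

    def test_zero_weight_removes_attribute(self):
        attrs = [PsaAttribute("a", "productivity", 1, 4), PsaAttribute("b", "productivity", 3, 0)]
        assert psa_axis_score(attrs) == 1.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(StockToolError):
            psa_axis_score([PsaAttribute("a", "productivity", 2, 0)])

    @pytest.mark.parametrize("p,s,v", [
        (3, 1, 0.0), (1, 3, math.sqrt(8)), (2, 2, math.sqrt(2)),
    ])
    def test_vulnerability_closed_forms(self, p, s, v):
        assert vulnerability(p, s) == pytest.approx(v)

    def test_vulnerability_domain_checked(self):
        with pytest.raises(StockToolError):
            vulnerability(0.5, 2)

    @given(st.floats(1, 3), st.floats(1, 3), st.floats(0, 2), st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_vulnerability_monotone(self, p, s, dp, ds):
        # non-increasing in productivity, non-decreasing in susceptibility
        assert vulnerability(min(p + dp, 3), s) <= vulnerability(p, s) + 1e-12
        assert vulnerability(p, min(s + ds, 3)) >= vulnerability(p, s) - 1e-12

    @given(
        st.lists(st.tuples(st.integers(1, 3), st.integers(1, 4)), min_size=1, max_size=8),
        st.integers(1, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_axis_score_bounds_and_weight_rescaling(self, pairs, scale):
        attrs = [PsaAttribute(f"a{i}", "productivity", s, w) for i, (s, w) in enumerate(pairs)]
        score = psa_axis_score(attrs)
        scores = [a.score for a in attrs]
        assert min(scores) - 1e-9 <= score <= max(scores) + 1e-9
        # uniform weight rescaling leaves the axis score unchanged
        rescaled = [
            PsaAttribute(a.name, a.axis, a.score, min(a.weight * scale, 4))
            for a in attrs
        ]
        if all(a.weight * scale <= 4 for a in attrs):
            assert psa_axis_score(rescaled) == pytest.approx(score)

    def test_full_psa_reports_mean_data_quality(self):
        attrs = [
            PsaAttribute("a", "productivity", 3, 2, data_quality=1),
            PsaAttribute("b", "susceptibility", 1, 2, data_quality=3),
        ]
        res = psa_score(attrs)
        assert res.vulnerability == pytest.approx(0.0)
        assert res.mean_data_quality == pytest.approx(2.0)


class TestFroese:
    def test_all_mature_sample(self):
        s = LengthSample("x", np.array([20.0, 25.0, 30.0]), l_mat=15, l_opt=22, l_max=40)
        assert froese_indicators(s).pct_mature == 100.0

    def test_hand_counted_bands(self):
        s = LengthSample("x", np.array([8.0, 10.0, 11.0, 13.0]), l_mat=7, l_opt=10, l_max=20)
        r = froese_indicators(s)
        assert r.pct_optimal == 50.0  # 10 and 11 within +/-10% of 10
        assert r.pct_megaspawners == 25.0  # 13 above the band

    @pytest.mark.parametrize("n,flag", [(28, "insufficient"), (100, "low_n"), (400, "ok")])
    def test_reliability_flags(self, n, flag):
        s = fx.make_length_sample("x", 10, 15, 30, n=n, seed=1)
        assert froese_indicators(s).reliability_flag == flag

    def test_empty_sample_rejected(self):
        s = LengthSample("x", np.array([]), l_mat=10, l_opt=15, l_max=30)
        with pytest.raises(StockToolError):
            froese_indicators(s)

    def test_bands_partition_the_sample(self):
        s = fx.make_length_sample("x", 10, 15, 30, n=500, seed=3)
        r = froese_indicators(s)
        below = 100.0 * np.count_nonzero(s.lengths < 0.9 * s.l_opt) / s.lengths.size
        assert below + r.pct_optimal + r.pct_megaspawners == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_per_fish_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 600))
        s = fx.make_length_sample("x", 12, 20, 45, n=n, seed=seed + 1000,
                                  mean=float(rng.uniform(10, 40)), sd=float(rng.uniform(2, 12)))
        r = froese_indicators(s)
        mature = optimal = mega = 0
        for length in s.lengths.tolist():
            if length >= s.l_mat:
                mature += 1
            if 0.9 * s.l_opt <= length <= 1.1 * s.l_opt:
                optimal += 1
            elif length > 1.1 * s.l_opt:
                mega += 1
        assert r.pct_mature == pytest.approx(100 * mature / n)
        assert r.pct_optimal == pytest.approx(100 * optimal / n)
        assert r.pct_megaspawners == pytest.approx(100 * mega / n)

    def test_l_opt_derivation_from_growth_and_mortality(self):
        # L_max * 3/(3 + M/K)
        assert derive_l_opt(100.0, 1.5) == pytest.approx(100 * 3 / 4.5)


class TestFroeseStatus:
    def test_acceptable_mature_fraction(self):
        st_ = froese_status(FroeseResult("x", 95.0, 80.0, 25.0, 500, "ok"))
        assert st_["mature"] == "acceptable"

    def test_megaspawners_below_lower_limit(self):
        st_ = froese_status(FroeseResult("x", 100.0, 100.0, 15.0, 500, "ok"))
        assert st_["megaspawners"] == "below_lower_limit"

    def test_optimal_at_target(self):
        st_ = froese_status(FroeseResult("x", 100.0, 100.0, 0.0, 500, "ok"))
        assert st_["optimal"] == "at_target"
        assert st_["megaspawners"] == "at_harvest_target"

    def test_healthy_age_structure_band(self):
        st_ = froese_status(FroeseResult("x", 100.0, 60.0, 35.0, 500, "ok"))
        assert st_["megaspawners"] == "healthy_age_structure"


class TestSeasalt:
    def test_all_fives(self):
        score = seasalt_evaluate({"Secure": {"c1": (5, 5), "c2": (5, 5)}})
        assert score.state["Secure"] == 5

    def test_rounded_mean_half_down(self):
        score = seasalt_evaluate({"Secure": {"c1": (4, 3), "c2": (3, 3), "c3": (3, 3)}})
        assert score.state["Secure"] == 3  # mean 3.33
        score2 = seasalt_evaluate({"Secure": {"c1": (4, 3), "c2": (3, 3)}})
        assert score2.state["Secure"] == 3  # mean 3.5 rounds down

    def test_indeterminate_excluded_and_flagged(self):
        score = seasalt_evaluate({"Limited": {"c1": (0, 3), "c2": (4, 3)}})
        assert score.state["Limited"] == 4
        assert "c1" in score.indeterminate["Limited"]

    def test_transferability_is_not_applicable(self):
        score = seasalt_evaluate({"Secure": {"c1": (5, 5)}, "Transferability": {}})
        assert score.transferability == "not_applicable"
        assert "Transferability" not in score.state

    def test_no_responses_rejected(self):
        with pytest.raises(StockToolError):
            seasalt_evaluate({"Secure": {}})


class TestQuotaPriorityTable:
    def _species(self, sid, vuln, include=True):
        from corridorplan.stocks import FeasibilityVerdict, PsaResult
        return {
            "feasibility": FeasibilityVerdict(sid, include, [] if include else ["multispecies fishery"]),
            "psa": PsaResult(3 - vuln, 1, vuln, 2.0),
        }

    def test_single_species_ranks_first(self):
        included, _ = quota_priority_table({"a": self._species("a", 1.0)})
        assert included.loc[0, "rank"] == 1

    def test_lower_vulnerability_ranks_first(self):
        included, _ = quota_priority_table({
            "a": self._species("a", 1.0), "b": self._species("b", 2.0),
        })
        assert included["species_id"].tolist() == ["a", "b"]

    def test_excluded_species_listed_separately(self):
        included, excluded = quota_priority_table({
            "a": self._species("a", 1.0),
            "flatfish": self._species("flatfish", 0.5, include=False),
        })
        assert "flatfish" not in included["species_id"].tolist()
        assert excluded["species_id"].tolist() == ["flatfish"]
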