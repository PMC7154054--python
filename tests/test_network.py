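"""Unit and property tests for rate laws, TF activities, and observables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import colicarb as cc
from colicarb.network import (
    REACTIONS,
    FluxVector,
    RegulationMap,
    RegulationEdge,
    TFActivities,
    compute_fluxes,
    compute_tf_activities,
    eiia_phosphorylated_fraction,
    rate_xt,
    rate_xyi,
    rate_xyk,
    regulated_vmax,
    atp_rate,
    growth_rate,
    nadph_rate,
)
from colicarb.params import ParameterError


def _state(**kw):
    return cc.NetworkState(kw)


# ---------------------------------------------------------------------------
# TF activities
# ---------------------------------------------------------------------------


class TestTFActivities:
    def test_override_pins_activity_regardless_of_state(self, params):
        g = cc.Genotype(tf_overrides={"ArcA": 0.95})
        for pep, nadh in [(0.1, 0.01), (5.0, 1.5)]:
            tfs = compute_tf_activities(
                _state(PEP=pep, PYR=1.0, NADH=nadh, NAD=0.5, FBP=1.0), g, params
            )
            assert tfs.arca == 0.95
            assert "ArcA" in tfs.overridden

    def test_cra_vanishes_at_saturating_fbp(self, params, wt):
        tfs = compute_tf_activities(_state(FBP=1e9, PYR=1.0, NAD=1.0), wt, params)
        assert tfs.cra == pytest.approx(0.0, abs=1e-12)

    def test_crp_ordering_follows_pep_pyr_ratio(self, params, wt):
        lo = compute_tf_activities(_state(PEP=0.5, PYR=5.0, NAD=1.0), wt, params)
        hi = compute_tf_activities(_state(PEP=5.0, PYR=0.5, NAD=1.0), wt, params)
        assert hi.crp > lo.crp

    @given(
        pep=st.floats(0.0, 50.0),
        pyr=st.floats(1e-6, 50.0),
        fbp=st.floats(0.0, 50.0),
        nadh=st.floats(0.0, 2.0),
        xylin=st.floats(0.0, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_activities_bounded(self, pep, pyr, fbp, nadh, xylin):
        params = cc.default_parameters()
        tfs = compute_tf_activities(
            _state(PEP=pep, PYR=pyr, FBP=fbp, NADH=nadh, NAD=1.0, XYLIN=xylin),
            cc.Genotype(),
            params,
        )
        for v in (tfs.crp, tfs.cra, tfs.arca, tfs.xylr):
            assert 0.0 <= v <= 1.0

    def test_xylr_monotone_in_intracellular_xylose(self, params, wt):
        acts = [
            compute_tf_activities(_state(XYLIN=x, PYR=1.0, NAD=1.0), wt, params).xylr
            for x in (0.0, 0.05, 0.5, 5.0)
        ]
        assert acts == sorted(acts)
        assert acts[0] == 0.0

    def test_anaerobic_floors_arca(self, params, wt):
        aer = compute_tf_activities(
            _state(NADH=0.05, NAD=1.9, PYR=1.0), wt, params, aerobic=True
        )
        ana = compute_tf_activities(
            _state(NADH=0.05, NAD=1.9, PYR=1.0), wt, params, aerobic=False
        )
        assert ana.arca >= 0.9 > aer.arca

    def test_eiia_fraction_in_unit_interval_and_monotone(self, params):
        fr = [
            eiia_phosphorylated_fraction(_state(PEP=p, PYR=1.0), params)
            for p in (0.0, 0.5, 2.0, 20.0)
        ]
        assert fr == sorted(fr)
        assert all(0.0 <= f <= 1.0 for f in fr)


# ---------------------------------------------------------------------------
# regulated vmax / f(TF)
# ---------------------------------------------------------------------------


class TestRegulatedVmax:
    def test_unregulated_reaction_returns_vmax_exactly(self, params, mid_tfs):
        reg = RegulationMap([])
        assert regulated_vmax("Pgi", mid_tfs, reg, params) == params.vmax("Pgi")

    def test_full_repression_with_unit_span_gives_zero(self, params):
        reg = RegulationMap([RegulationEdge("ArcA", "CS", "-", a=0.0, b=1.0)])
        tfs = TFActivities(crp=0.5, cra=0.5, arca=1.0, xylr=0.5)
        assert regulated_vmax("CS", tfs, reg, params) == 0.0

    def test_two_activator_product_matches_hand_evaluation(self, params):
        reg = RegulationMap(
            [
                RegulationEdge("Crp", "XT", "+", a=0.02, b=0.98),
                RegulationEdge("XylR", "XT", "+", a=0.15, b=0.85),
            ]
        )
        tfs = TFActivities(crp=0.7, cra=0.5, arca=0.2, xylr=0.4)
        expected = params.vmax("XT") * (0.02 + 0.98 * 0.7) * (0.15 + 0.85 * 0.4)
        assert regulated_vmax("XT", tfs, reg, params) == pytest.approx(expected, rel=1e-14)

    def test_unknown_reaction_raises(self, params, regmap, mid_tfs):
        with pytest.raises(KeyError):
            regulated_vmax("NoSuchReaction", mid_tfs, regmap, params)

    @given(lo=st.floats(0.0, 1.0), hi=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_in_each_tf(self, lo, hi):
        """Raising an activator never lowers capacity; symmetric for repressors."""
        params = cc.default_parameters()
        reg = RegulationMap.from_parameters(params)
        lo, hi = min(lo, hi), max(lo, hi)
        for edge in reg.edges:
            base = {"crp": 0.5, "cra": 0.5, "arca": 0.5, "xylr": 0.5}
            key = edge.tf.lower()
            t_lo = TFActivities(**{**base, key: lo})
            t_hi = TFActivities(**{**base, key: hi})
            v_lo = regulated_vmax(edge.target, t_lo, reg, params)
            v_hi = regulated_vmax(edge.target, t_hi, reg, params)
            if edge.sign == "+":
                assert v_hi >= v_lo - 1e-12
            else:
                assert v_hi <= v_lo + 1e-12


# ---------------------------------------------------------------------------
# xylose subsystem rate laws: closed-form limits
# ---------------------------------------------------------------------------


class TestXyloseRateLaws:
    def test_xt_zero_substrate(self, params, regmap, mid_tfs):
        assert rate_xt(_state(XYL=0.0, PYR=1.0), mid_tfs, params, regmap) == 0.0

    def test_xt_saturation_without_inducer_exclusion(self, params, regmap, mid_tfs):
        s = dict(_state(PYR=1.0))
        s["XYL"] = 1e15
        s["EIIA"] = 0.0
        vmax_f = regulated_vmax("XT", mid_tfs, regmap, params)
        assert rate_xt(s, mid_tfs, params, regmap) == pytest.approx(vmax_f, rel=1e-12)

    def test_xt_inducer_exclusion_one_third(self, params, regmap, mid_tfs):
        """[XYL]=K_XYL and [EIIA]=K_I make the denominator 3*K_XYL."""
        s = dict(_state(PYR=1.0))
        s["XYL"] = params.rx("XT", "K_XYL")
        s["EIIA"] = params.rx("XT", "K_I")
        vmax_f = regulated_vmax("XT", mid_tfs, regmap, params)
        assert rate_xt(s, mid_tfs, params, regmap) == pytest.approx(
            vmax_f / 3.0, rel=1e-12
        )

    @pytest.mark.parametrize(
        "xylin,expected_factor",
        [(0.0, 0.0), ("K", 0.5), (1e12, 1.0)],
    )
    def test_xyi_limits(self, params, regmap, mid_tfs, xylin, expected_factor):
        if xylin == "K":
            xylin = params.rx("Xyi", "K_XYLIN")
        vmax_f = regulated_vmax("Xyi", mid_tfs, regmap, params)
        v = rate_xyi(_state(XYLIN=xylin, PYR=1.0), mid_tfs, params, regmap)
        assert v == pytest.approx(vmax_f * expected_factor, rel=1e-12, abs=1e-15)

    def test_xyk_zero_atp(self, params, regmap, mid_tfs):
        assert rate_xyk(_state(XYLU=1.0, ATP=0.0, PYR=1.0), mid_tfs, params, regmap) == 0.0

    def test_xyk_quarter_at_double_half_saturation(self, params, regmap, mid_tfs):
        s = _state(PYR=1.0)
        s["XYLU"] = params.rx("Xyk", "K_XYLU")
        s["ATP"] = params.rx("Xyk", "K_ATP")
        vmax_f = regulated_vmax("Xyk", mid_tfs, regmap, params)
        assert rate_xyk(s, mid_tfs, params, regmap) == pytest.approx(
            vmax_f / 4.0, rel=1e-12
        )

    def test_xyk_saturation(self, params, regmap, mid_tfs):
        s = _state(PYR=1.0)
        s["XYLU"] = 1e9
        s["ATP"] = 1e9
        vmax_f = regulated_vmax("Xyk", mid_tfs, regmap, params)
        assert rate_xyk(s, mid_tfs, params, regmap) == pytest.approx(vmax_f, rel=1e-6)


# ---------------------------------------------------------------------------
# flux vector
# ---------------------------------------------------------------------------


class TestComputeFluxes:
    def test_knockout_zeroes_mapped_reaction(self, params, reference_state):
        for gene, reaction in [("pgi", "Pgi"), ("ptsG", "PTS"), ("ackA", "PTACK"),
                               ("pfl", "Pfl")]:
            v = compute_fluxes(reference_state, cc.Genotype(knockouts={gene}), params)
            assert v[reaction] == 0.0

    def test_empty_cell_carries_no_flux(self, params, wt):
        v = compute_fluxes(cc.NetworkState(), wt, params)
        assert all(abs(val) < 1e-12 for val in v.values())

    def test_fluxes_finite_and_irreversibles_nonnegative(self, params, wt, reference_state):
        v = compute_fluxes(reference_state, wt, params)
        reversible = {"Pgi", "Rpe", "Rpi", "TktA", "TktB", "Tal", "Fum"}
        for name, val in v.items():
            assert math.isfinite(val)
            if name not in reversible:
                assert val >= 0.0

    def test_mva_fluxes_zero_without_pathway(self, params, wt, reference_state):
        v = compute_fluxes(reference_state, wt, params)
        assert v["AtoB"] == v["HMGS"] == v["HMGR"] == 0.0
        g = cc.Genotype(mva_pathway=True)
        v2 = compute_fluxes(reference_state, g, params)
        assert v2["AtoB"] > 0 and v2["HMGS"] > 0 and v2["HMGR"] > 0

    def test_hmgr_requires_nadph(self, params, reference_state):
        g = cc.Genotype(mva_pathway=True)
        s = cc.NetworkState(dict(reference_state))
        s["NADPH"] = 0.0
        assert compute_fluxes(s, g, params)["HMGR"] == 0.0

    def test_flux_vector_matches_independent_rate_law_evaluation(
        self, params, wt, regmap, reference_state
    ):
        """Brute-force oracle: re-evaluate each rate law in isolation."""
        s = reference_state
        tfs = compute_tf_activities(s, wt, params)
        v = compute_fluxes(s, wt, params, tfs=tfs, reg=regmap)

        def f(r):
            return regulated_vmax(r, tfs, regmap, params)

        def mm(c, k):
            return c / (k + c)

        p = params.rx
        rpp = s["PEP"] / s["PYR"]
        expected = {
            "PTS": f("PTS") * mm(s["GLC"], p("PTS", "K_GLC")) * (rpp / (p("PTS", "K_pp") + rpp))
            / (1 + (s["G6P"] / p("PTS", "Ki_G6P")) ** 2),
            "Pgi": f("Pgi") * (s["G6P"] - s["F6P"] / p("Pgi", "Keq"))
            / (p("Pgi", "K_G6P") + s["G6P"] + s["F6P"] * p("Pgi", "K_G6P") / p("Pgi", "K_F6P")),
            "Pfk": f("Pfk") * mm(s["F6P"], p("Pfk", "K_F6P")) * mm(s["ATP"], p("Pfk", "K_ATP"))
            / (1 + s["PEP"] / p("Pfk", "Ki_PEP")),
            "Fba": f("Fba") * mm(s["FBP"], p("Fba", "K_FBP")),
            "L_Emp": f("L_Emp") * mm(s["GAP"], p("L_Emp", "K_GAP"))
            * mm(s["NAD"], p("L_Emp", "K_NAD")) * mm(s["ADP"], p("L_Emp", "K_ADP")),
            "G6PDH": f("G6PDH") * mm(s["G6P"], p("G6PDH", "K_G6P"))
            * mm(s["NADP"], p("G6PDH", "K_NADP"))
            / (1 + (s["NADPH"] / p("G6PDH", "Ki_NADPH")) ** 2),
            "CS": f("CS") * mm(s["ACCOA"], p("CS", "K_ACCOA")) * mm(s["OAA"], p("CS", "K_OAA")),
            "ICDH": f("ICDH") * mm(s["ICIT"], p("ICDH", "K_ICIT"))
            * mm(s["NADP"], p("ICDH", "K_NADP")) / (1 + s["NADPH"] / p("ICDH", "Ki_NADPH")),
            "Mez": f("Mez") * mm(s["MAL"], p("Mez", "K_MAL")) * mm(s["NADP"], p("Mez", "K_NADP")),
            "PTACK": f("PTACK") * mm(s["ACCOA"], p("PTACK", "K_ACCOA"))
            * mm(s["ADP"], p("PTACK", "K_ADP")),
        }
        for name, want in expected.items():
            assert v[name] == pytest.approx(want, rel=1e-12), name


# ---------------------------------------------------------------------------
# scalar observables: signed-sum oracles
# ---------------------------------------------------------------------------


class TestObservables:
    ATP_PLUS = ("OP", "L_Emp", "Pyk", "PTACK", "aKGDH")
    ATP_MINUS = ("Glk", "Pfk", "Pps", "Pck", "Acs", "XT", "Xyk")

    def test_atp_rate_worked_example(self, params):
        v = FluxVector(OP=10, L_Emp=5, Pyk=3, PTACK=2, aKGDH=1, Glk=1, Pfk=2,
                       Pps=0, Pck=0, Acs=0, XT=1, Xyk=1)
        assert atp_rate(v, params) == pytest.approx(16.0)

    def test_atp_rate_zero_fluxes(self, params):
        assert atp_rate(FluxVector(), params) == 0.0

    def test_atp_and_nadph_rates_match_oracle_on_random_fluxes(self, params):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            v = FluxVector({r: rng.uniform(-5, 15) for r in REACTIONS})
            want_atp = sum(v[r] for r in self.ATP_PLUS) - sum(
                v[r] for r in self.ATP_MINUS
            )
            want_nadph = v["G6PDH"] + v["PGDH"] + v["ICDH"] + v["Mez"]
            assert atp_rate(v, params) == pytest.approx(want_atp, rel=1e-12, abs=1e-12)
            assert nadph_rate(v, params) == pytest.approx(want_nadph, rel=1e-12, abs=1e-12)

    def test_nadph_rate_component_sum(self, params):
        v = FluxVector(G6PDH=1, PGDH=2, ICDH=3, Mez=4)
        assert nadph_rate(v, params) == pytest.approx(10.0)

    def test_nadph_first_site_configurable(self, params):
        alt = params.copy()
        alt.data["globals"]["nadph_first_site"]["value"] = "GAPDH"
        v = FluxVector(G6PDH=1, L_Emp=7, PGDH=2, ICDH=3, Mez=4)
        assert nadph_rate(v, params) == pytest.approx(10.0)
        assert nadph_rate(v, alt) == pytest.approx(16.0)

    def test_growth_rate_acetate_inhibition(self, params):
        k_atp = params.g("k_ATP")
        k_ace = params.g("k_ACE")
        assert growth_rate(10.0, 0.0, params) == pytest.approx(k_atp * 10.0)
        assert growth_rate(10.0, k_ace, params) == pytest.approx(k_atp * 5.0)
        assert growth_rate(10.0, 1e12, params) == pytest.approx(0.0, abs=1e-9)
        assert growth_rate(-5.0, 0.0, params) == 0.0  # clamped

    def test_growth_rate_rejects_negative_acetate(self, params):
        with pytest.raises(ValueError):
            growth_rate(1.0, -0.1, params)


class TestGenotype:
    def test_unknown_knockout_rejected(self):
        with pytest.raises(KeyError):
            cc.Genotype(knockouts={"notagene"})

    def test_override_bounds_enforced(self):
        with pytest.raises(ValueError):
            cc.Genotype(tf_overrides={"ArcA": 1.5})

    def test_missing_tf_constant_names_the_tf(self, params, wt):
        broken = params.copy()
        del broken.data["tfs"]["Crp"]["K"]
        with pytest.raises(ParameterError, match="Crp"):
            compute_tf_activities(_state(PYR=1.0, NAD=1.0), wt, broken)
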