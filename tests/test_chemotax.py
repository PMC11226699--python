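import numpy as np
import pytest

from polytax.chemotax import (
    ND,
    ChemProfile,
    api_similarity,
    fame_similarity,
    fit_calibration,
    invert_calibration,
    molar_ratio,
    profile_correlation,
    quinone_pairing,
)
from polytax.fixtures import (
    ND_QUINONE_STRAINS,
    PRINTED_QUINONE_R,
    REFERENCE_STRAIN,
    load_api_profiles,
    load_calibration_params,
    load_quinone_profiles,
)
from polytax.synthetic import child_seed

SLOPE, INTERCEPT = 566488.0, 2302.2


class TestFitCalibration:
    def _noiseless_points(self):
        xs = [7.81, 15.62, 31.25, 62.5, 125.0]
        return [(x, SLOPE * x + INTERCEPT) for x in xs]

    def test_exact_recovery_on_noiseless_points(self):
        curve = fit_calibration(self._noiseless_points())
        assert curve.slope == pytest.approx(SLOPE, abs=1e-6)
        assert curve.intercept == pytest.approx(INTERCEPT, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert (curve.range_low, curve.range_high) == (7.81, 125.0)

    def test_packaged_parameters_agree(self):
        params = load_calibration_params()
        assert params["slope"] == SLOPE
        assert params["intercept"] == INTERCEPT
        assert params["r_squared"] == 0.9962

    def test_loq_lod_ratio_forced(self):
        curve = fit_calibration(self._noiseless_points(), noise_sd=1000.0)
        assert curve.loq / curve.lod == pytest.approx(10.0 / 3.0, abs=1e-12)

    def test_noisy_fit(self):
        rng = child_seed(0, "calib")
        pts = [(x, SLOPE * x + INTERCEPT + rng.normal(0, 5000)) for x in
               np.linspace(7.81, 125, 12)]
        curve = fit_calibration(pts)
        assert curve.r_squared < 1.0
        assert curve.slope == pytest.approx(SLOPE, rel=0.01)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


class TestInvertCalibration:
    CURVE_POINTS = [(x, SLOPE * x + INTERCEPT) for x in (7.81, 31.25, 125.0)]

    def test_y_equals_b_gives_zero(self):
        curve = fit_calibration(self.CURVE_POINTS)
        value, _ = invert_calibration(curve, curve.intercept)
        assert value == 0.0

    def test_forced_arithmetic(self):
        curve = fit_calibration(self.CURVE_POINTS)
        value, extrapolated = invert_calibration(curve, SLOPE * 50 + INTERCEPT)
        assert value == pytest.approx(0.05)  # 50 ng/mL = 0.05 mg/L
        assert not extrapolated

    def test_roundtrip_with_concentration_factor(self):
        # planted 0.4 mg/L, 10-fold concentrated extract: the measured
        # response corresponds to x = 0.4 * 1000 * 10 ng/mL on the curve
        planted_mg_l = 0.4
        factor = 10.0
        clean = fit_calibration(self.CURVE_POINTS)
        value, _ = invert_calibration(
            clean, SLOPE * (planted_mg_l * 1000 * factor) + INTERCEPT,
            concentration_factor=factor,
        )
        assert value == pytest.approx(planted_mg_l, rel=1e-9)

    def test_noisy_roundtrip_within_one_percent(self):
        rng = child_seed(1, "invert")
        curve = fit_calibration(
            [(x, SLOPE * x + INTERCEPT + rng.normal(0, 2000)) for x in
             np.linspace(7.81, 125, 12)]
        )
        planted_ng_ml = 60.0
        value, _ = invert_calibration(curve, SLOPE * planted_ng_ml + INTERCEPT)
        assert value == pytest.approx(planted_ng_ml / 1000.0, rel=0.01)

    def test_below_lod_reported_as_string(self):
        curve = fit_calibration(self.CURVE_POINTS, noise_sd=SLOPE)  # LOD = 3
        value, _ = invert_calibration(curve, SLOPE * 1.0 + INTERCEPT)
        assert value == "<LOD"

    def test_extrapolation_flagged(self):
        curve = fit_calibration(self.CURVE_POINTS)
        _, extrapolated = invert_calibration(curve, SLOPE * 500 + INTERCEPT)
        assert extrapolated


class TestMolarRatio:
    def test_single_detected_component_is_100(self):
        out = molar_ratio({"Q8": 3.5, "DMK8": None, "MK8": None})
        assert out["Q8"] == 100.0
        assert out["DMK8"] == ND and out["MK8"] == ND

    def test_equal_thirds(self):
        out = molar_ratio({"a": 2.0, "b": 2.0, "c": 2.0})
        assert all(v == pytest.approx(100 / 3) for v in out.values())

    def test_two_one_one(self):
        out = molar_ratio({"a": 2.0, "b": 1.0, "c": 1.0})
        assert (out["a"], out["b"], out["c"]) == (50.0, 25.0, 25.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            molar_ratio({"a": 0.0})

    def test_normalized_sums_to_100(self, rng):
        amounts = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 5, 6))}
        out = molar_ratio(amounts)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        profiles = load_quinone_profiles()
        r = profile_correlation(
            profiles[REFERENCE_STRAIN], profiles[REFERENCE_STRAIN], quinone_pairing()
        )
        assert r == pytest.approx(1.0)

    @pytest.mark.parametrize("strain,expected", sorted(PRINTED_QUINONE_R.items()))
    def test_printed_coefficients_reproduced(self, strain, expected):
        profiles = load_quinone_profiles()
        r = profile_correlation(
            profiles[REFERENCE_STRAIN], profiles[strain], quinone_pairing()
        )
        assert round(r, 3) == expected

    @pytest.mark.parametrize("strain", ND_QUINONE_STRAINS)
    def test_nd_profiles_give_nd(self, strain):
        profiles = load_quinone_profiles()
        r = profile_correlation(
            profiles[REFERENCE_STRAIN], profiles[strain], quinone_pairing()
        )
        assert r == ND

    def test_fixture_rows_sum_to_100(self):
        profiles = load_quinone_profiles()
        for strain, prof in profiles.items():
            for cond in prof.conditions():
                vals = [
                    v for (c, _), v in prof.values.items() if c == cond
                ]
                assert sum(vals) == pytest.approx(100.0, abs=0.5), (strain, cond)

    def test_symmetric_and_affine_invariant(self):
        profiles = load_quinone_profiles()
        a = profiles[REFERENCE_STRAIN]
        b = profiles["E_coli_MG1655"]
        pairing = quinone_pairing()
        r_ab = profile_correlation(a, b, pairing)
        r_ba = profile_correlation(b, a, pairing)
        assert r_ab == pytest.approx(r_ba)
        scaled = ChemProfile(
            "scaled", {k: 3.0 * v + 7.0 for k, v in b.values.items()}
        )
        assert profile_correlation(a, scaled, pairing) == pytest.approx(r_ab)
        assert -1.0 <= r_ab <= 1.0

    def test_zero_variance_is_nd(self):
        flat = ChemProfile("flat", {k: 10.0 for k in quinone_pairing()})
        other = load_quinone_profiles()[REFERENCE_STRAIN]
        assert profile_correlation(flat, other, quinone_pairing()) == ND

    def test_needs_three_cells(self):
        a = ChemProfile("a", {("c", "x"): 1.0, ("c", "y"): 2.0})
        with pytest.raises(ValueError):
            profile_correlation(a, a, [("c", "x"), ("c", "y")])


class TestFameSimilarity:
    def _profile(self, name, comps):
        return ChemProfile(name, {("", c): v for c, v in comps.items()})

    def test_identical_composition(self):
        p = self._profile("a", {"C16:0": 30.0, "C18:1": 50.0, "C14:0": 20.0})
        q = self._profile("b", {"C16:0": 30.0, "C18:1": 50.0, "C14:0": 20.0})
        assert fame_similarity(p, q) == pytest.approx(1.0)

    def test_missing_component_treated_as_zero(self):
        p = self._profile("a", {"x": 50.0, "y": 30.0, "z": 20.0})
        q = self._profile("b", {"x": 50.0, "y": 30.0, "w": 20.0})
        r = fame_similarity(p, q)
        # brute-force oracle over the 4-component union with zeros filled in
        va = [50.0, 0.0, 30.0, 20.0]
        vb = [50.0, 20.0, 30.0, 0.0]
        expected = np.corrcoef(va, vb)[0, 1]
        assert r == pytest.approx(expected)

    def test_planted_correlation_recovered(self):
        rng = child_seed(5, "fame")
        base = rng.uniform(5, 40, size=10)
        # noise sd chosen so that corr(base, base+noise) = 0.9:
        # sd_n = sd_b * sqrt(1/0.81 - 1) ~= 0.4843 * sd_b
        rs = []
        for _ in range(30):
            noise = rng.normal(0, base.std() * 0.4843, size=10)
            other = base + noise
            p = self._profile("a", {f"c{i}": float(v) for i, v in enumerate(base)})
            q = self._profile(
                "b", {f"c{i}": float(max(v, 0.01)) for i, v in enumerate(other)}
            )
            rs.append(fame_similarity(p, q))
        assert np.mean(rs) == pytest.approx(0.9, abs=0.05)

    def test_too_few_components(self):
        p = self._profile("a", {"x": 1.0, "y": 2.0})
        with pytest.raises(ValueError):
            fame_similarity(p, p)


class TestApiSimilarity:
    def test_identical_vectors(self):
        v = ["+", "-", "+", "-"]
        assert api_similarity(v, v) == 1.0

    def test_half_matching_of_20(self):
        a = ["+"] * 20
        b = ["+"] * 10 + ["-"] * 10
        assert api_similarity(a, b) == 0.5

    def test_v_and_nd_excluded(self):
        a = ["+", "V", "ND", "-"]
        b = ["+", "-", "+", "ND"]
        assert api_similarity(a, b) == 1.0  # only position 0 compared

    def test_no_comparable_positions(self):
        with pytest.raises(ValueError):
            api_similarity(["V"], ["+"])

    def test_jaccard_alternative(self):
        a = ["+", "+", "-", "-"]
        b = ["+", "-", "+", "-"]
        assert api_similarity(a, b, method="jaccard") == pytest.approx(1 / 3)

    def test_packaged_table_screening(self):
        cols = load_api_profiles()
        pd1 = cols["PD-1_24h"]
        sims = {
            name: api_similarity(pd1, cols[name])
            for name in cols
            if name not in ("PD-1_24h", "PD-1_48h")
        }
        # brute-force recount for the nearest-relative column
        ref = cols["P_beijingensis"]
        comparable = [
            (x, y)
            for x, y in zip(pd1, ref)
            if x not in ("V", "ND") and y not in ("V", "ND")
        ]
        expected = sum(x == y for x, y in comparable) / len(comparable)
        assert sims["P_beijingensis"] == pytest.approx(expected)
        assert all(0.0 <= s <= 1.0 for s in sims.values())
        # the nearest relative clears the 0.6 screening threshold
        assert sims["P_beijingensis"] > 0.6
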