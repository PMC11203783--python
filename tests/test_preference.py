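import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beechoice import (
    ChoiceDataset,
    ConsumptionRecord,
    consumption_rate,
    depth_comparison,
    fit_two_choice,
    intercept_closed_form,
    mann_whitney,
    preference_table,
    recover_counts,
)


class TestClosedForm:
    @pytest.mark.parametrize(
        "a,b,est,se",
        [
            (1, 1, 0.0, 1.41421),
            (11, 16, -0.3747, 0.3917),
            (9, 24, -0.9808, 0.3909),
        ],
    )
    def test_reference_values(self, a, b, est, se):
        got_est, got_se = intercept_closed_form(a, b)
        assert got_est == pytest.approx(est, abs=5e-5)
        assert got_se == pytest.approx(se, abs=5e-5)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            intercept_closed_form(0, 5)


class TestFitTwoChoice:
    @pytest.mark.parametrize(
        "a,b,est,se,z",
        [
            (39, 13, 1.099, 0.320, 3.430),
            (148, 58, 0.937, 0.155, 6.047),
        ],
    )
    def test_reconstructed_coefficient_rows(self, a, b, est, se, z):
        ds = ChoiceDataset.from_counts(a, b)
        fit = fit_two_choice(ds, "hue", species="species")
        coef = fit.intercept
        assert round(coef.estimate, 3) == est
        assert round(coef.std_error, 3) == se
        assert round(coef.z_value, 3) == z

    def test_equal_counts_give_zero_intercept(self):
        ds = ChoiceDataset.from_counts(25, 25)
        coef = fit_two_choice(ds, "hue", species="species").intercept
        assert coef.estimate == pytest.approx(0.0, abs=1e-10)
        assert coef.p_value == pytest.approx(1.0)

    @given(a=st.integers(1, 250), b=st.integers(1, 250))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_intercept_only_fit_equals_closed_form(self, a, b):
        ds = ChoiceDataset.from_counts(a, b)
        coef = fit_two_choice(ds, "hue", species="species").intercept
        est, se = intercept_closed_form(a, b)
        assert coef.estimate == pytest.approx(est, abs=1e-6)
        assert coef.std_error == pytest.approx(se, abs=1e-6)

    def test_relabeling_flips_sign_preserves_z(self):
        ds = ChoiceDataset.from_counts(30, 12)
        up = fit_two_choice(ds, "hue", species="species", success_level="yellow")
        down = fit_two_choice(ds, "hue", species="species", success_level="blue")
        assert up.intercept.estimate == pytest.approx(-down.intercept.estimate)
        assert abs(up.intercept.z_value) == pytest.approx(abs(down.intercept.z_value))
        assert up.intercept.p_value == pytest.approx(down.intercept.p_value)

    def test_complete_separation_flagged_not_raised(self):
        ds = ChoiceDataset.from_counts(10, 0, pair=("blue", "yellow"))
        fit = fit_two_choice(ds, "hue", species="species")
        assert fit.separation
        assert math.isinf(fit.intercept.estimate) and fit.intercept.estimate > 0

    def test_global_fit_includes_species_factor(self):
        a = ChoiceDataset.from_counts(30, 10, species="sp1")
        b = ChoiceDataset.from_counts(5, 25, species="sp2")
        ds = ChoiceDataset(a.records + b.records, a.variant_pairs)
        fit = fit_two_choice(ds, "hue")
        assert fit.n_obs == 70
        assert any("species" in name for name in fit.coefficients)


class TestRecoverCounts:
    @pytest.mark.parametrize(
        "est,se,a,b",
        [
            (1.099, 0.320, 39, 13),
            (0.937, 0.155, 148, 58),
            (0.0, 1.41421, 1, 1),
        ],
    )
    def test_reference_inversions(self, est, se, a, b):
        rec = recover_counts(est, se)
        assert (rec.successes, rec.failures) == (a, b)

    def test_no_match_raises(self):
        with pytest.raises(ValueError):
            recover_counts(0.001, 0.0011, max_total=200)

    @given(a=st.integers(1, 150), b=st.integers(1, 150))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_roundtrip_identity_on_unique_pairs(self, a, b):
        est, se = intercept_closed_form(a, b)
        rec = recover_counts(round(est, 3), round(se, 3), max_total=300)
        if rec.unique:
            assert (rec.successes, rec.failures) == (a, b)
        else:
            got_est, got_se = intercept_closed_form(rec.successes, rec.failures)
            assert round(got_est, 3) == round(est, 3)
            assert round(got_se, 3) == round(se, 3)


def oracle_mann_whitney(x, y):
    """Brute-force oracle: U by pairwise comparison, p by enumerating every
    reassignment of the pooled values to the two groups."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    mu = nx * ny / 2.0
    obs = abs(u_stat(x, y) - mu)
    pooled = x + y
    hits = total = 0
    for idx in itertools.combinations(range(nx + ny), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(nx + ny) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= obs - 1e-9:
            hits += 1
    return u_stat(x, y), hits / total


class TestMannWhitney:
    def test_disjoint_samples(self):
        u, p = mann_whitney([1, 2], [3, 4], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([5, 6, 7], [5, 6, 7], mode="exact")
        assert p == pytest.approx(1.0)

    def test_u_statistics_sum_to_product(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=6), rng.normal(size=5)
        ux, _ = mann_whitney(x, y, mode="exact")
        uy, _ = mann_whitney(y, x, mode="exact")
        assert ux + uy == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("nx,ny,seed", [(2, 3, 0), (3, 3, 1), (4, 4, 2), (3, 5, 3)])
    def test_exact_p_equals_enumeration_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        # integer values force ties, exercising the midrank handling
        x = rng.integers(0, 4, size=nx).astype(float)
        y = rng.integers(0, 4, size=ny).astype(float)
        u, p = mann_whitney(x, y, mode="exact")
        u_o, p_o = oracle_mann_whitney(x, y)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o)

    def test_degenerate_normal_mode(self):
        _, p = mann_whitney([2.0] * 8, [2.0] * 8, mode="normal")
        assert p == 1.0


class TestConsumption:
    def make(self, w0, w40, w2h, depth="flat"):
        return ConsumptionRecord(
            "f1", depth, {"t0": w0, "t40min": w40, "t2h": w2h}
        )

    @pytest.mark.parametrize(
        "window,w_end,expected",
        [("40min", 900.0, 150.0), ("40min", 1000.0, 0.0), ("2h", 880.0, 60.0)],
    )
    def test_rates(self, window, w_end, expected):
        rec = self.make(1000.0, w_end if window == "40min" else 950.0,
                        w_end if window == "2h" else 900.0)
        assert consumption_rate(rec, window) == pytest.approx(expected)

    def test_missing_timestamp_rejected(self):
        rec = ConsumptionRecord("f1", "deep", {"t0": 1000.0, "t2h": 900.0})
        with pytest.raises(ValueError):
            consumption_rate(rec, "40min")

    def test_negative_loss_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            rec = self.make(1000.0, 1005.0, 990.0)
        with pytest.warns(UserWarning):
            assert consumption_rate(rec, "40min") == 0.0

    def test_depth_comparison_report(self):
        records = [
            ConsumptionRecord(f"flat{i}", "flat", {"t0": 1000.0, "t40min": 1000.0 - w})
            for i, w in enumerate((80.0, 90.0, 100.0))
        ] + [
            ConsumptionRecord(f"deep{i}", "deep", {"t0": 1000.0, "t40min": 1000.0 - w})
            for i, w in enumerate((20.0, 30.0, 40.0))
        ]
        out = depth_comparison(records, window="40min", mode="exact")
        assert out["n_flat"] == out["n_deep"] == 3
        assert out["mean_rate_flat_mg_h"] == pytest.approx(135.0)
        assert out["U"] == 9.0  # flat rates all exceed deep rates
        assert out["p_value"] == pytest.approx(0.1)


class TestPreferenceTable:
    def build(self, counts):
        records, pairs = [], {}
        for (trait, species, pair), (a, b) in counts.items():
            ds = ChoiceDataset.from_counts(a, b, trait=trait, species=species, pair=pair)
            records.extend(ds.records)
            pairs.update(ds.variant_pairs)
        return ChoiceDataset(records, pairs)

    def test_preferred_labels_match_significance(self):
        ds = self.build(
            {
                ("hue", "L. villosulum", ("blue", "yellow")): (39, 13),
                ("hue", "O. bicornis", ("blue", "yellow")): (11, 16),
            }
        )
        table = preference_table(ds).set_index("species")
        assert table.loc["L. villosulum", "preferred"] == "yellow"
        assert table.loc["O. bicornis", "preferred"] == "no preference"
        assert table.loc["O. bicornis", "p_value"] == pytest.approx(0.339, abs=5e-4)

    def test_boundary_p_equal_alpha_is_no_preference(self):
        ds = self.build({("hue", "sp", ("blue", "yellow")): (33, 17)})
        fit = fit_two_choice(ds, "hue", species="sp")
        table = preference_table(ds, alpha=fit.intercept.p_value)
        assert table.loc[0, "preferred"] == "no preference"
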