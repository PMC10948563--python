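"""Plasticity index definitions, closed-form identities, and the
noise-free link back to the generator's treatment multipliers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootplast.errors import UndefinedIndexError, ValidationError
from rootplast.plasticity import (
    compute_index,
    cv_means,
    cv_total,
    percent_change,
    pi_cv_ratio,
    pi_v,
    species_indices,
)

positive = st.floats(1e-3, 1e6, allow_nan=False)


class TestCvTotal:
    def test_example(self):
        assert cv_total([2.0, 4.0, 6.0]) == pytest.approx(0.5, abs=1e-12)

    def test_constant_values(self):
        assert cv_total([3.0, 3.0, 3.0]) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(values=st.lists(positive, min_size=2, max_size=10),
           k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, values, k):
        assert cv_total([v * k for v in values]) == pytest.approx(
            cv_total(values), rel=1e-9
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedIndexError):
            cv_total([0.0, 0.0])


class TestPiV:
    def test_halving(self):
        assert pi_v(6.0, 3.0) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric(self):
        assert pi_v(3.0, 6.0) == pytest.approx(0.5, abs=1e-12)

    def test_equal_means_zero(self):
        assert pi_v(4.2, 4.2) == 0.0

    def test_paper_style_increase(self):
        # a 67% low-to-high increase is a ~40% high-to-low decrease
        m = 2.31
        assert pi_v(1.67 * m, m) == pytest.approx(1 - 1 / 1.67, abs=1e-12)
        assert pi_v(1.67 * m, m) == pytest.approx(0.4012, abs=5e-5)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedIndexError):
            pi_v(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            pi_v(-1.0, 2.0)


class TestCvMeans:
    def test_example(self):
        # SD of (6, 3) = 3/sqrt(2); mean = 4.5
        assert cv_means(6.0, 3.0) == pytest.approx(0.4714, abs=5e-5)

    def test_equal_means(self):
        assert cv_means(5.0, 5.0) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(m1=positive, m2=positive)
    def test_two_value_identity(self, m1, m2):
        expected = math.sqrt(2) * abs(m1 - m2) / (m1 + m2)
        assert cv_means(m1, m2) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(m1=positive, m2=positive)
    def test_algebraic_link_to_pi_v(self, m1, m2):
        expected = math.sqrt(2) * pi_v(m1, m2) * max(m1, m2) / (m1 + m2)
        assert cv_means(m1, m2) == pytest.approx(expected, rel=1e-9)


class TestPiCvRatio:
    def test_anchor_value(self):
        assert pi_cv_ratio(0.5, 0.5) == pytest.approx(1.0, abs=1e-15)

    def test_no_plasticity(self):
        assert pi_cv_ratio(0.0, 0.3) == 0.0

    def test_zero_cv_undefined(self):
        with pytest.raises(UndefinedIndexError):
            pi_cv_ratio(0.5, 0.0)

    def test_brute_force_on_pure_treatment_variation(self):
        """When the only variation is the treatment effect (4 identical
        plots per arm), the ratio matches direct enumeration over the 8
        plot values."""
        h, lo = 6.0, 2.0
        values = np.array([h] * 4 + [lo] * 4)
        ratio = compute_index("pi_cv_ratio", values[:4], values[4:])
        # independent arithmetic over the 8 values
        piv = (h - lo) / h
        cv = values.std(ddof=1) / values.mean()
        assert ratio == pytest.approx(piv / cv, rel=1e-12)


class TestPercentChange:
    def test_increase(self):
        m = 3.7
        assert percent_change(m, 1.67 * m) == pytest.approx(67.0, rel=1e-9)

    def test_matching_decrease(self):
        m = 3.7
        pc = percent_change(1.67 * m, m)
        assert round(pc) == -40
        assert pc == pytest.approx(-40.1198, abs=5e-5)

    def test_equal_means(self):
        assert percent_change(2.0, 2.0) == 0.0

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedIndexError):
            percent_change(0.0, 1.0)


class TestSpeciesIndices:
    def _table(self, drop_plot=False):
        rows = []
        for t, vals in (("high", [5, 6, 7, 6]), ("low", [3, 4, 3, 4])):
            for i, v in enumerate(vals):
                rows.append({"plot_id": f"B{i}-As-{t}", "species_code": "As",
                             "treatment": t, "block": f"B{i}", "value": v})
        df = pd.DataFrame(rows)
        return df.iloc[:-1] if drop_plot else df

    def test_matches_scalar_functions(self):
        df = self._table()
        out = species_indices(df, "demo").iloc[0]
        hi = df.loc[df["treatment"] == "high", "value"].to_numpy(float)
        lo = df.loc[df["treatment"] == "low", "value"].to_numpy(float)
        assert out["pi_v"] == pi_v(hi.mean(), lo.mean())
        assert out["cv_means"] == cv_means(hi.mean(), lo.mean())
        assert out["cv_total"] == cv_total(np.concatenate([hi, lo]))
        assert out["pi_cv_ratio"] == pytest.approx(
            out["pi_v"] / out["cv_total"], rel=1e-12
        )
        assert (out["n_high"], out["n_low"]) == (4, 4)

    def test_missing_plot_warns(self):
        with pytest.warns(UserWarning, match="fewer plots"):
            species_indices(self._table(drop_plot=True), "demo",
                            expected_n_per_arm=4)

    def test_negative_values_rejected(self):
        df = self._table()
        df.loc[0, "value"] = -1.0
        with pytest.raises(ValidationError):
            species_indices(df, "demo")

    def test_empty_arm_rejected(self):
        df = self._table()
        df = df[df["treatment"] == "high"]
        with pytest.raises(ValidationError, match="As"):
            species_indices(df, "demo")
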