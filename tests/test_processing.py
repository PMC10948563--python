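"""Fragment allocation, pooling and density computation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootplast.errors import GapError, ValidationError
from rootplast.processing import (
    allocate_fragments,
    compute_density,
    pool_by_plot_depth,
    process_samples,
)
from rootplast.synthetic import STRATUM_SAMPLE_COLUMNS

CORE_VOLUME_5CM = math.pi * 2.54**2 * 5.0  # 101.341 cm^3


def _sample_row(**overrides):
    row = {
        "block": "B1", "plot_id": "B1-Bp-high", "species_code": "Bp",
        "treatment": "high", "core_id": "C1", "stratum_index": 0,
        "absorptive_mass": 0.0, "transportive_mass": 0.0, "coarse_mass": 0.0,
        "dead_mass": 0.0, "fragment_tray_mass": 0.0,
        "soil_volume": CORE_VOLUME_5CM,
    }
    row.update(overrides)
    return row


def _frame(rows):
    return pd.DataFrame(rows, columns=STRATUM_SAMPLE_COLUMNS)


class TestAllocateFragments:
    @pytest.mark.parametrize("args,expected", [
        ((30.0, 10.0, 2.0, 0.10), (45.0, 15.0)),   # 20 mg split 3:1
        ((30.0, 10.0, 0.0, 0.10), (30.0, 10.0)),   # no fragments
        ((0.0, 0.0, 2.0, 0.10), (20.0, 0.0)),      # all-to-absorptive fallback
    ])
    def test_examples(self, args, expected):
        assert allocate_fragments(*args) == pytest.approx(expected, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            allocate_fragments(-1.0, 0.0, 0.0)
        with pytest.raises(ValidationError):
            allocate_fragments(1.0, 1.0, -0.5)
        with pytest.raises(ValidationError):
            allocate_fragments(1.0, 1.0, 1.0, tray_fraction=0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        absorptive=st.floats(0, 1e4),
        dead=st.floats(0, 1e4),
        tray=st.floats(0, 1e3),
        fraction=st.floats(0.01, 1.0),
    )
    def test_mass_conservation(self, absorptive, dead, tray, fraction):
        adj_a, adj_d = allocate_fragments(absorptive, dead, tray, fraction)
        assert adj_a >= 0 and adj_d >= 0
        total = absorptive + dead + tray / fraction
        assert adj_a + adj_d == pytest.approx(total, rel=1e-12, abs=1e-9)


class TestPooling:
    def test_masses_and_volumes_sum(self):
        rows = [
            _sample_row(core_id=f"C{i}", absorptive_mass=m)
            for i, m in enumerate((10.0, 20.0, 30.0), start=1)
        ]
        pooled = pool_by_plot_depth(_frame(rows))
        assert len(pooled) == 1
        assert pooled["absorptive_mass"].iloc[0] == pytest.approx(60.0)
        assert pooled["soil_volume"].iloc[0] == pytest.approx(3 * CORE_VOLUME_5CM)
        assert pooled["soil_volume"].iloc[0] == pytest.approx(304.02, abs=0.01)
        assert pooled["core_id"].iloc[0] == "pooled"

    def test_single_core_identity(self):
        df = _frame([_sample_row(absorptive_mass=12.5, dead_mass=3.0)])
        pooled = pool_by_plot_depth(df)
        for col in ("absorptive_mass", "dead_mass", "soil_volume"):
            assert pooled[col].iloc[0] == df[col].iloc[0]

    def test_missing_stratum_raises_gap_error(self):
        rows = [
            _sample_row(stratum_index=0),
            _sample_row(stratum_index=1),
            _sample_row(plot_id="B1-Qr-low", species_code="Qr",
                        treatment="low", stratum_index=0),
        ]
        with pytest.raises(GapError, match="B1-Qr-low.*stratum 1"):
            pool_by_plot_depth(_frame(rows))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            pool_by_plot_depth(_frame([]))


class TestDensity:
    def test_mass_over_volume(self):
        pooled = _frame([_sample_row(absorptive_mass=50.0, core_id="pooled")])
        out = compute_density(pooled)
        assert out["absorptive_density"].iloc[0] == pytest.approx(
            50.0 / CORE_VOLUME_5CM
        )
        assert out["absorptive_density"].iloc[0] == pytest.approx(0.4934, abs=5e-5)

    def test_zero_masses_zero_densities(self):
        out = compute_density(_frame([_sample_row(core_id="pooled")]))
        for col in ("absorptive_density", "transportive_density",
                    "coarse_density", "dead_density"):
            assert out[col].iloc[0] == 0.0

    def test_fragment_adjusted_density(self):
        pooled = _frame([_sample_row(absorptive_mass=30.0, dead_mass=10.0,
                                     fragment_tray_mass=2.0, core_id="pooled")])
        out = compute_density(pooled)
        assert out["absorptive_density"].iloc[0] == pytest.approx(
            45.0 / CORE_VOLUME_5CM
        )
        assert out["absorptive_density"].iloc[0] == pytest.approx(0.4440, abs=5e-5)

    def test_zero_volume_rejected(self):
        pooled = _frame([_sample_row(core_id="pooled", soil_volume=0.0)])
        with pytest.raises(ValidationError):
            compute_density(pooled)


class TestInvariants:
    def test_pooling_order_invariance(self):
        """Pooling then densifying equals densities of the mass sums."""
        rng = np.random.default_rng(3)
        rows = []
        for c in range(3):
            for s in range(2):
                rows.append(_sample_row(
                    core_id=f"C{c}", stratum_index=s,
                    absorptive_mass=rng.uniform(1, 50),
                    dead_mass=rng.uniform(0, 10),
                    fragment_tray_mass=rng.uniform(0, 2),
                ))
        df = _frame(rows)
        out = process_samples(df)
        for s in range(2):
            sub = df[df["stratum_index"] == s]
            from rootplast.processing import allocate_fragments as alloc
            adj_a, _ = alloc(sub["absorptive_mass"].sum(),
                             sub["dead_mass"].sum(),
                             sub["fragment_tray_mass"].sum())
            expected = adj_a / sub["soil_volume"].sum()
            got = out.loc[out["stratum_index"] == s,
                          "absorptive_density"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_unit_rescaling_invariance(self):
        """Scaling all masses and volumes by the same factor leaves
        densities unchanged."""
        df = _frame([_sample_row(absorptive_mass=30.0, dead_mass=10.0,
                                 fragment_tray_mass=2.0, core_id="pooled")])
        scaled = df.copy()
        for col in ("absorptive_mass", "transportive_mass", "coarse_mass",
                    "dead_mass", "fragment_tray_mass", "soil_volume"):
            scaled[col] *= 1000.0
        a = compute_density(df)
        b = compute_density(scaled)
        pd.testing.assert_frame_equal(a, b)
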