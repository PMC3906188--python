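"""Phase-plane scans, the line of optimality and availability patterns."""

import numpy as np
import pytest

from redoxplane import (
    availability_pattern,
    fba,
    line_of_optimality,
    scan,
    set_uptake,
)
from redoxplane.phaseplane import find_exchange

from _oracle import brute_force_o2_at_optimum
from conftest import with_uptakes


@pytest.fixture(scope="module")
def grid_sc(sc):
    return scan(sc)


@pytest.fixture(scope="module")
def grid_ss(ss):
    return scan(ss)


class TestScan:
    def test_growth_monotone_in_glucose_at_fixed_oxygen(self, grid_sc):
        g = np.nan_to_num(grid_sc.growth, nan=0.0)
        assert (np.diff(g, axis=0) >= -1e-9).all()

    def test_growth_monotone_in_oxygen_up_to_line_of_optimality(self, grid_sc):
        for i, loo in enumerate(grid_sc.loo):
            row = grid_sc.growth[i]
            left = grid_sc.o2_axis < loo
            vals = row[left & grid_sc.feasible[i]]
            assert (np.diff(vals) >= -1e-9).all()

    def test_growth_beyond_line_never_exceeds_growth_on_line(self, sc, grid_sc):
        for i, glc in enumerate(grid_sc.glc_axis):
            loo = grid_sc.loo[i]
            if not np.isfinite(loo):
                continue
            z_line = fba(
                with_uptakes(sc, glc, loo), check_degeneracy=False
            ).objective
            beyond = grid_sc.growth[i][grid_sc.o2_axis > loo]
            beyond = beyond[np.isfinite(beyond)]
            assert (beyond <= z_line + 1e-6).all()

    def test_ethanol_positive_left_of_line_and_zero_on_it(self, sc, grid_sc):
        # strictly oxygen-limited points more than one sink capacity below
        # the line must ferment; on the line itself ethanol vanishes
        for i, glc in enumerate(grid_sc.glc_axis):
            loo = grid_sc.loo[i]
            if not np.isfinite(loo):
                continue
            on_line = fba(with_uptakes(sc, glc, loo), check_degeneracy=False)
            from redoxplane import remove_loops

            clean = remove_loops(with_uptakes(sc, glc, loo), on_line)
            assert clean.flux("EX_eth") <= 1e-6
            mask = grid_sc.feasible[i] & (grid_sc.o2_axis < loo - 1.0)
            assert (grid_sc.ethanol[i][mask] > 0).all()

    def test_degenerate_ranges_rejected(self, sc):
        with pytest.raises(ValueError, match="steps"):
            scan(sc, glc_range=(1.0, 10.0, 1))
        with pytest.raises(ValueError, match="steps"):
            scan(sc, o2_range=(5.0, 5.0, 4))

    def test_model_without_oxygen_exchange_rejected(self, sc):
        broken = sc.copy()
        broken.metabolites[broken.metabolite_index("o2_c")] = type(
            broken.metabolites[0]
        )("xx_c", "", "c")
        broken.__post_init__()
        with pytest.raises(KeyError, match="no exchange"):
            find_exchange(broken, ("o2", "oxygen"))

    def test_scan_is_deterministic(self, sc):
        a = scan(sc, glc_range=(2, 8, 4), o2_range=(1, 10, 4))
        b = scan(sc, glc_range=(2, 8, 4), o2_range=(1, 10, 4))
        assert np.array_equal(
            np.nan_to_num(a.growth), np.nan_to_num(b.growth)
        )
        assert (a.classification == b.classification).all()


class TestLineOfOptimality:
    def test_slope_matches_vertex_oracle(self, sc):
        """The oracle's minimal oxygen uptake among optimal vertices equals
        the loop-removed oxygen demand at maximal biomass yield."""
        glc = 10.0
        loo = float(line_of_optimality(sc, [glc])[0])
        m = set_uptake(sc, "EX_o2", "unbounded")
        oracle = brute_force_o2_at_optimum(m, m.reaction_index("EX_o2"))
        assert loo == pytest.approx(oracle, rel=1e-6)

    def test_zero_glucose_gives_undefined_line(self, sc):
        out = line_of_optimality(sc, [0.0])
        assert np.isnan(out[0])

    def test_line_scales_linearly_with_glucose(self, sc):
        vals = line_of_optimality(sc, [2.0, 4.0, 8.0])
        assert vals[1] == pytest.approx(2 * vals[0], rel=1e-6)
        assert vals[2] == pytest.approx(4 * vals[0], rel=1e-6)


class TestAvailabilityPattern:
    def test_sc_all_excess_and_ss_subset(self, grid_sc, grid_ss):
        p_sc = availability_pattern(grid_sc)
        p_ss = availability_pattern(grid_ss)
        assert p_sc.all_excess_o2_limited and not p_sc.subset_excess
        assert p_ss.subset_excess and not p_ss.all_excess_o2_limited
        assert 0.0 < p_ss.fraction_excess < 1.0

    def test_ss_excess_confined_to_low_oxygen(self, grid_ss):
        """Within each glucose column the excess verdicts sit strictly below
        the limiting ones: the excess region is the low-oxygen sub-region."""
        for i in range(len(grid_ss.glc_axis)):
            col = grid_ss.classification[i]
            mask = grid_ss.o2_limited[i]
            o2_exc = grid_ss.o2_axis[mask & (col == "excess")]
            o2_lim = grid_ss.o2_axis[mask & (col == "limiting")]
            if o2_exc.size and o2_lim.size:
                assert o2_exc.max() < o2_lim.min()

    def test_pattern_stable_under_grid_refinement(self, ss):
        coarse = availability_pattern(
            scan(ss, glc_range=(0.5, 10, 10), o2_range=(0.5, 15, 10))
        )
        fine = availability_pattern(
            scan(ss, glc_range=(0.5, 10, 20), o2_range=(0.5, 15, 20))
        )
        assert coarse.subset_excess == fine.subset_excess
        assert coarse.all_excess_o2_limited == fine.all_excess_o2_limited
        assert coarse.fraction_excess == pytest.approx(
            fine.fraction_excess, abs=0.12
        )

    def test_no_oxygen_limited_points_is_an_error(self, sc):
        tiny = scan(sc, glc_range=(0.5, 1.0, 2), o2_range=(14.0, 18.0, 2))
        with pytest.raises(ValueError, match="oxygen-limited"):
            availability_pattern(tiny)

    def test_all_neutral_grid_reports_zero_fraction(self, grid_sc):
        neutral = grid_sc
        cls = neutral.classification.copy()
        try:
            neutral.classification = np.full_like(cls, "neutral")
            p = availability_pattern(neutral)
            assert p.fraction_excess == 0.0
            assert not p.all_excess_o2_limited and not p.subset_excess
        finally:
            neutral.classification = cls


class TestExport:
    def test_long_format_roundtrip(self, grid_sc, tmp_path):
        df = grid_sc.to_dataframe()
        assert set(df.columns) >= {
            "glc", "o2", "growth", "ethanol", "gamma_red", "classification"
        }
        assert len(df) == len(grid_sc.glc_axis) * len(grid_sc.o2_axis)
        grid_sc.to_csv(tmp_path / "grid.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "grid.csv")
        assert len(back) == len(df)
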