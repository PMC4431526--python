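import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wormscreen as ws
from wormscreen import fitness, layout

ND = float("nan")


def nd(value):
    return isinstance(value, float) and math.isnan(value)


class TestComputeRF:
    @pytest.mark.parametrize("parents,progeny,expected", [
        (5, 40, 8.0),
        (2, 10, 5.0),       # lower window edge is valid
        (12, 0, 0.0),       # upper edge, zero fitness is a value, not ND
        (1, 30, ND),        # below the 2-parent floor
        (13, 30, ND),       # above the 12-parent ceiling
        (0, 0, ND),
        (ND, 30, ND),
    ])
    def test_quality_window(self, parents, progeny, expected):
        got = ws.compute_rf(parents, progeny)
        assert nd(got) if nd(expected) else got == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ws.compute_rf(-1, 5)
        with pytest.raises(ValueError):
            ws.compute_rf(5, -1)


class TestNormalizePlate:
    def test_sample_median_division(self):
        rfs = {f"B{i:02d}": v for i, v in enumerate([2, 4, 6, 8, 10], start=2)}
        out, info = ws.normalize_plate(rfs, sample_wells=rfs.keys())
        assert info["median"] == 6 and info["normalizable"]
        assert [out[w] for w in sorted(out)] == pytest.approx(
            [2 / 6, 4 / 6, 1.0, 8 / 6, 10 / 6]
        )

    def test_controls_normalized_but_excluded_from_median(self):
        rfs = {"A01": 100.0, "B02": 2.0, "B03": 4.0, "B04": 6.0}
        out, info = ws.normalize_plate(rfs, sample_wells={"B02", "B03", "B04"})
        assert info["median"] == 4.0
        assert out["A01"] == 25.0  # control divided by the sample median

    def test_all_nd_samples_unnormalizable(self):
        rfs = {"B02": ND, "B03": ND, "A01": 5.0}
        out, info = ws.normalize_plate(rfs, sample_wells={"B02", "B03"})
        assert not info["normalizable"]
        assert all(nd(v) for v in out.values())

    def test_zero_median_unnormalizable(self):
        rfs = {"B02": 0.0, "B03": 0.0, "B04": 0.0}
        out, info = ws.normalize_plate(rfs, sample_wells=rfs.keys())
        assert not info["normalizable"]
        assert all(nd(v) for v in out.values())

    @settings(deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           values=st.lists(st.floats(min_value=0.1, max_value=100), min_size=3, max_size=30))
    def test_scale_invariance(self, scale, values):
        wells = {f"W{i}": v for i, v in enumerate(values)}
        scaled = {w: v * scale for w, v in wells.items()}
        base, _ = ws.normalize_plate(wells, sample_wells=wells.keys())
        resc, _ = ws.normalize_plate(scaled, sample_wells=wells.keys())
        for w in wells:
            assert resc[w] == pytest.approx(base[w], rel=1e-9)

    @given(values=st.lists(st.floats(min_value=0.1, max_value=100), min_size=1, max_size=31))
    def test_median_of_normalized_samples_is_one(self, values):
        wells = {f"W{i}": v for i, v in enumerate(values)}
        out, _ = ws.normalize_plate(wells, sample_wells=wells.keys())
        assert np.median(list(out.values())) == pytest.approx(1.0, abs=1e-12)

    def test_nd_propagates(self):
        rfs = {"B02": 2.0, "B03": 4.0, "B04": ND}
        out, _ = ws.normalize_plate(rfs, sample_wells=rfs.keys())
        assert nd(out["B04"]) and not nd(out["B02"])


class TestReplicateAndRatio:
    @pytest.mark.parametrize("r1,r2,expected", [
        (0.8, 1.2, 1.0),
        (ND, 0.9, 0.9),   # the single replicate that worked
        (0.9, ND, 0.9),
        (ND, ND, ND),
    ])
    def test_technical_summary(self, r1, r2, expected):
        got = ws.summarize_technical(r1, r2)
        assert nd(got) if nd(expected) else got == pytest.approx(expected)

    @pytest.mark.parametrize("mut,wt,expected", [
        (0.5, 1.0, 0.5),
        (1.0, 0.0, ND),   # zero wild-type fitness: ratio undefined
        (0.9, 0.9, 1.0),
        (ND, 1.0, ND),
    ])
    def test_ratio(self, mut, wt, expected):
        got = ws.compute_rf_ratio(mut, wt)
        assert nd(got) if nd(expected) else got == pytest.approx(expected)

    @given(mut=st.floats(min_value=0.01, max_value=10),
           wt=st.floats(min_value=0.01, max_value=10))
    def test_strain_swap_inverts_ratio(self, mut, wt):
        r = ws.compute_rf_ratio(mut, wt, orientation="mut_over_wt")
        r_swapped = ws.compute_rf_ratio(mut, wt, orientation="wt_over_mut")
        assert r_swapped == pytest.approx(1.0 / r)

    @pytest.mark.parametrize("rf,expected", [
        (0.05, 0.95),
        (1.0, 0.0),
        (1.4, 0.0),   # over-typical fitness clamps to zero lethality
        (ND, ND),
    ])
    def test_lethality(self, rf, expected):
        got = ws.compute_lethality(rf)
        assert nd(got) if nd(expected) else got == pytest.approx(expected)


class TestTableChain:
    """Vectorized drivers must agree with the scalar definitions."""

    def test_table_chain_matches_scalar_path(self, small_screen):
        wells, _ = small_screen
        scored = fitness.add_rf(wells)
        for _, row in scored.sample(50, random_state=0).iterrows():
            expected = ws.compute_rf(row["Parents"], row["Progeny"])
            got = row["RF"]
            assert nd(got) if nd(expected) else got == pytest.approx(expected)

    def test_plate_medians_of_normalized_samples_are_one(self, small_screen):
        wells, _ = small_screen
        scored = fitness.add_rf(wells)
        normalized, log = fitness.normalize_screen(scored)
        ok = normalized[normalized["Description"] == layout.SAMPLE]
        med = ok.groupby(fitness.PLATE_GROUP)["RF_norm"].median()
        normalizable = log.set_index(fitness.PLATE_GROUP)["normalizable"]
        assert (normalizable.reindex(med.index)).all()
        assert np.allclose(med.to_numpy(), 1.0, atol=1e-12)

    def test_count_rescaling_leaves_normalized_rf_unchanged(self, small_screen):
        # raw fitness measurements scaled by a constant per plate cancel out
        wells, _ = small_screen
        scored = fitness.add_rf(wells)
        scaled = scored.copy()
        scaled["RF"] = scaled["RF"] * 3.7
        base, _ = fitness.normalize_screen(scored)
        resc, _ = fitness.normalize_screen(scaled)
        pd.testing.assert_series_equal(base["RF_norm"], resc["RF_norm"], rtol=1e-9)

    def test_nd_never_becomes_a_number(self, small_screen):
        wells, _ = small_screen
        broken = wells.copy()
        nd_mask = broken.index[:40]
        broken.loc[nd_mask, "Parents"] = np.nan
        scored = fitness.add_rf(broken)
        assert scored.loc[nd_mask, "RF"].isna().all()
        normalized, _ = fitness.normalize_screen(scored)
        assert normalized.loc[nd_mask, "RF_norm"].isna().all()

    def test_clone_table_covers_every_clone_once(self, small_screen):
        wells, _ = small_screen
        scored = fitness.add_rf(wells)
        normalized, _ = fitness.normalize_screen(scored)
        averaged = fitness.average_technical(normalized)
        clones = fitness.build_clone_table(averaged)
        keys = wells[["Plate", "Well", "BioRep"]].drop_duplicates()
        assert len(clones) == len(keys)
        assert not clones.duplicated(subset=["Plate", "Well", "BioRep"]).any()
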