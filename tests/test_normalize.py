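import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from osteoscreen.normalize import (
    NormalizationError,
    edge_correct,
    fold_change_vs_mock,
    normalize_readings,
    plate_normalize,
    subtract_background,
    trimmed_mean,
)
from osteoscreen.plate import WellRole, all_wells, default_layout


def make_plate_df(values_by_well, plate_id="p1", channel="alamar_blue"):
    """Annotated-readings frame for one plate from a {well: value} mapping."""
    layout = default_layout("fiber", "kinase", 1, [f"g{i}" for i in range(89)],
                            plate_id=plate_id)
    rows = []
    for addr, assign in sorted(layout.wells.items()):
        rows.append(
            {
                "plate_id": plate_id,
                "well": str(addr),
                "channel": channel,
                "value": values_by_well[str(addr)],
                "role": assign.role.value,
                "gene_id": assign.gene_id,
                "topography": "fiber",
                "library": "kinase",
                "replicate": 1,
                "is_edge": addr.is_edge,
            }
        )
    return pd.DataFrame(rows)


class TestTrimmedMean:
    @pytest.mark.parametrize(
        "values,trim,expected",
        [
            (list(range(1, 11)), 0.2, 5.5),  # drop {1,2},{9,10}; mean 3..8
            ([7, 7, 7, 7, 7], 0.2, 7.0),
            ([3, 1, 2], 0.0, 2.0),
        ],
    )
    def test_examples(self, values, trim, expected):
        assert trimmed_mean(values, trim) == pytest.approx(expected, abs=1e-12)

    def test_empty_and_bad_fraction_rejected(self):
        with pytest.raises(NormalizationError):
            trimmed_mean([], 0.2)
        with pytest.raises(NormalizationError):
            trimmed_mean([1.0], 0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=60
        ),
        trim=st.floats(0, 0.49),
    )
    def test_matches_scipy_truncation_rule(self, values, trim):
        k = int(np.floor(trim * len(values)))
        if 2 * k >= len(values):
            return
        ours = trimmed_mean(values, trim)
        theirs = stats.trim_mean(values, trim)
        assert ours == pytest.approx(theirs, rel=1e-12, abs=1e-9)


class TestSubtractBackground:
    def test_constant_plate_self_subtracts(self):
        df = make_plate_df({str(w): 5.0 for w in all_wells()})
        out, rec = subtract_background(df)
        assert np.allclose(out["value"], 0.0)
        assert rec["background_value"].iloc[0] == 5.0

    def test_mean_of_multiple_background_wells(self):
        vals = {str(w): 10.0 for w in all_wells()}
        df = make_plate_df(vals)
        # add a second background well by editing roles directly
        df.loc[df["well"] == "G12", "role"] = WellRole.BACKGROUND.value
        df.loc[df["well"] == "H12", "value"] = 1.0
        df.loc[df["well"] == "G12", "value"] = 3.0
        out, rec = subtract_background(df)
        assert rec["background_value"].iloc[0] == 2.0
        assert out.loc[out["well"] == "A1", "value"].iloc[0] == 8.0

    def test_missing_background_rejected_with_plate_name(self):
        df = make_plate_df({str(w): 1.0 for w in all_wells()})
        df = df[df["well"] != "H12"]
        with pytest.raises(NormalizationError, match="p1"):
            subtract_background(df)


class TestEdgeCorrect:
    def test_constant_plate_factor(self):
        vals = {
            str(w): (1.0 if w.is_edge else 2.0) for w in all_wells()
        }
        df = make_plate_df(vals)
        out, rec = edge_correct(df)
        assert rec["edge_correction_factor"].iloc[0] == pytest.approx(2.0)
        edge_vals = out.loc[out["well"] == "A1", "value"]
        assert edge_vals.iloc[0] == pytest.approx(2.0)
        assert out.loc[out["well"] == "D6", "value"].iloc[0] == 2.0

    def test_identity_when_no_edge_effect(self):
        df = make_plate_df({str(w): 3.0 for w in all_wells()})
        out, rec = edge_correct(df)
        assert rec["edge_correction_factor"].iloc[0] == pytest.approx(1.0)
        assert np.allclose(out["value"], 3.0)

    def test_noisy_attenuated_edge_recovers_factor(self, rng):
        base = {str(w): float(rng.normal(100, 5)) for w in all_wells()}
        vals = {w: (0.8 * v if is_edge else v)
                for (w, v), is_edge in zip(base.items(), (a.is_edge for a in all_wells()))}
        df = make_plate_df(vals)
        out, rec = edge_correct(df)
        factor = rec["edge_correction_factor"].iloc[0]
        assert factor == pytest.approx(1.25, rel=0.05)
        # post-condition: trimmed means of edge and interior cell wells equal
        cells = out[out["role"] != WellRole.BACKGROUND.value]
        tm_edge = trimmed_mean(cells.loc[cells["is_edge"], "value"], 0.2)
        tm_int = trimmed_mean(cells.loc[~cells["is_edge"], "value"], 0.2)
        assert tm_edge == pytest.approx(tm_int, rel=1e-9)

    def test_nonpositive_edge_mean_rejected(self):
        vals = {str(w): (-1.0 if w.is_edge else 2.0) for w in all_wells()}
        df = make_plate_df(vals)
        with pytest.raises(NormalizationError, match="edge"):
            edge_correct(df)


class TestPlateNormalize:
    def test_constant_eligible_wells_become_one(self):
        vals = {str(w): 4.0 for w in all_wells()}
        df = make_plate_df(vals)
        out, rec = plate_normalize(df)
        assert rec["plate_scale"].iloc[0] == pytest.approx(4.0)
        eligible = out[~out["role"].isin(
            [WellRole.CELL_DEATH.value, WellRole.BACKGROUND.value,
             WellRole.MEDIA_GROWTH.value, WellRole.MEDIA_MINERALIZATION.value,
             WellRole.CELLS_SECONDARY_ONLY.value])]
        assert np.allclose(eligible["value"], 1.0)

    def test_positive_controls_excluded_from_scale_but_divided(self):
        vals = {str(w): 2.0 for w in all_wells()}
        df = make_plate_df(vals)
        # make the cell-death control extreme: must not move the scale
        df.loc[df["role"] == WellRole.CELL_DEATH.value, "value"] = 1000.0
        out, rec = plate_normalize(df)
        assert rec["plate_scale"].iloc[0] == pytest.approx(2.0)
        cd = out.loc[out["role"] == WellRole.CELL_DEATH.value, "value"]
        assert cd.iloc[0] == pytest.approx(500.0)

    def test_trimmed_mean_of_eligible_is_one_after(self, rng):
        vals = {str(w): float(rng.lognormal(3, 0.3)) for w in all_wells()}
        df = make_plate_df(vals)
        out, _ = plate_normalize(df)
        from osteoscreen.normalize import POSITIVE_CONTROL_ROLES
        eligible = out[~out["role"].isin(POSITIVE_CONTROL_ROLES)]
        assert trimmed_mean(eligible["value"], 0.2) == pytest.approx(1.0, rel=1e-9)


class TestFoldChangeVsMock:
    def _two_plate_df(self, mock_values):
        frames = []
        for i, mv in enumerate(mock_values, start=1):
            vals = {str(w): 2.0 for w in all_wells()}
            df = make_plate_df(vals, plate_id=f"p{i}")
            df.loc[df["role"] == WellRole.MOCK.value, "value"] = mv
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_unit_median_changes_nothing(self):
        df = self._two_plate_df([0.9, 1.0, 1.1])
        out, rec = fold_change_vs_mock(df)
        assert rec["mock_median"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out["well"] == "D6", "value"].iloc[0] == pytest.approx(2.0)

    def test_constant_mock_divides_everything(self):
        df = self._two_plate_df([2.0, 2.0])
        out, rec = fold_change_vs_mock(df)
        assert rec["mock_median"].iloc[0] == 2.0
        assert out.loc[out["well"] == "D6", "value"].iloc[0] == pytest.approx(1.0)

    def test_median_mock_fold_change_is_exactly_one(self, rng):
        df = self._two_plate_df(list(rng.lognormal(0, 0.2, size=5)))
        out, _ = fold_change_vs_mock(df)
        mock_fc = out.loc[out["role"] == WellRole.MOCK.value, "value"]
        assert float(np.median(mock_fc)) == 1.0

    def test_no_mock_rejected(self):
        df = make_plate_df({str(w): 1.0 for w in all_wells()})
        df = df[df["role"] != WellRole.MOCK.value]
        with pytest.raises(NormalizationError, match="MOCK"):
            fold_change_vs_mock(df)


class TestFullChain:
    def test_chain_invariants_on_noisy_screen(self, small_screen):
        dataset, _, _ = small_screen
        norm, records = normalize_readings(dataset.annotated())
        assert (records["edge_correction_factor"] > 0).all()
        assert (records["plate_scale"] > 0).all()
        assert (records["mock_median"] > 0).all()
        mock = norm[norm["role"] == WellRole.MOCK.value]
        for ch, sub in mock.groupby("channel"):
            assert float(np.median(sub["value"])) == 1.0
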