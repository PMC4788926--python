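"""Comparative-CT layer: I/O, reference selection, ddCT arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fflscreen import qpcr
from fflscreen.errors import (
    DuplicateRecordError, InsufficientDataError, NormalizationError,
    PairingError, RangeError, SchemaError,
)
from fflscreen.qpcr import (
    CONTROL, FormatConfig, compute_ddct, read_ct_table, select_reference_gene,
    write_ct_table,
)

from conftest import make_ct_table


def write_long(path, rows, header="sample_id,perturbation,time_h,phase,replicate,gene,ct"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadCtTable:
    def test_long_round_trip_preserves_cells(self, tmp_path):
        rows = [
            f"{cond}_t2_r{r},{cond},2,stimulation,{r},{gene},{ct + r * 0.01}"
            for cond, base in ((CONTROL, 20.0), ("P1", 22.0))
            for r in (1, 2)
            for gene, ct in (("GA", base), ("GB", base + 1.234567891234))
        ]
        src = tmp_path / "ct.csv"
        write_long(src, rows)
        ct = read_ct_table(src)
        assert len(ct.genes) == 2 and len(ct.samples) == 4
        dst = tmp_path / "out.csv"
        write_ct_table(ct, dst)
        again = read_ct_table(dst)
        pd.testing.assert_frame_equal(ct.values, again.values)
        assert [s.sample_id for s in again.samples] == [s.sample_id for s in ct.samples]

    def test_undetermined_becomes_missing(self, tmp_path):
        src = tmp_path / "ct.csv"
        write_long(src, [
            "s1,CONTROL,2,stimulation,1,GA,20.0",
            "s1,CONTROL,2,stimulation,1,GB,Undetermined",
        ])
        ct = read_ct_table(src)
        assert math.isnan(ct.values.loc["GB", "s1"])
        assert ct.values.loc["GA", "s1"] == 20.0

    def test_missing_ct_column_is_schema_error(self, tmp_path):
        src = tmp_path / "ct.csv"
        src.write_text("sample_id,perturbation,time_h,replicate,gene\ns1,CONTROL,2,1,GA\n")
        with pytest.raises(SchemaError, match="ct"):
            read_ct_table(src)

    def test_duplicate_cell_rejected(self, tmp_path):
        src = tmp_path / "ct.csv"
        write_long(src, [
            "s1,CONTROL,2,stimulation,1,GA,20.0",
            "s1,CONTROL,2,stimulation,1,GA,21.0",
        ])
        with pytest.raises(DuplicateRecordError):
            read_ct_table(src)

    def test_ct_out_of_range_rejected(self, tmp_path):
        src = tmp_path / "ct.csv"
        write_long(src, ["s1,CONTROL,2,stimulation,1,GA,44.5"])
        with pytest.raises(RangeError, match="44.5"):
            read_ct_table(src)

    def test_phase_derived_from_time_when_absent(self, tmp_path):
        src = tmp_path / "ct.csv"
        src.write_text(
            "sample_id,perturbation,time_h,replicate,gene,ct\n"
            "s1,CONTROL,12,1,GA,20.0\n"
        )
        ct = read_ct_table(src)
        assert ct.samples[0].phase == "washout"

    def test_wide_dialect(self, tmp_path):
        (tmp_path / "m.csv").write_text(
            "sample_id,perturbation,time_h,replicate\n"
            "s1,CONTROL,2,1\ns2,P1,2,1\n"
        )
        (tmp_path / "w.csv").write_text("gene,s1,s2\nGA,20,21\nGB,22,Undetermined\n")
        ct = read_ct_table(
            tmp_path / "w.csv",
            FormatConfig(dialect="wide", metadata_path=str(tmp_path / "m.csv")),
        )
        assert ct.values.loc["GA", "s2"] == 21.0
        assert math.isnan(ct.values.loc["GB", "s2"])


class TestReferenceSelection:
    def _table_with_sds(self):
        # candidate SDs constructed directly: HK1 ~ 0.1, HK2 ~ 0.5, HK3 ~ 1.0
        spread = {"HK1": 0.1, "HK2": 0.5, "HK3": 1.0}

        def fill(g, cond, t, r):
            offset = spread.get(g, 2.0) * (1 if r == 1 else -1) / np.sqrt(2)
            return 25.0 + offset

        return make_ct_table(["GA", "HK1", "HK2", "HK3"], fill=fill,
                             housekeeping=("HK1", "HK2", "HK3"))

    def test_smallest_sd_wins(self):
        ct = self._table_with_sds()
        best, scores = select_reference_gene(ct)
        assert best == "HK1"
        # oracle: SD computed directly from the raw CT rows
        for cand in scores.index:
            expected = float(ct.values.loc[cand].std(ddof=1))
            assert scores[cand] == pytest.approx(expected)
        assert scores["HK1"] < scores["HK2"] < scores["HK3"]

    def test_single_candidate_returned(self):
        ct = self._table_with_sds()
        best, _ = select_reference_gene(ct, ["HK2"])
        assert best == "HK2"

    def test_tie_broken_by_list_order(self):
        ct = make_ct_table(["HK1", "HK2"], fill=lambda g, c, t, r: 25.0,
                           housekeeping=("HK2", "HK1"))
        best, _ = select_reference_gene(ct)
        assert best == "HK2"

    def test_empty_candidates_rejected(self):
        ct = self._table_with_sds()
        with pytest.raises(ValueError):
            select_reference_gene(ct, [])

    def test_too_few_observations_rejected(self):
        ct = self._table_with_sds()
        ct.values.loc["HK3", :] = np.nan
        ct.values.loc["HK3", ct.values.columns[0]] = 25.0
        with pytest.raises(InsufficientDataError):
            select_reference_gene(ct, ["HK3"])


class TestComputeDdct:
    def test_direct_formula(self):
        # KD dCT = 5, control dCT = 3 -> ddCT = 2
        def fill(g, cond, t, r):
            if g == "REF":
                return 20.0
            return 20.0 + (5.0 if cond == "P1" else 3.0)

        ct = make_ct_table(["GA", "REF"], fill=fill)
        ddct = compute_ddct(ct, "REF")
        cells = ddct.cells[ddct.cells["gene"] == "GA"]
        assert (cells["ddct"] == 2.0).all()
        row = ddct.summary[ddct.summary["gene"] == "GA"].iloc[0]
        assert row["mean_ddct"] == 2.0
        assert row["fold_change"] == pytest.approx(0.25)
        assert row["K"] == 2

    def test_identical_conditions_give_zero(self, rng):
        ct = make_ct_table(["GA", "GB", "REF"],
                           fill=lambda g, c, t, r: 20.0 + hash(g) % 7)
        ddct = compute_ddct(ct, "REF")
        assert (ddct.cells["ddct"] == 0.0).all()
        assert (ddct.summary["fold_change"] == 1.0).all()

    @pytest.mark.parametrize("mean,fc", [(1.0, 0.5), (-1.0, 2.0), (0.0, 1.0)])
    def test_fold_change_formula(self, mean, fc):
        def fill(g, cond, t, r):
            return 20.0 + (mean if (cond == "P1" and g == "GA") else 0.0)

        ct = make_ct_table(["GA", "REF"], fill=fill)
        row = compute_ddct(ct, "REF").summary
        row = row[row["gene"] == "GA"].iloc[0]
        assert row["fold_change"] == pytest.approx(fc)

    def test_missing_ct_reduces_K(self):
        ct = make_ct_table(["GA", "REF"], fill=lambda g, c, t, r: 21.0)
        ct.values.loc["GA", "P1_t2_r1"] = np.nan
        ddct = compute_ddct(ct, "REF")
        row = ddct.summary[(ddct.summary["gene"] == "GA") & (ddct.summary["time_h"] == 2.0)]
        assert row.iloc[0]["K"] == 1
        assert math.isnan(row.iloc[0]["var_ddct"])

    def test_missing_reference_is_normalization_error(self):
        ct = make_ct_table(["GA", "REF"], fill=lambda g, c, t, r: 21.0)
        ct.values.loc["REF", "P1_t2_r1"] = np.nan
        with pytest.raises(NormalizationError, match="P1_t2_r1"):
            compute_ddct(ct, "REF")

    def test_unmatched_stratum_is_pairing_error(self):
        ct = make_ct_table(["GA", "REF"], fill=lambda g, c, t, r: 21.0)
        ct_missing = make_ct_table(["GA", "REF"], fill=lambda g, c, t, r: 21.0)
        keep = [s for s in ct_missing.samples if not
                (s.perturbation == CONTROL and s.time_h == 8.0)]
        trimmed = qpcr.CtTable(
            values=ct.values[[s.sample_id for s in keep]].copy(),
            samples=keep, schedule=ct.schedule,
        )
        with pytest.raises(PairingError, match="8"):
            compute_ddct(trimmed, "REF")

    def test_mean_control_policy(self):
        # control replicates differ; pairing vs mean-control disagree per replicate
        def fill(g, cond, t, r):
            if g == "REF":
                return 20.0
            if cond == CONTROL:
                return 23.0 + (0.5 if r == 1 else -0.5)
            return 25.0

        ct = make_ct_table(["GA", "REF"], fill=fill)
        paired = compute_ddct(ct, "REF", pairing="paired")
        pooled = compute_ddct(ct, "REF", pairing="mean_control")
        cells_p = paired.cells[paired.cells["gene"] == "GA"]
        cells_m = pooled.cells[pooled.cells["gene"] == "GA"]
        assert set(np.round(cells_p["ddct"], 9)) == {1.5, 2.5}
        assert (cells_m["ddct"] == 2.0).all()
        # replicate means agree between the two policies
        assert paired.summary[paired.summary["gene"] == "GA"]["mean_ddct"].tolist() == \
            pooled.summary[pooled.summary["gene"] == "GA"]["mean_ddct"].tolist()


class TestInvariants:
    @given(st.floats(-5, 5, allow_nan=False))
    def test_sample_wide_shift_cancels_in_ddct(self, c):
        """Adding a constant to every gene of one sample leaves ddCT unchanged."""
        base = make_ct_table(["GA", "GB", "REF"],
                             fill=lambda g, cond, t, r: 20.0 + (hash((g, cond)) % 5))
        shifted = base.values.copy()
        shifted["P1_t2_r1"] = shifted["P1_t2_r1"] + c
        ct2 = qpcr.CtTable(values=shifted, samples=base.samples, schedule=base.schedule)
        d1 = compute_ddct(base, "REF").cells.set_index(["gene", "time_h", "replicate"])
        d2 = compute_ddct(ct2, "REF").cells.set_index(["gene", "time_h", "replicate"])
        pd.testing.assert_frame_equal(d1, d2, check_exact=False, atol=1e-9)

    @given(st.floats(-5, 5, allow_nan=False))
    def test_reference_shift_across_all_samples_cancels(self, c):
        base = make_ct_table(["GA", "REF"],
                             fill=lambda g, cond, t, r: 20.0 + (3.0 if cond == "P1" else 0.0))
        shifted = base.values.copy()
        shifted.loc["REF"] = shifted.loc["REF"] + c
        ct2 = qpcr.CtTable(values=shifted, samples=base.samples, schedule=base.schedule)
        d1 = compute_ddct(base, "REF").cells["ddct"].to_numpy()
        d2 = compute_ddct(ct2, "REF").cells["ddct"].to_numpy()
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_swapping_conditions_negates_ddct(self, rng):
        ct = make_ct_table(["GA", "GB", "REF"],
                           fill=lambda g, c, t, r: float(20 + (hash((g, c, t, r)) % 100) / 25))
        fwd = compute_ddct(ct, "REF").cells
        relabeled = [
            qpcr.SampleMeta(s.sample_id,
                            "P1" if s.perturbation == CONTROL else CONTROL,
                            s.time_h, s.phase, s.replicate)
            for s in ct.samples
        ]
        ct_rev = qpcr.CtTable(values=ct.values.copy(), samples=relabeled,
                              schedule=ct.schedule)
        rev = compute_ddct(ct_rev, "REF").cells
        key = ["gene", "time_h", "replicate"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        np.testing.assert_allclose(merged["ddct_f"], -merged["ddct_r"], atol=1e-9)

    @given(st.floats(-10, 10, allow_nan=False))
    def test_fold_change_reciprocal(self, m):
        assert 2.0 ** (-m) * 2.0 ** (m) == pytest.approx(1.0)
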