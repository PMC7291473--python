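"""Peak-table and metadata I/O, and size-standard validation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbpkit import (
    CERun,
    PeakRecord,
    SizeStandardDef,
    read_metadata,
    read_peak_table,
    validate_size_standard,
    write_peak_table,
)
from tbpkit.binning import bin_markers
from tbpkit.errors import ColumnMappingError, CrossReferenceError, TBPKitError
from tbpkit.fragment_io import (
    check_sample_codes,
    normalize_region,
    read_matrix,
    write_matrix,
    write_metadata,
    SampleMetadata,
)

from conftest import make_profile


class TestReadPeakTable:
    def test_reads_one_run_with_ascending_peaks(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text(
            "Sample,Region,Amp,Dilution,Size,Height\n"
            "S1,first,1,1,302.1,500\n"
            "S1,first,1,1,450.0,900\n"
            "S1,first,1,1,610.5,120\n"
        )
        runs = read_peak_table(p)
        assert len(runs) == 1
        assert [pk.size_bp for pk in runs[0].peaks] == [302.1, 450.0, 610.5]

    def test_out_of_order_sizes_are_sorted(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text(
            "Sample,Size,Height\nS1,610.5,120\nS1,302.1,500\nS1,450.0,900\n"
        )
        runs = read_peak_table(p)
        sizes = [pk.size_bp for pk in runs[0].peaks]
        assert sizes == sorted(sizes) == [302.1, 450.0, 610.5]

    def test_missing_height_column_is_named(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("Sample,Size\nS1,302.1\n")
        with pytest.raises(ColumnMappingError, match="height"):
            read_peak_table(p)

    def test_duplicate_rows_keep_highest_rfu(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text(
            "Sample,Size,Height\nS1,302.1,500\nS1,302.1,900\nS1,302.1,100\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            runs = read_peak_table(p)
        assert len(runs[0].peaks) == 1
        assert runs[0].peaks[0].height_rfu == 900

    def test_unparseable_rows_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("Sample,Size,Height\nS1,302.1,500\nS1,oops,900\n")
        with pytest.warns(UserWarning, match="unparseable"):
            runs = read_peak_table(p)
        assert len(runs[0].peaks) == 1

    def test_round_trip_full_precision(self, tmp_path, rng):
        runs = [
            CERun(
                f"S{i}",
                "first" if i % 2 else "second",
                str(1 + i % 2),
                "1",
                peaks=[
                    PeakRecord(float(s), float(h))
                    for s, h in zip(
                        np.sort(rng.uniform(50, 1200, 8)), rng.uniform(51, 30000, 8)
                    )
                ],
            )
            for i in range(4)
        ]
        p = tmp_path / "rt.csv"
        write_peak_table(runs, p)
        back = read_peak_table(p)
        assert len(back) == len(runs)
        for a, b in zip(runs, back):
            assert a.key == b.key
            assert [x.size_bp for x in a.peaks] == [x.size_bp for x in b.peaks]
            assert [x.height_rfu for x in a.peaks] == [x.height_rfu for x in b.peaks]


@pytest.mark.parametrize(
    "token,expected",
    [("1", "first"), ("first", "first"), ("TBPTD1i", "first"),
     ("2", "second"), ("Second", "second"), ("TBPTD2i", "second")],
)
def test_region_token_normalization(token, expected):
    assert normalize_region(token) == expected


def test_unknown_region_token_rejected():
    with pytest.raises(TBPKitError, match="region"):
        normalize_region("third")


class TestSizeStandard:
    STD = SizeStandardDef("toy", (100.0, 200.0, 300.0))

    def test_exact_observation_passes(self):
        obs = [PeakRecord(s, 1000.0) for s in (100.0, 200.0, 300.0)]
        v = validate_size_standard(obs, self.STD)
        assert v.passed and v.n_matched == 3

    def test_missing_middle_fragment_fails_and_blocks_sizing(self):
        obs = [PeakRecord(100.0, 1000.0), PeakRecord(300.0, 1000.0)]
        v = validate_size_standard(obs, self.STD)
        assert not v.passed
        assert v.assignments[200.0] is None
        # peaks between the broken flanks are unsizeable, outside they are fine
        assert not v.sizeable(150.0)
        assert not v.sizeable(250.0)
        assert v.standard_ok  # two fragments still matched

    def test_matching_within_tolerance(self):
        std = SizeStandardDef("toy2", (100.0, 200.0))
        obs = [PeakRecord(100.3, 1000.0), PeakRecord(199.8, 1000.0)]
        v = validate_size_standard(obs, std, size_tol_bp=0.5)
        assert v.passed
        assert v.sizeable(150.0)

    def test_low_relative_height_peaks_ignored(self):
        obs = [
            PeakRecord(100.0, 1000.0),
            PeakRecord(199.9, 5.0),  # noise spike near an expected fragment
            PeakRecord(300.0, 1000.0),
        ]
        v = validate_size_standard(obs, self.STD, rel_height_min=0.1)
        assert v.assignments[200.0] is None

    @given(
        frags=st.lists(
            st.floats(min_value=50, max_value=1000), min_size=2, max_size=6, unique=True
        ),
        jitter=st.lists(st.floats(-1.0, 1.0), min_size=6, max_size=6),
        tol_big=st.floats(0.2, 2.0),
        shrink=st.floats(0.05, 1.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_shrinking_tolerance_never_turns_fail_into_pass(
        self, frags, jitter, tol_big, shrink
    ):
        expected = tuple(sorted(frags))
        if min(b - a for a, b in zip(expected, expected[1:])) < 5:
            return  # keep fragments separated so matching is unambiguous
        obs = sorted(f + j for f, j in zip(expected, jitter))
        peaks = [PeakRecord(s, 1000.0) for s in obs]
        std = SizeStandardDef("h", expected)
        big = validate_size_standard(peaks, std, size_tol_bp=tol_big)
        small = validate_size_standard(peaks, std, size_tol_bp=tol_big * shrink)
        if not big.passed:
            assert not small.passed


class TestMetadataAndMatrixIO:
    def test_metadata_round_trip_and_cross_reference(self, tmp_path):
        meta = [
            SampleMetadata("S1", "Arachis hypogaea", {"Ploidy": "4"}),
            SampleMetadata("S2", "Arachis duranensis", {"Ploidy": "2"}),
        ]
        p = tmp_path / "meta.csv"
        write_metadata(meta, p)
        back = read_metadata(p)
        assert [m.sample_code for m in back] == ["S1", "S2"]
        assert back[0].species == "Arachis hypogaea"
        assert back[0].groups["Ploidy"] == "4"
        check_sample_codes(["S1", "S2"], back)
        with pytest.raises(CrossReferenceError, match="S9"):
            check_sample_codes(["S1", "S9"], back)

    def test_matrix_round_trip_bit_exact(self, tmp_path):
        profiles = [
            make_profile("A", "first", [302.1, 450.0, 610.5, 700.0]),
            make_profile("B", "first", [302.8, 455.2, 610.4]),
            make_profile("C", "first", [302.4, 700.1]),
        ]
        _, m = bin_markers(profiles)
        p = tmp_path / "matrix.csv"
        write_matrix(m, p)
        back = read_matrix(p)
        assert back.samples == m.samples
        assert [b.label for b in back.bins] == [b.label for b in m.bins]
        assert np.array_equal(back.values, m.values)

    def test_empty_matrix_round_trip(self, tmp_path):
        _, m = bin_markers([])
        p = tmp_path / "empty.csv"
        write_matrix(m, p)
        back = read_matrix(p)
        assert back.shape == (0, 0)
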