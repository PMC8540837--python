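"""Amplicon filters, taxonomy assignment, and OTU-table normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from peatmox import (
    AmpliconRead,
    OTUTable,
    ReferenceDB,
    ValidationError,
    assign_taxonomy,
    denoise,
    frame_stop_filter,
    length_window_filter,
    log_normalize,
    quality_window_filter,
    to_relative_abundance,
)
from peatmox.simulate import gen_reference_orfs


def _read(seq_or_len, quals, rid="r"):
    if isinstance(seq_or_len, int):
        seq = "A" * seq_or_len
    else:
        seq = seq_or_len
    return AmpliconRead(id=rid, nucleotides=seq, qualities=np.asarray(quals, dtype=float))


def brute_force_keep(q: np.ndarray, window: int = 50, thresh: float = 20.0) -> bool:
    """All-windows oracle: kept iff every window mean >= threshold."""
    if len(q) < window:
        return q.mean() >= thresh
    return all(q[i : i + window].mean() >= thresh for i in range(len(q) - window + 1))


class TestQualityWindowFilter:
    def test_uniform_q30_read_kept(self):
        report = quality_window_filter([_read(100, [30] * 100)])
        assert report.n_kept == 1 and report.n_rejected == 0

    def test_contiguous_q15_stretch_discarded(self):
        quals = [35] * 100 + [15] * 50 + [35] * 100
        report = quality_window_filter([_read(250, quals)])
        assert report.n_rejected == 1

    def test_short_read_judged_on_full_length(self):
        assert quality_window_filter([_read(20, [25] * 20)]).n_kept == 1
        assert quality_window_filter([_read(20, [15] * 20)]).n_rejected == 1

    def test_planted_failure_count(self):
        reads = []
        for i in range(100):
            if i < 17:
                quals = [30] * 30 + [10] * 50 + [30] * 30
            else:
                quals = [30] * 110
            reads.append(_read(110, quals, rid=f"r{i}"))
        report = quality_window_filter(reads)
        assert report.n_kept == 83
        assert report.n_rejected == 17

    def test_matches_all_windows_oracle_on_random_reads(self):
        rng = np.random.default_rng(0)
        reads, expected = [], []
        for i in range(1000):
            n = int(rng.integers(30, 200))
            # mixture around the threshold so both outcomes occur
            q = rng.integers(10, 41, size=n).astype(float)
            reads.append(_read(n, q, rid=f"r{i}"))
            expected.append(brute_force_keep(q))
        report = quality_window_filter(reads)
        kept_ids = {r.id for r in report.kept}
        for read, keep in zip(reads, expected):
            assert (read.id in kept_ids) == keep

    def test_quality_length_mismatch_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            AmpliconRead(id="r", nucleotides="ACGT", qualities=np.array([30.0, 30.0]))


class TestFrameStopFilter:
    def test_valid_orf_passes(self):
        seq = "".join(gen_reference_orfs(1, length=465, seed=1)[0][1])
        ok, reason = frame_stop_filter(seq)
        assert ok, reason

    def test_length_not_divisible_by_three_fails(self):
        ok, reason = frame_stop_filter("A" * 466)
        assert not ok and "divisible" in reason

    def test_in_frame_stop_fails(self):
        seq = "ATG" * 19 + "TAA" + "ATG" * 135  # stop at codon 20
        ok, reason = frame_stop_filter(seq)
        assert not ok and "TAA" in reason

    def test_out_of_frame_stop_is_tolerated(self):
        # TAA spanning a codon boundary is not an in-frame stop
        seq = "AT" + "TAA" + "G" + "ATG" * 2
        assert len(seq) % 3 == 0
        ok, _ = frame_stop_filter(seq)
        assert ok

    def test_frame_offset_shifts_the_reading_frame(self):
        seq = "G" + "ATG" * 10 + "TAA" + "GG"
        assert not frame_stop_filter(seq, frame_offset=1)[0]

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValidationError):
            frame_stop_filter("ACGX" * 3)

    def test_agrees_with_biopython_translation_on_references(self):
        from Bio.Seq import Seq

        for _, seq in gen_reference_orfs(10, seed=2):
            ok, _ = frame_stop_filter(seq)
            assert ok == ("*" not in Seq(seq).translate(table=11))


class TestLengthWindow:
    @pytest.mark.parametrize(
        "length, primer, expected",
        [
            (465, "mb661R", True),
            (474, "mb661R", True),
            (464, "mb661R", False),
            (475, "mb661R", False),
            (492, "A682R", True),
            (495, "A682R", True),
            (496, "A682R", False),
        ],
    )
    def test_inclusive_windows(self, length, primer, expected):
        assert length_window_filter("A" * length, primer) is expected

    def test_unknown_primer_set_rejected(self):
        with pytest.raises(ValidationError):
            length_window_filter("A" * 465, "nifH")


class TestTaxonomy:
    @pytest.fixture()
    def db(self):
        return ReferenceDB(gen_reference_orfs(3, seed=5))

    def test_identical_query_scores_100(self, db):
        result = assign_taxonomy(db.entries[1][1], db)
        assert result.taxonomy == db.entries[1][0]
        assert result.percent_identity == pytest.approx(100.0)
        assert not result.tie

    def test_single_substitution_identity(self, db):
        ref = db.entries[0][1]
        substitute = "C" if ref[10] != "C" else "G"
        query = ref[:10] + substitute + ref[11:]
        result = assign_taxonomy(query, db)
        assert result.taxonomy == db.entries[0][0]
        assert result.percent_identity == pytest.approx(100.0 * 464 / 465, abs=1e-6)

    def test_exact_tie_broken_by_database_order(self):
        seq = gen_reference_orfs(1, seed=6)[0][1]
        db = ReferenceDB([("taxA", seq), ("taxB", seq)])
        result = assign_taxonomy(seq, db)
        assert result.taxonomy == "taxA"
        assert result.tie

    def test_empty_database_rejected(self):
        with pytest.raises(ValidationError):
            ReferenceDB([])


class TestRelativeAbundance:
    def test_simple_row_normalization(self):
        table = OTUTable(pd.DataFrame([[10, 30, 60]], index=["s1"], columns=list("abc")))
        rel, empty = to_relative_abundance(table)
        np.testing.assert_allclose(rel.counts.loc["s1"], [0.1, 0.3, 0.6])
        assert empty == []

    def test_all_zero_row_stays_zero_and_is_flagged(self):
        table = OTUTable(
            pd.DataFrame([[1, 1], [0, 0]], index=["s1", "s2"], columns=["a", "b"])
        )
        rel, empty = to_relative_abundance(table)
        assert empty == ["s2"]
        assert (rel.counts.loc["s2"] == 0).all()
        assert rel.counts.loc["s1"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            OTUTable(pd.DataFrame([[-1, 2]], columns=["a", "b"]))


class TestDenoise:
    def test_strict_threshold_decision(self):
        # 0.0009 zeroed, exactly 0.001 retained
        counts = pd.DataFrame([[9, 10, 9981]], index=["s1"], columns=list("abc"))
        result = denoise(OTUTable(counts), threshold=1e-3)
        assert result.table.counts.loc["s1", "a"] == 0
        assert result.table.counts.loc["s1", "b"] == 10
        assert result.removed_read_fraction == pytest.approx(9 / 10000)
        assert result.n_zeroed_entries == 1

    def test_relative_abundances_recomputed_on_survivors(self):
        counts = pd.DataFrame([[9, 10, 9981]], index=["s1"], columns=list("abc"))
        result = denoise(OTUTable(counts), threshold=1e-3)
        assert result.relative.counts.loc["s1"].sum() == pytest.approx(1.0)
        assert result.relative.counts.loc["s1", "b"] == pytest.approx(10 / 9991)

    def test_removed_fraction_stays_under_the_expected_band(self):
        # table built so ~3% of reads sit below the threshold
        rng = np.random.default_rng(8)
        common = rng.integers(500, 2000, size=(8, 20))
        rare = rng.integers(1, 8, size=(8, 30))  # each < 0.1% of ~20k reads
        counts = pd.DataFrame(np.hstack([common, rare]))
        counts.columns = [f"otu{i}" for i in range(50)]
        result = denoise(OTUTable(counts), threshold=1e-3)
        assert 0.0 < result.removed_read_fraction < 0.05

    def test_denoise_idempotent_when_no_entry_crosses_after_renormalization(self):
        counts = pd.DataFrame([[5, 100, 9895]], index=["s1"], columns=list("abc"))
        once = denoise(OTUTable(counts), 1e-3)
        twice = denoise(once.table, 1e-3)
        pd.testing.assert_frame_equal(once.table.counts, twice.table.counts)
        assert twice.removed_read_fraction == 0.0

    def test_threshold_bounds_enforced(self):
        counts = pd.DataFrame([[1, 2]], columns=["a", "b"])
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValidationError):
                denoise(OTUTable(counts), bad)


class TestLogNormalize:
    @pytest.mark.parametrize("base", [2.0, 10.0, np.e])
    def test_unit_value_maps_to_one(self, base):
        assert log_normalize(np.array([1.0]), base)[0] == pytest.approx(1.0)

    def test_zero_maps_to_zero_and_log2_of_8(self):
        out = log_normalize(np.array([0.0, 8.0]), base=2.0)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(4.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(min_value=1e-6, max_value=1e6), st.floats(min_value=1e-6, max_value=1e6))
    def test_monotone_on_positive_values(self, a, b):
        lo, hi = sorted([a, b])
        out = log_normalize(np.array([lo, hi]), base=2.0)
        assert out[0] <= out[1]

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            log_normalize(np.array([-1.0, 2.0]))

    def test_dataframe_round_trips_labels(self):
        df = pd.DataFrame([[0, 2], [4, 1]], index=["s1", "s2"], columns=["a", "b"])
        out = log_normalize(df, base=2.0)
        assert list(out.columns) == ["a", "b"]
        assert out.loc["s2", "a"] == pytest.approx(3.0)
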