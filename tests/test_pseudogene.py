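"""Stop counting under the invertebrate mitochondrial code, frame and
indel detection, GC statistics, and the injector/screen round trip."""

import numpy as np
import pytest
from Bio.Seq import Seq

from barcodekit.pseudogene import (
    best_reading_frame,
    count_stops,
    detect_frameshift,
    gc_correlation,
    gc_percent,
    gc_stats,
    screen_pseudogenes,
)
from barcodekit.records import SequenceRecord
from barcodekit.synthetic import SimConfig, generate_dataset, inject_pseudogene


class TestCountStops:
    @pytest.mark.parametrize(
        "seq, frame, expected",
        [
            ("ATGTTATAA", 1, 1),   # TAA in frame
            ("ATGAGAAGG", 1, 0),   # AGA/AGG are serine in table 5
            ("ATGTGATAA", 1, 1),   # TGA is tryptophan, TAA stops
            ("TTAATAG", 2, 2),     # frame 2 reads TAA TAG: two stops
            ("ATGTAA", 3, 0),      # frame 3: GTA + trailing partial
        ],
    )
    def test_examples(self, seq, frame, expected):
        assert count_stops(seq, frame) == expected

    def test_matches_codon_walk(self):
        rng = np.random.default_rng(4)
        stops = {"TAA", "TAG"}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 60))))
            for frame in (1, 2, 3):
                sub = seq[frame - 1 :]
                manual = sum(
                    sub[k : k + 3] in stops for k in range(0, len(sub) - 2, 3)
                )
                assert count_stops(seq, frame) == manual


class TestBestFrame:
    def test_clean_synthetic_is_frame_one(self, small_dataset):
        _, records, _ = small_dataset
        for rec in records["COI"][:5]:
            frame, n = best_reading_frame(rec.residues)
            assert (frame, n) == (1, 0)

    def test_all_a_sequence(self):
        assert best_reading_frame("A" * 30) == (1, 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            best_reading_frame("ACG")


class TestDetectFrameshift:
    def test_expected_length_no_flag(self):
        assert not detect_frameshift("A" * 658, reference_length_mod3=658)

    def test_one_base_deletion_flagged(self):
        assert detect_frameshift("A" * 657, reference_length_mod3=658)

    def test_in_frame_gap_run_not_flagged(self):
        seq = "A" * 30 + "---" + "A" * 28  # 58 bases + 3-gap: mod3 matches 61
        assert not detect_frameshift(seq, reference_length_mod3=58, aligned=True)

    def test_out_of_frame_gap_run_flagged(self):
        seq = "A" * 30 + "--" + "A" * 28
        assert detect_frameshift(seq, reference_length_mod3=58, aligned=True)


class TestGCStats:
    @pytest.mark.parametrize("seq, expected", [("GGCC", 100.0), ("ATGC", 50.0), ("AATT", 0.0)])
    def test_gc_percent(self, seq, expected):
        assert gc_percent(seq) == expected

    def test_ambiguity_codes_excluded(self):
        assert gc_percent("GCNN") == 100.0

    def test_invariant_under_reverse_and_complement(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        assert gc_percent(seq[::-1]) == gc_percent(seq)
        assert gc_percent(str(Seq(seq).complement())) == gc_percent(seq)

    def test_shifted_record_is_only_outlier(self, small_dataset):
        _, records, _ = small_dataset
        cohort = [r.copy(qualities=None) for r in records["COI"]]
        shifted = inject_pseudogene(cohort[0], "gc_shift", seed=99, gc_delta=0.12)
        stats = gc_stats([shifted] + cohort[1:], z_cut=3.0)
        outliers = set(
            stats.per_sequence[stats.per_sequence["gc_outlier"]]["specimen_id"]
        )
        assert outliers == {shifted.specimen_id}

    def test_zero_base_sequence_excluded(self):
        recs = [
            SequenceRecord("a", "COI", "ACGT"),
            SequenceRecord("b", "COI", "ACGG"),
            SequenceRecord("c", "COI", "NN--"),
        ]
        stats = gc_stats(recs)
        assert stats.excluded == ["c"]
        assert len(stats.per_sequence) == 2


class TestGCCorrelation:
    def _recs(self, marker, values):
        out = []
        for i, v in enumerate(values):
            n_gc = int(round(v * 100))
            out.append(SequenceRecord(f"s{i}", marker, "G" * n_gc + "A" * (100 - n_gc)))
        return out

    def test_identical_vectors_r_one(self):
        vals = [0.3, 0.4, 0.5, 0.6]
        r = gc_correlation(self._recs("COI", vals), self._recs("16S", vals))
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        r = gc_correlation(self._recs("COI", [0.4] * 4), self._recs("16S", [0.3, 0.4, 0.5, 0.6]))
        assert r is None

    def test_shared_driver_gives_positive_r(self):
        recs, _ = generate_dataset(SimConfig(n_species=10, seqs_per_species=3, seed=23))
        r = gc_correlation(recs["COI"], recs["16S"])
        assert r > 0.5

    def test_independent_gc_within_permutation_envelope(self):
        """Random independent GC vectors: |r| stays inside the null
        envelope from shuffling one marker's values."""
        rng = np.random.default_rng(31)
        x = rng.uniform(0.3, 0.5, 40)
        y = rng.uniform(0.3, 0.5, 40)
        r = gc_correlation(self._recs("COI", x), self._recs("16S", y))
        null = []
        for _ in range(200):
            null.append(abs(np.corrcoef(x, rng.permutation(y))[0, 1]))
        assert abs(r) <= np.quantile(null, 0.99)


class TestRoundTrip:
    def test_injected_flagged_clean_not(self, small_dataset):
        _, records, _ = small_dataset
        clean = [r.copy(qualities=None) for r in records["COI"]]
        injected = []
        for i, mode in enumerate(["stop", "frameshift", "gc_shift"] * 2):
            rec = clean[i * 3].copy(specimen_id=f"PSEUDO-{i}-{mode}")
            injected.append((mode, inject_pseudogene(rec, mode, seed=i, keep_alignment=True)))
        cohort = [rec for _, rec in injected] + clean
        report = screen_pseudogenes(cohort, records["16S"])
        frame = report.per_sequence.set_index("specimen_id")
        for mode, rec in injected:
            flags = frame.loc[rec.specimen_id, "flags"]
            expected = {"stop": "stop", "frameshift": "indel", "gc_shift": "gc_outlier"}[mode]
            assert expected in flags
        for rec in clean:
            flags = frame.loc[rec.specimen_id, "flags"]
            assert "stop" not in flags and "indel" not in flags
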