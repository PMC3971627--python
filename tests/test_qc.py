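import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccsqc import simulate as sim
from ccsqc.qc import (
    AmpliconDesign,
    BarcodeMatch,
    Orientation,
    QCParams,
    apply_filters,
    has_zero_quality,
    homopolymer_window_size,
    match_barcode,
    max_homopolymer_run,
    min_windowed_mean_quality,
    orient_read,
)
from ccsqc.seqio import SeqRecord, reverse_complement
from ccsqc.simulate import SimParams


def brute_force_min_window_mean(quals, w):
    return min(
        sum(quals[i : i + w]) / w for i in range(len(quals) - w + 1)
    )


def brute_force_max_run(seq):
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


class TestZeroQuality:
    def test_positive_and_negative(self):
        assert not has_zero_quality(SeqRecord("r", "ACGT", [1, 5, 9, 93]))
        assert has_zero_quality(SeqRecord("r", "ACGT", [1, 0, 9, 93]))

    def test_planted_fraction_recovered_exactly(self, design):
        p = SimParams(seed=30, n_templates=10, chimera_fraction=0.0)
        defects = sim.CcsDefects(zero_quality_fraction=0.1)
        records, truths = sim.make_ccs_library(design, p, 100, defects=defects)
        flagged = [has_zero_quality(r) for r in records]
        truth = ["zero_quality" in t.defects for t in truths]
        assert flagged == truth
        assert sum(flagged) == 10


class TestHomopolymers:
    @pytest.mark.parametrize("seq,run", [("ACGT", 1), ("AAAATT", 4), ("A", 1)])
    def test_examples(self, seq, run):
        assert max_homopolymer_run(seq) == run

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            max_homopolymer_run("")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        assert max_homopolymer_run(seq) == brute_force_max_run(seq)

    def test_window_size_rule(self):
        # runs >=2 in AAAACCGT: {4, 2}, mean 3, window 6
        assert homopolymer_window_size("AAAACCGT", min_run=2) == 6
        assert homopolymer_window_size("AAAAAA", min_run=2) == 12
        # no qualifying run: fallback/floor
        assert homopolymer_window_size("ACGTACGT", min_run=2) == 4


class TestWindowedQuality:
    def test_limiting_windows(self):
        quals = [30, 10, 50, 20]
        assert min_windowed_mean_quality(quals, 1) == 10
        assert min_windowed_mean_quality(quals, 4) == pytest.approx(27.5)

    def test_hand_example(self):
        assert min_windowed_mean_quality([30, 30, 5, 5, 30, 30], 2) == 5.0

    def test_window_too_large_is_error(self):
        with pytest.raises(ValueError):
            min_windowed_mean_quality([1, 2], 3)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_matches_brute_force_at_every_window(self, seed):
        # the value is deliberately not asserted monotone in w: it is not
        # ([0,100,0]: w=2 gives 50, w=3 gives 33.3)
        rng = np.random.default_rng(seed)
        quals = rng.integers(0, 94, int(rng.integers(5, 60))).tolist()
        lo = min(quals)
        for w in range(1, len(quals) + 1):
            v = min_windowed_mean_quality(quals, w)
            assert v == pytest.approx(brute_force_min_window_mean(quals, w))
            assert v >= lo - 1e-9


def _intact_read(design, rng, rid="read"):
    p = SimParams(seed=int(rng.integers(2**20)), n_templates=1, chimera_fraction=0.0)
    mols = sim.make_library(sim.make_templates(p, rng), design, p, rng, n_molecules=1)
    seq = mols[0].construct
    return SeqRecord(rid, seq, np.full(len(seq), 60))


class TestOrientation:
    def test_forward_read_unchanged(self, design, rng):
        read = _intact_read(design, rng)
        oriented = orient_read(read, design)
        assert oriented.strand is Orientation.PLUS
        assert oriented.record.seq == read.seq

    def test_reverse_read_flipped_and_idempotent(self, design, rng):
        read = _intact_read(design, rng)
        flipped = reverse_complement(read)
        oriented = orient_read(flipped, design)
        assert oriented.strand is Orientation.MINUS
        assert oriented.record.seq == read.seq
        again = orient_read(oriented.record, design)
        assert again.strand is Orientation.PLUS
        assert again.record.seq == read.seq

    def test_primerless_read_not_found(self, design, rng):
        junk = "".join(rng.choice(list("ACGT"), 200))
        oriented = orient_read(SeqRecord("j", junk, np.full(200, 60)), design)
        assert oriented.strand is Orientation.NOT_FOUND

    def test_mixed_strand_library_unified(self, design):
        p = SimParams(seed=31, n_templates=5, chimera_fraction=0.0,
                      reverse_strand_fraction=0.5)
        records, truths = sim.make_ccs_library(design, p, 100)
        n_minus = 0
        for rec, truth in zip(records, truths):
            oriented = orient_read(rec, design)
            assert oriented.strand in (Orientation.PLUS, Orientation.MINUS)
            n_minus += oriented.strand is Orientation.MINUS
            label = match_barcode(oriented.record, design)
            assert label == truth.barcodes[0]
        assert 20 <= n_minus <= 80  # both strands actually exercised


class TestBarcodes:
    def test_exact_and_one_mismatch(self, design, rng):
        read = _intact_read(design, rng)
        assert match_barcode(read, design) in design.barcodes
        mutated = "G" + read.seq[1:] if read.seq[0] != "G" else "T" + read.seq[1:]
        lab = match_barcode(SeqRecord("m", mutated, np.full(len(mutated), 60)), design)
        assert lab in design.barcodes

    def test_equidistant_barcodes_ambiguous(self):
        design = AmpliconDesign(
            fwd_primer="ACGTACGTAC",
            rev_primer="TTGCATGCAT",
            barcodes={"a": "AAAA", "b": "AAAT"},
            expected_length=60,
            length_tolerance=10,
        )
        # prefix AAAG is at distance 1 from both barcodes
        seq = "AAAG" + "ACGTACGTAC" + "C" * 30
        assert (
            match_barcode(SeqRecord("r", seq, np.full(len(seq), 60)), design)
            is BarcodeMatch.AMBIGUOUS
        )

    def test_distant_prefix_unassigned(self, design):
        seq = "GGGGGGGGGGGGGGGG" + design.fwd_primer.replace("M", "A") + "A" * 40
        assert (
            match_barcode(SeqRecord("r", seq, np.full(len(seq), 60)), design)
            is BarcodeMatch.UNASSIGNED
        )


class TestFilterBattery:
    def _clean(self, design, rng, rid):
        return _intact_read(design, rng, rid)

    def test_designed_fixture_per_filter_accounting(self, design, rng):
        params = QCParams(window_threshold=15.0)
        reads = []
        expected = {}

        clean1 = self._clean(design, rng, "clean1")
        clean2 = self._clean(design, rng, "clean2")
        reads += [(clean1, False), (clean2, False)]

        r = self._clean(design, rng, "zeroq")
        r.quals[100] = 0
        reads.append((r, False))
        expected["zeroq"] = ["zero_quality"]

        r = self._clean(design, rng, "ambig")
        r.seq = r.seq[:200] + "N" + r.seq[201:]
        reads.append((r, False))
        expected["ambig"] = ["ambiguous_base"]

        r = self._clean(design, rng, "lowavg")
        r.quals[:] = 20
        reads.append((r, False))
        expected["lowavg"] = ["avg_quality"]

        r = self._clean(design, rng, "lowwin")
        r.quals[300:312] = 5
        reads.append((r, False))
        expected["lowwin"] = ["window_quality"]

        r = self._clean(design, rng, "homop")
        r.seq = r.seq[:100] + "A" * 9 + r.seq[109:]
        reads.append((r, False))
        expected["homop"] = ["homopolymer"]

        r = self._clean(design, rng, "short")
        cut = design.expected_length // 2
        r = SeqRecord("short", r.seq[:cut] + r.seq[cut + 60 :],
                      np.concatenate([r.quals[:cut], r.quals[cut + 60 :]]))
        reads.append((r, False))
        expected["short"] = ["length"]

        r = self._clean(design, rng, "badprimer")
        s = list(r.seq)
        s[17] = "C" if s[17] != "C" else "G"   # two edits inside fwd primer
        s[19] = "C" if s[19] != "C" else "G"
        r = SeqRecord("badprimer", "".join(s), r.quals)
        reads.append((r, False))
        expected["badprimer"] = ["primer"]

        r = self._clean(design, rng, "badbarcode")
        s = list(r.seq)
        s[0] = "C" if s[0] != "C" else "G"
        s[2] = "C" if s[2] != "C" else "G"
        s[4] = "C" if s[4] != "C" else "G"
        r = SeqRecord("badbarcode", "".join(s), r.quals)
        reads.append((r, False))
        expected["badbarcode"] = ["barcode"]

        r = self._clean(design, rng, "pcrchimera")
        reads.append((r, True))  # normal-size read flagged by the external hook
        expected["pcrchimera"] = ["chimera"]

        decisions = {
            rec.id: apply_filters(rec, design, params, verdict)
            for rec, verdict in reads
        }
        survivors = [d for d in decisions.values() if d.passed]
        assert {d.read_id for d in survivors} == {"clean1", "clean2"}
        for rid, fails in expected.items():
            assert decisions[rid].failures == fails, rid
        counts = {}
        for d in decisions.values():
            for f in d.failures:
                counts[f] = counts.get(f, 0) + 1
        assert all(v == 1 for v in counts.values())
        assert len(counts) == 9

    def test_multi_failure_read_lists_all(self, design, rng):
        r = self._clean(design, rng, "double")
        r.quals[5] = 0
        r.seq = r.seq[:100] + "G" * 9 + r.seq[109:]
        d = apply_filters(r, design, QCParams(), False)
        assert not d.passed
        assert "zero_quality" in d.failures and "homopolymer" in d.failures

    def test_all_pass_read(self, design, rng):
        d = apply_filters(self._clean(design, rng, "ok"), design, QCParams(), False)
        assert d.passed and d.failures == []

    def test_average_filter_masks_what_window_filter_catches(self, design, rng):
        """High scores elsewhere mask a low-quality stretch in the mean:
        the average filter passes the read, the rolling window removes it."""
        r = self._clean(design, rng, "masked")
        r.quals[:] = 90
        r.quals[250:262] = 3
        assert r.mean_quality > 25
        without_window = apply_filters(r, design, QCParams(), False)
        assert "avg_quality" not in without_window.failures
        assert without_window.passed
        with_window = apply_filters(
            r, design, QCParams(window_threshold=20.0), False
        )
        assert with_window.failures == ["window_quality"]
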