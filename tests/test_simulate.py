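import math

import numpy as np
import pytest

from ccsqc import simulate as sim
from ccsqc.ccs import edit_distance
from ccsqc.chimera import scan_motifs
from ccsqc.seqio import revcomp
from ccsqc.simulate import (
    LibraryMolecule,
    SimParams,
    corrupt,
    make_library,
    make_templates,
    simulate_long_read,
)


def longest_run(seq: str) -> int:
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def runs_ge(seq: str, k: int) -> int:
    count = 0
    cur = 1
    for a, b in zip(seq, seq[1:]):
        if a == b:
            cur += 1
        else:
            if cur >= k:
                count += 1
            cur = 1
    return count + (1 if cur >= k else 0)


class TestTemplates:
    def test_deterministic_under_seed(self):
        p = SimParams(seed=7, n_templates=5)
        assert make_templates(p) == make_templates(p)

    def test_planted_homopolymers(self):
        p = SimParams(seed=3, n_templates=20, homopolymer_boost=3)
        for tmpl in make_templates(p):
            assert runs_ge(tmpl, 4) >= 3
            assert longest_run(tmpl) <= 8

    def test_gc_composition(self):
        p = SimParams(seed=5, n_templates=10, gc_fraction=0.6)
        for tmpl in make_templates(p):
            gc = sum(tmpl.count(b) for b in "GC") / len(tmpl)
            assert abs(gc - 0.6) < 0.05

    def test_gc_zero_means_no_strong_bases(self):
        p = SimParams(seed=5, n_templates=5, gc_fraction=0.0)
        for tmpl in make_templates(p):
            assert set(tmpl) <= {"A", "T"}

    def test_short_template_rejected(self):
        with pytest.raises(ValueError):
            SimParams(seed=1, template_length=40)


class TestLibrary:
    def test_no_chimeras_means_intact_lengths(self, design):
        p = SimParams(seed=1, n_templates=10, chimera_fraction=0.0)
        mols = make_library(make_templates(p), design, p, n_molecules=50)
        for mol in mols:
            assert mol.truth.order == 1
            assert abs(len(mol) - design.expected_length) <= design.length_tolerance

    def test_chimera_count_in_binomial_interval(self, design):
        p = SimParams(seed=9, n_templates=10, chimera_fraction=0.5)
        mols = make_library(make_templates(p), design, p, n_molecules=1000)
        n_chim = sum(m.truth.is_concatemer for m in mols)
        # 99% binomial interval around 500 at n=1000, p=0.5
        half = 2.576 * math.sqrt(1000 * 0.25)
        assert abs(n_chim - 500) <= half

    def test_concatemer_order2_has_two_of_each_primer(self, design):
        p = SimParams(seed=4, n_templates=10, chimera_fraction=1.0)
        mols = make_library(make_templates(p), design, p, n_molecules=5)
        from ccsqc.seqio import SeqRecord

        for mol in mols:
            assert mol.truth.order == 2
            rec = SeqRecord("m", mol.construct, np.full(len(mol.construct), 50))
            hits = scan_motifs(rec, design, max_mm=0)
            names = [h.motif for h in hits if not h.motif.startswith("barcode")]
            assert names.count("fwd_primer") == 2
            assert names.count("rev_primer") == 2

    def test_order_beyond_template_pool_rejected(self, design):
        p = SimParams(
            seed=1, n_templates=2, chimera_fraction=1.0, concatemer_order_range=(2, 5)
        )
        with pytest.raises(ValueError):
            make_library(make_templates(p)[:2], design, p, n_molecules=1)


class TestLongReads:
    def test_zero_error_passes_match_molecule(self, design):
        p = SimParams(seed=2, n_templates=2, per_pass_error_rate=0.0, chimera_fraction=0.0)
        rng = np.random.default_rng(2)
        mol = make_library(make_templates(p, rng), design, p, rng, n_molecules=1)[0]
        read, truth = simulate_long_read(mol, design.adapter, p, rng)
        # every adapter-delimited fragment equals the molecule on one strand
        body = read.seq
        for frag in body.split(design.adapter):
            frag = frag.replace(revcomp(design.adapter), "\n")
            for piece in frag.split("\n"):
                if len(piece) == len(mol.construct):
                    assert piece in (mol.construct, revcomp(mol.construct))

    def test_single_pass_error_load_within_binomial_3_sigma(self, design):
        p = SimParams(seed=6, n_templates=1, chimera_fraction=0.0)
        rng = np.random.default_rng(6)
        tmpl = make_templates(p, rng)[0]
        d = edit_distance(corrupt(tmpl, 0.10, 0.5, rng), tmpl)
        mean = 0.10 * len(tmpl)
        sigma = math.sqrt(len(tmpl) * 0.10 * 0.90)
        assert abs(d - mean) <= 3 * sigma

    def test_mean_error_rate_converges(self):
        # law of large numbers over 200 independently corrupted passes
        rng = np.random.default_rng(8)
        tmpl = make_templates(SimParams(seed=8, n_templates=1), rng)[0]
        rates = [
            edit_distance(corrupt(tmpl, 0.10, 0.5, rng), tmpl) / len(tmpl)
            for _ in range(200)
        ]
        sem = np.std(rates) / math.sqrt(len(rates))
        mean = float(np.mean(rates))
        # edit distance lower-bounds the number of error events (nearby
        # indels and substitutions can merge into cheaper alignments), so
        # the mean sits just below the nominal rate but never above it
        assert mean <= 0.10 + 3 * sem
        assert mean >= 0.10 * 0.9

    def test_long_read_quality_averages_phred_of_error_rate(self, design):
        p = SimParams(seed=3, n_templates=1, chimera_fraction=0.0)
        rng = np.random.default_rng(3)
        mol = make_library(make_templates(p, rng), design, p, rng, n_molecules=1)[0]
        read, _ = simulate_long_read(mol, design.adapter, p, rng)
        assert 8.0 <= read.mean_quality <= 12.0
        assert read.quals.max() <= 15

    def test_deterministic_given_seed(self, design):
        out = []
        for _ in range(2):
            p = SimParams(seed=123, n_templates=3, chimera_fraction=0.1)
            records, truths = sim.make_ccs_library(design, p, 20)
            out.append([(r.id, r.seq, tuple(r.quals)) for r in records])
        assert out[0] == out[1]


class TestCcsLibraryDefects:
    def test_planted_defect_bookkeeping(self, design):
        p = SimParams(seed=10, n_templates=10, chimera_fraction=0.0)
        defects = sim.CcsDefects(zero_quality_fraction=0.1, low_window_fraction=0.05)
        records, truths = sim.make_ccs_library(design, p, 200, defects=defects)
        n_zero = sum("zero_quality" in t.defects for t in truths)
        n_win = sum("low_window" in t.defects for t in truths)
        assert n_zero == 20
        assert n_win == 10
        for rec, truth in zip(records, truths):
            assert ((rec.quals == 0).any()) == ("zero_quality" in truth.defects)
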