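"""Synthetic CCS amplicon libraries and raw multi-pass long reads.

The generator reproduces the statistical structure that makes circular
consensus sequencing work and that the QC stages must handle:

* templates with planted homopolymer runs (the quality-dip hotspots of ccs
  reads);
* barcoded, primered constructs loaded in mixed strand orientation
  (the instrument sequences either strand);
* raw long reads made of alternating-strand passes separated by hairpin
  adapter copies, each pass independently corrupted with uniformly placed
  substitution/indel errors — "randomly distributed errors" is precisely
  the property that lets a plurality consensus cancel them;
* ligation concatemers: 2+ complete barcoded amplicons joined end to end,
  the library-preparation artifact that PCR-chimera detectors miss.

Every molecule carries a truth record sufficient to score downstream
classifiers exactly.  All generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .qc import AmpliconDesign
from .seqio import MAX_PHRED, SeqRecord, error_prob_to_phred, revcomp

#: Synthetic stand-in for the SMRTbell hairpin-loop adapter (45 nt).  The
#: real adapter sequence is proprietary to the platform; only its role
#: (a fixed separator between passes) matters here, and it is configurable
#: everywhere it is consumed.
DEFAULT_ADAPTER = "ATCTCTCTCTTTTCCTCCTCCTCCGTTGTTGTTGTTGAGAGAGAT"

_BASES = "ACGT"


@dataclass
class SimParams:
    """Knobs of the synthetic library.

    Defaults describe a bacterial V1-V3-style run: 515 bp inserts, ~0.10
    per-base error per pass (raw long-read quality averaging around Phred
    10), ~9.5 passes per long read, half the molecules loaded on the minus
    strand, and ~2% of molecules being ligation concatemers.
    """

    n_templates: int = 20
    template_length: int = 515
    gc_fraction: float = 0.5
    homopolymer_boost: int = 3
    per_pass_error_rate: float = 0.10
    indel_fraction_of_errors: float = 0.5
    passes_mean: float = 9.5
    chimera_fraction: float = 0.02
    concatemer_order_range: tuple[int, int] = (2, 2)
    reverse_strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "per_pass_error_rate",
            "indel_fraction_of_errors",
            "chimera_fraction",
            "reverse_strand_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_templates < 1 or self.template_length < 50:
            raise ValueError("need n_templates >= 1 and template_length >= 50")
        lo, hi = self.concatemer_order_range
        if lo < 2 or hi < lo:
            raise ValueError("concatemer orders must satisfy 2 <= lo <= hi")
        if self.passes_mean <= 0:
            raise ValueError("passes_mean must be positive")


@dataclass
class MoleculeTruth:
    """Provenance of one library molecule (and later of its reads)."""

    molecule_id: str
    template_indices: list[int]
    barcodes: list[str]
    unit_strands: list[str]
    order: int
    strand: str = "+"
    defects: list[str] = field(default_factory=list)

    @property
    def is_concatemer(self) -> bool:
        return self.order >= 2


@dataclass
class LibraryMolecule:
    construct: str
    truth: MoleculeTruth

    def __len__(self) -> int:
        return len(self.construct)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """n bases with exact GC composition round(gc*n), randomly permuted."""
    n_gc = int(round(gc * n))
    strong = rng.choice(list("GC"), size=n_gc)
    weak = rng.choice(list("AT"), size=n - n_gc)
    bases = np.concatenate([strong, weak])
    rng.shuffle(bases)
    return list(bases)


def _break_long_runs(bases: list[str], max_run: int, gc: float, rng) -> None:
    """Substitute every (max_run+1)-th base of over-long runs in place."""
    alphabet = "AT" if gc == 0.0 else ("GC" if gc == 1.0 else _BASES)
    i = 0
    n = len(bases)
    while i < n:
        j = i
        while j < n and bases[j] == bases[i]:
            j += 1
        if j - i > max_run:
            for k in range(i + max_run, j, max_run + 1):
                choices = [
                    b
                    for b in alphabet
                    if b != bases[k]
                    and (k + 1 >= n or b != bases[k + 1])
                    and b != bases[k - 1]
                ]
                bases[k] = choices[int(rng.integers(len(choices)))] if choices else bases[k]
        i = j


def make_templates(params: SimParams, rng: np.random.Generator | None = None) -> list[str]:
    """Generate ``n_templates`` homopolymer-bearing template sequences.

    Each template has the requested exact GC composition (before run
    editing), at least ``homopolymer_boost`` planted runs of length 4-8,
    and no run longer than 8 elsewhere (natural over-long runs are broken
    so the homopolymer filter's truth stays the planted one).
    """
    if params.template_length < 50:
        raise ValueError("template_length must be >= 50")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    L = params.template_length
    gc = params.gc_fraction
    templates = []
    for _ in range(params.n_templates):
        bases = _random_bases(rng, L, gc)
        _break_long_runs(bases, 8, gc, rng)
        # Plant runs at well-separated slots so plants never merge.
        n_slots = max(params.homopolymer_boost, (L - 20) // 14)
        slot_starts = np.linspace(10, L - 20, num=n_slots).astype(int)
        chosen = rng.choice(n_slots, size=params.homopolymer_boost, replace=False)
        for slot in chosen:
            run_len = int(rng.integers(4, 9))
            if gc == 0.0:
                base = str(rng.choice(list("AT")))
            elif gc == 1.0:
                base = str(rng.choice(list("GC")))
            else:
                base = str(rng.choice(list("GC"))) if rng.random() < gc else str(
                    rng.choice(list("AT"))
                )
            start = int(slot_starts[slot])
            bases[start : start + run_len] = [base] * run_len
            # keep the planted run maximal but not over-long
            if start > 0 and bases[start - 1] == base:
                bases[start - 1] = _other_base(base, gc, rng)
            end = start + run_len
            if end < L and bases[end] == base:
                bases[end] = _other_base(base, gc, rng)
        _break_long_runs(bases, 8, gc, rng)
        templates.append("".join(bases))
    return templates


def _other_base(base: str, gc: float, rng) -> str:
    alphabet = "AT" if gc == 0.0 else ("GC" if gc == 1.0 else _BASES)
    choices = [b for b in alphabet if b != base]
    return choices[int(rng.integers(len(choices)))]


def _resolve_iupac(motif: str, rng: np.random.Generator) -> str:
    """Instantiate degenerate primer positions with concrete bases.

    A synthesised amplicon carries the primer with one concrete base at
    each degenerate position; the draw is uniform over the expansion.
    """
    from ._motif import IUPAC

    return "".join(
        b if b in _BASES else IUPAC[b][int(rng.integers(len(IUPAC[b].replace("N", ""))))]
        for b in motif
    )


def _unit(template: str, barcode: str, design: AmpliconDesign, rng) -> str:
    from ._motif import revcomp_iupac

    return (
        barcode
        + _resolve_iupac(design.fwd_primer, rng)
        + template
        + _resolve_iupac(revcomp_iupac(design.rev_primer), rng)
        + barcode
    )


def make_library(
    templates: list[str],
    design: AmpliconDesign,
    params: SimParams,
    rng: np.random.Generator | None = None,
    n_molecules: int | None = None,
) -> list[LibraryMolecule]:
    """Assemble barcoded library molecules, a fraction of them concatemers.

    Each molecule is an intact construct (order 1) or, with probability
    ``chimera_fraction``, a ligation concatemer of 2+ complete units drawn
    from distinct templates.  Units after the first are ligated in random
    orientation, as blunt adapter ligation has no strand preference.  The
    truth record keeps template indices, barcode labels, unit strands and
    order for every molecule.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lo, hi = params.concatemer_order_range
    if params.chimera_fraction > 0 and hi > len(templates):
        raise ValueError(
            f"concatemer order up to {hi} requires >= {hi} distinct templates, "
            f"got {len(templates)}"
        )
    labels = list(design.barcodes)
    n = n_molecules if n_molecules is not None else len(templates)
    molecules = []
    for i in range(n):
        is_chimera = rng.random() < params.chimera_fraction
        order = int(rng.integers(lo, hi + 1)) if is_chimera else 1
        idx = [int(t) for t in rng.choice(len(templates), size=order, replace=False)]
        barcodes = [labels[int(rng.integers(len(labels)))] for _ in range(order)]
        strands = ["+"] + [
            "-" if rng.random() < 0.5 else "+" for _ in range(order - 1)
        ]
        parts = []
        for t, bc, strand in zip(idx, barcodes, strands):
            unit = _unit(templates[t], design.barcodes[bc], design, rng)
            parts.append(unit if strand == "+" else revcomp(unit))
        molecules.append(
            LibraryMolecule(
                construct="".join(parts),
                truth=MoleculeTruth(
                    molecule_id=f"mol{i:05d}",
                    template_indices=idx,
                    barcodes=barcodes,
                    unit_strands=strands,
                    order=order,
                ),
            )
        )
    return molecules


def corrupt(
    seq: str,
    error_rate: float,
    indel_fraction: float,
    rng: np.random.Generator,
) -> str:
    """Apply uniformly distributed errors to a sequence.

    Each base independently errs with ``error_rate``; an error is a
    substitution with probability ``1 - indel_fraction``, otherwise an
    insertion or deletion with equal probability.
    """
    if error_rate == 0.0:
        return seq
    out = []
    errs = rng.random(len(seq)) < error_rate
    for i, base in enumerate(seq):
        if not errs[i]:
            out.append(base)
            continue
        r = rng.random()
        if r >= indel_fraction:  # substitution
            out.append(_BASES[(_BASES.index(base) + 1 + int(rng.integers(3))) % 4])
        elif r < indel_fraction / 2:  # insertion (keep base, add one)
            out.append(base)
            out.append(_BASES[int(rng.integers(4))])
        # else: deletion — emit nothing
    return "".join(out)


def _longread_quals(n: int, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base qualities averaging ~ the Phred of the per-pass error rate."""
    center = min(float(MAX_PHRED), error_prob_to_phred(max(error_rate, 1e-9)))
    hi = int(min(MAX_PHRED, round(center) + 5))
    q = np.rint(rng.normal(center, 3.0, size=n)).astype(np.int16)
    return np.clip(q, 0, hi)


def simulate_long_read(
    molecule: LibraryMolecule,
    adapter: str,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[SeqRecord, MoleculeTruth]:
    """One raw polymerase read: alternating-strand passes split by adapters.

    The circularised molecule is traversed ``~Poisson(passes_mean)`` times
    (at least once); traversal i reads the forward construct for even i and
    its reverse complement for odd i, each independently corrupted.  A
    uniformly truncated partial terminal pass follows the last full pass.
    Adapter copies (in matching orientation) separate consecutive passes.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n_full = max(1, int(rng.poisson(params.passes_mean)))
    truth = replace(molecule.truth)
    truth.defects = list(molecule.truth.defects)
    pieces = []
    for i in range(n_full):
        unit = molecule.construct if i % 2 == 0 else revcomp(molecule.construct)
        ad = adapter if i % 2 == 0 else revcomp(adapter)
        if i > 0:
            pieces.append(corrupt(ad, params.per_pass_error_rate, params.indel_fraction_of_errors, rng))
        pieces.append(
            corrupt(unit, params.per_pass_error_rate, params.indel_fraction_of_errors, rng)
        )
    # partial terminal pass, uniformly truncated (may be length 0)
    cut = int(rng.integers(0, len(molecule.construct)))
    if cut > 0:
        unit = molecule.construct if n_full % 2 == 0 else revcomp(molecule.construct)
        ad = adapter if n_full % 2 == 0 else revcomp(adapter)
        pieces.append(corrupt(ad, params.per_pass_error_rate, params.indel_fraction_of_errors, rng))
        pieces.append(
            corrupt(unit[:cut], params.per_pass_error_rate, params.indel_fraction_of_errors, rng)
        )
    seq = "".join(pieces)
    quals = _longread_quals(len(seq), params.per_pass_error_rate, rng)
    record = SeqRecord(f"{truth.molecule_id}/long", seq, quals)
    record.flags["n_full_passes"] = n_full
    return record, truth


@dataclass
class CcsDefects:
    """Fractions of ccs-like reads to plant with specific QC defects."""

    zero_quality_fraction: float = 0.0
    low_window_fraction: float = 0.0
    low_window_length: int = 12
    low_window_quality: int = 5


def simulate_ccs_read(
    molecule: LibraryMolecule,
    params: SimParams,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.0,
    mean_quality: float = 78.0,
) -> tuple[SeqRecord, MoleculeTruth]:
    """A ccs-like read of the molecule: optional residual error, random strand.

    Qualities are drawn around ``mean_quality`` (ccs reads from ~9-10
    passes average in the high 70s), clipped to [1, 93]; quality zero is
    reserved for explicitly planted defects.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    seq = corrupt(seq=molecule.construct, error_rate=error_rate,
                  indel_fraction=params.indel_fraction_of_errors, rng=rng)
    truth = replace(molecule.truth)
    truth.defects = list(molecule.truth.defects)
    if rng.random() < params.reverse_strand_fraction:
        seq = revcomp(seq)
        truth.strand = "-"
    quals = np.clip(
        np.rint(rng.normal(mean_quality, 4.0, size=len(seq))).astype(np.int16),
        1,
        MAX_PHRED,
    )
    record = SeqRecord(f"{truth.molecule_id}/ccs", seq, quals)
    return record, truth


def make_ccs_library(
    design: AmpliconDesign,
    params: SimParams,
    n_molecules: int,
    defects: CcsDefects | None = None,
    error_rate: float = 0.0,
) -> tuple[list[SeqRecord], list[MoleculeTruth]]:
    """End-to-end ccs-read library with truth: templates -> molecules -> reads.

    Defects (zero-quality bases, low-quality windows) are planted in
    disjoint random subsets of the reads and recorded in the truth, so a
    pipeline run can be scored filter by filter.
    """
    rng = np.random.default_rng(params.seed)
    templates = make_templates(params, rng)
    molecules = make_library(templates, design, params, rng, n_molecules=n_molecules)
    records, truths = [], []
    for mol in molecules:
        rec, truth = simulate_ccs_read(mol, params, rng, error_rate=error_rate)
        records.append(rec)
        truths.append(truth)
    if defects is not None:
        n = len(records)
        n_zero = int(round(defects.zero_quality_fraction * n))
        n_window = int(round(defects.low_window_fraction * n))
        chosen = rng.choice(n, size=min(n, n_zero + n_window), replace=False)
        for j in chosen[:n_zero]:
            rec, truth = records[j], truths[j]
            rec.quals[int(rng.integers(len(rec.quals)))] = 0
            truth.defects.append("zero_quality")
        for j in chosen[n_zero : n_zero + n_window]:
            rec, truth = records[j], truths[j]
            w = min(defects.low_window_length, len(rec.quals))
            start = int(rng.integers(0, len(rec.quals) - w + 1))
            rec.quals[start : start + w] = defects.low_window_quality
            truth.defects.append("low_window")
    return records, truths


def write_truth_table(truths: list[MoleculeTruth], handle) -> None:
    """Tab-separated truth: molecule id, templates, barcodes, strand, order."""
    handle.write(
        "molecule_id\ttemplate_indices\tbarcodes\tunit_strands\tstrand\torder\tdefects\n"
    )
    for t in truths:
        handle.write(
            "\t".join(
                [
                    t.molecule_id,
                    ",".join(map(str, t.template_indices)),
                    ",".join(t.barcodes),
                    ",".join(t.unit_strands),
                    t.strand,
                    str(t.order),
                    ",".join(t.defects) or "-",
                ]
            )
            + "\n"
        )


def default_design(adapter: str = DEFAULT_ADAPTER, insert_length: int = 515) -> AmpliconDesign:
    """A bacterial V1-V3-style design: 27F/534R primers, four 16-nt barcodes."""
    fwd = "AGAGTTTGATCMTGGCTCAG"  # 27F, IUPAC M
    rev = "ATTACCGCGGCTGCTGG"  # 534R
    barcodes = {
        "bc01": "TCAGACGATGCGTCAT",
        "bc02": "CTATACATGACTCTGC",
        "bc03": "TACTAGAGTAGCACTC",
        "bc04": "TGTGTATCAGTACATG",
    }
    expected = insert_length + len(fwd) + len(rev) + 2 * 16
    return AmpliconDesign(
        fwd_primer=fwd,
        rev_primer=rev,
        barcodes=barcodes,
        expected_length=expected,
        length_tolerance=50,
        adapter=adapter,
    )
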