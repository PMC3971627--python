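"""PacBio-adjusted amplicon read filters.

Standard amplicon preprocessing (remove reads with ambiguous bases, low
average quality, primer/barcode mismatches, bad length, chimeras) needs
several adjustments for ccs reads:

* PacBio assigns an actual nucleotide — not 'N' — to bases with Phred score
  0, so ambiguous-base culling must instead search the quality scores for
  zeros (:func:`has_zero_quality`).
* ccs quality does not decay positionally; low-quality stretches sit on
  homopolymers, and the read's many very high scores (up to 93) mask them
  in the average.  A rolling-window minimum-mean filter
  (:func:`min_windowed_mean_quality`) with a window spanning twice the
  read's average homopolymer length (:func:`homopolymer_window_size`)
  catches what the average-quality filter cannot.
* The instrument sequences either template strand, so orientation must be
  recognised and unified (:func:`orient_read`) before alignment-based
  analyses or anchored barcode matching.

:func:`apply_filters` evaluates the full battery per read and records every
violated filter, so aggregate reports can attribute multi-failures.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import seqio
from ._motif import best_anchored, hamming_distance, revcomp_iupac
from .seqio import SeqRecord


@dataclass(frozen=True)
class AmpliconDesign:
    """The amplicon construct: primers, barcodes, expected size, adapter.

    A library molecule is ``barcode + fwd_primer + insert +
    revcomp(rev_primer) + barcode``; ``expected_length`` is the length of
    that full construct and ``length_tolerance`` the accepted deviation.
    Primers may carry IUPAC degeneracies.
    """

    fwd_primer: str
    rev_primer: str
    barcodes: dict[str, str]
    expected_length: int
    length_tolerance: int
    adapter: str = ""

    def __post_init__(self) -> None:
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be non-empty")
        if not self.barcodes:
            raise ValueError("barcode table must be non-empty")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("all barcodes must share one length")
        overhead = (
            len(self.fwd_primer) + len(self.rev_primer) + 2 * self.barcode_length
        )
        if self.expected_length <= overhead:
            raise ValueError(
                f"expected_length {self.expected_length} must exceed primer+"
                f"barcode overhead {overhead}"
            )

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @property
    def insert_length(self) -> int:
        return self.expected_length - (
            len(self.fwd_primer) + len(self.rev_primer) + 2 * self.barcode_length
        )


@dataclass
class QCParams:
    """Thresholds for the filter battery.

    Defaults follow the PacBio-adjusted battery: mean quality >= 25, no
    homopolymer run longer than 8 bases, at most 1 mismatch to each primer
    and to a barcode.  The length window defaults to ``expected_length +/-
    length_tolerance`` of the design when unset.  ``window_threshold``
    activates the rolling-window quality filter; it has no defensible
    universal default and is therefore off (None) until set.
    ``window_override`` fixes the window size; otherwise the window is
    derived per read from its homopolymer content (2x mean run length,
    floor ``window_floor``).
    """

    min_avg_qual: float = 25.0
    max_homopolymer_run: int = 8
    min_length: int | None = None
    max_length: int | None = None
    max_primer_mismatches: int = 1
    max_barcode_mismatches: int = 1
    window_threshold: float | None = None
    window_override: int | None = None
    window_min_run: int = 2
    window_floor: int = 4
    primer_search_span: int = 60

    def __post_init__(self) -> None:
        for name in (
            "min_avg_qual",
            "max_homopolymer_run",
            "max_primer_mismatches",
            "max_barcode_mismatches",
            "window_floor",
            "primer_search_span",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length must not exceed max_length")

    def length_window(self, design: AmpliconDesign) -> tuple[int, int]:
        lo = (
            self.min_length
            if self.min_length is not None
            else design.expected_length - design.length_tolerance
        )
        hi = (
            self.max_length
            if self.max_length is not None
            else design.expected_length + design.length_tolerance
        )
        return lo, hi


class Orientation(enum.Enum):
    PLUS = "+"
    MINUS = "-"
    NOT_FOUND = "not_found"
    AMBIGUOUS = "ambiguous"


@dataclass
class OrientedRead:
    record: SeqRecord
    strand: Orientation
    fwd_mismatches: int | None = None


@dataclass
class FilterDecision:
    """Per-read outcome: `passed` iff `failures` is empty."""

    read_id: str
    passed: bool
    failures: list[str]
    barcode: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failures) == 0)


#: Filter names in evaluation (and reporting) order.
FILTER_NAMES = (
    "zero_quality",
    "ambiguous_base",
    "avg_quality",
    "window_quality",
    "homopolymer",
    "length",
    "primer",
    "barcode",
    "chimera",
)


def has_zero_quality(record: SeqRecord) -> bool:
    """True iff any per-base Phred score is 0.

    This, not 'N' counting, is how ambiguous calls are culled in ccs data:
    a zero-quality base still carries an actual nucleotide.
    """
    return bool(len(record.quals)) and bool((record.quals == 0).any())


def homopolymer_runs(seq: str) -> list[int]:
    """Lengths of all maximal runs of identical consecutive nucleotides."""
    if not seq:
        return []
    runs = []
    current = 1
    for a, b in zip(seq, seq[1:]):
        if a == b:
            current += 1
        else:
            runs.append(current)
            current = 1
    runs.append(current)
    return runs


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest homopolymer run; empty sequence is an error."""
    if not seq:
        raise ValueError("empty sequence has no homopolymer run")
    return max(homopolymer_runs(seq))


def homopolymer_window_size(
    seq: str, min_run: int = 2, fallback: int = 4, floor: int = 4
) -> int:
    """Window for the rolling quality filter: 2x the mean homopolymer length.

    Runs shorter than `min_run` are not homopolymers for this purpose
    (every base is a run of 1).  With no qualifying run the `fallback` is
    returned; the result is never below `floor`.
    """
    if not seq:
        raise ValueError("empty sequence")
    runs = [r for r in homopolymer_runs(seq) if r >= min_run]
    if not runs:
        return max(fallback, floor)
    mean = sum(runs) / len(runs)
    return max(floor, 2 * int(np.floor(mean + 0.5)))


def min_windowed_mean_quality(quals, window: int) -> float:
    """Minimum over all step-1 sliding windows of the window mean quality.

    window == 1 gives the minimum score; window == len gives the overall
    mean.
    """
    q = np.asarray(quals, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(q):
        raise ValueError(f"window {window} exceeds read length {len(q)}")
    cumsum = np.concatenate(([0.0], np.cumsum(q)))
    sums = cumsum[window:] - cumsum[:-window]
    return float(sums.min() / window)


def _primer_prefix_mismatches(
    seq: str, primer: str, span: int, offset_hint: int | None = None
) -> int | None:
    hit = best_anchored(seq, primer, span)
    return None if hit is None else hit[1]


def primer_mismatches(
    record: SeqRecord, design: AmpliconDesign, span: int
) -> tuple[int | None, int | None]:
    """Minimal anchored mismatch counts to the forward primer near the 5'
    end and to the (reverse-complemented) reverse primer near the 3' end
    of an already-oriented read.  None where the primer does not fit."""
    fwd = _primer_prefix_mismatches(record.seq, design.fwd_primer, span)
    rev_rc = revcomp_iupac(design.rev_primer)
    tail = record.seq[-(span + len(rev_rc)) :]
    rev = _primer_prefix_mismatches(tail, rev_rc, span)
    return fwd, rev


def orient_read(
    record: SeqRecord,
    design: AmpliconDesign,
    max_mm: int = 1,
    span: int = 60,
) -> OrientedRead:
    """Unify strand orientation by locating the forward primer.

    The forward primer is searched (anchored, IUPAC-aware Hamming) within
    `span` offsets of the 5' end of the read and of its reverse
    complement.  The read is flipped iff the better match is on the minus
    strand.  No match on either strand within `max_mm` reports NOT_FOUND
    (the read will fail the primer filter); an exact tie reports AMBIGUOUS.
    Orienting an already-oriented read is the identity.
    """
    fwd_hit = best_anchored(record.seq, design.fwd_primer, span)
    rc = seqio.reverse_complement(record)
    rev_hit = best_anchored(rc.seq, design.fwd_primer, span)
    fwd_mm = fwd_hit[1] if fwd_hit else None
    rev_mm = rev_hit[1] if rev_hit else None
    fwd_ok = fwd_mm is not None and fwd_mm <= max_mm
    rev_ok = rev_mm is not None and rev_mm <= max_mm
    if fwd_ok and rev_ok and fwd_mm == rev_mm:
        return OrientedRead(record, Orientation.AMBIGUOUS)
    if fwd_ok and (not rev_ok or fwd_mm <= rev_mm):
        return OrientedRead(record, Orientation.PLUS, fwd_mm)
    if rev_ok:
        return OrientedRead(rc, Orientation.MINUS, rev_mm)
    return OrientedRead(record, Orientation.NOT_FOUND)


class BarcodeMatch(enum.Enum):
    UNASSIGNED = "unassigned"
    AMBIGUOUS = "ambiguous"


def match_barcode(
    record: SeqRecord,
    design: AmpliconDesign,
    max_mm: int = 1,
    check_suffix: bool = False,
):
    """Assign an oriented read to a barcode by Hamming distance on its prefix.

    Returns the unique best label with distance <= max_mm,
    BarcodeMatch.UNASSIGNED when none qualifies, or
    BarcodeMatch.AMBIGUOUS when two labels tie at the minimal distance.
    With ``check_suffix`` the trailing barcode copy of the dual-barcoded
    construct must agree with the same label within max_mm as well.
    """
    blen = design.barcode_length
    if len(record.seq) < blen:
        return BarcodeMatch.UNASSIGNED
    prefix = record.seq[:blen]
    distances = {
        label: hamming_distance(prefix, bc) for label, bc in design.barcodes.items()
    }
    best = min(distances.values())
    if best > max_mm:
        return BarcodeMatch.UNASSIGNED
    winners = [label for label, d in distances.items() if d == best]
    if len(winners) > 1:
        return BarcodeMatch.AMBIGUOUS
    label = winners[0]
    if check_suffix:
        suffix = record.seq[-blen:]
        if hamming_distance(suffix, design.barcodes[label]) > max_mm:
            return BarcodeMatch.UNASSIGNED
    return label


def apply_filters(
    record: SeqRecord,
    design: AmpliconDesign,
    params: QCParams,
    chimera_verdict: bool,
) -> FilterDecision:
    """Evaluate the whole filter battery on one read.

    Every filter is evaluated (no short-circuit) and every violated filter
    is named in ``failures``; the read passes iff no filter fails, so
    survival does not depend on evaluation order.  ``chimera_verdict`` is
    True when the read was classified as chimeric — either by the
    ligation-concatemer detector or by an external PCR-chimera tool.
    """
    failures: list[str] = []
    if has_zero_quality(record):
        failures.append("zero_quality")
    if "N" in record.seq:
        failures.append("ambiguous_base")
    if record.mean_quality < params.min_avg_qual:
        failures.append("avg_quality")
    if params.window_threshold is not None and len(record):
        window = params.window_override or homopolymer_window_size(
            record.seq,
            min_run=params.window_min_run,
            fallback=params.window_floor,
            floor=params.window_floor,
        )
        window = min(window, len(record))
        if min_windowed_mean_quality(record.quals, window) < params.window_threshold:
            failures.append("window_quality")
    if len(record) and max_homopolymer_run(record.seq) > params.max_homopolymer_run:
        failures.append("homopolymer")
    lo, hi = params.length_window(design)
    if not lo <= len(record) <= hi:
        failures.append("length")

    oriented = orient_read(
        record, design, params.max_primer_mismatches, params.primer_search_span
    )
    strand = oriented.strand.value
    barcode_label: str | None = None
    if oriented.strand in (Orientation.NOT_FOUND, Orientation.AMBIGUOUS):
        failures.append("primer")
    else:
        fwd_mm, rev_mm = primer_mismatches(
            oriented.record, design, params.primer_search_span
        )
        if (
            fwd_mm is None
            or rev_mm is None
            or fwd_mm > params.max_primer_mismatches
            or rev_mm > params.max_primer_mismatches
        ):
            failures.append("primer")
        bc = match_barcode(oriented.record, design, params.max_barcode_mismatches)
        if isinstance(bc, BarcodeMatch):
            failures.append("barcode")
        else:
            barcode_label = bc
    if chimera_verdict:
        failures.append("chimera")

    return FilterDecision(
        read_id=record.id,
        passed=not failures,
        failures=failures,
        barcode=barcode_label,
        strand=strand,
    )
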