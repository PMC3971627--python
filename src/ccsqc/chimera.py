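"""Detection of SMRTbell ligation concatemers ("PacBio chimeras").

During library preparation, blunt adapter ligation can join two or more
complete, barcoded amplicons end to end before the SMRTbells go on.  The
resulting reads are unlike PCR chimeras: their length is a multiple of the
amplicon length and they carry internal primer and barcode copies at every
unit boundary, because each joined fragment is a full-length amplicon.
Reference-free PCR-chimera detectors (UCHIME-style) do not flag them — the
junctions fall between amplicons, not inside them — so they must be caught
by size and by motif structure.

Detection here combines both signals: anomalous length is the sufficient
removal condition, and internal primer/barcode motif hits reconstruct the
unit structure (order, per-unit barcodes) as the explanatory annotation.
PCR-chimera detection is *not* implemented; the pipeline accepts an
external verdict per read through a hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from ._motif import (
    find_occurrences,
    greedy_nonoverlapping,
    hamming_distance,
    revcomp_iupac,
)
from .qc import AmpliconDesign
from .seqio import SeqRecord


@dataclass
class MotifHit:
    """One located primer or barcode occurrence on a read."""

    motif: str  # 'fwd_primer', 'rev_primer' or 'barcode:<label>'
    strand: str  # '+' or '-'
    start: int  # 0-based half-open
    end: int
    mismatches: int


@dataclass
class SegmentAnnotation:
    """The partition of a read into amplicon units, plus its verdict.

    classification is one of 'intact', 'concatemer', 'out_of_size',
    'unclassifiable'; `order` counts complete units.
    """

    read_id: str
    read_length: int
    hits: list[MotifHit]
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    classification: str = "unclassifiable"
    order: int = 0

    @property
    def is_chimeric(self) -> bool:
        return self.classification == "concatemer"


def scan_motifs(
    record: SeqRecord, design: AmpliconDesign, max_mm: int = 1
) -> list[MotifHit]:
    """All non-overlapping primer occurrences on both strands, plus the
    barcode copies adjacent to them.

    Primer hits are selected greedily by (fewest mismatches, leftmost)
    among anchored IUPAC-Hamming occurrences with <= max_mm mismatches.
    Barcode hits are only reported immediately flanking a primer hit (the
    outward side of the unit), since a lone barcode-length match carries
    no signal.
    """
    hits: list[MotifHit] = []
    for name, primer in (("fwd_primer", design.fwd_primer), ("rev_primer", design.rev_primer)):
        for strand, motif in (("+", primer), ("-", revcomp_iupac(primer))):
            for start, mm in find_occurrences(record.seq, motif, max_mm):
                hits.append(MotifHit(name, strand, start, start + len(motif), mm))
    primer_hits = greedy_nonoverlapping(hits)

    blen = design.barcode_length
    barcode_hits: list[MotifHit] = []
    for hit in primer_hits:
        # The barcode sits outward of the primer.  A unit read on the plus
        # strand starts fwd(+) and ends rev(-); a reversed unit starts
        # rev(+) and ends fwd(-).  So '+' primer hits open a unit (barcode
        # before), '-' hits close one (barcode after), and the barcode
        # copy matches forward for plus-oriented units, reverse-complement
        # for reversed ones.
        unit_start = hit.strand == "+"
        unit_plus = (hit.motif == "fwd_primer") == (hit.strand == "+")
        if unit_start:
            start, end = hit.start - blen, hit.start
        else:
            start, end = hit.end, hit.end + blen
        if start < 0 or end > len(record.seq):
            continue
        window = record.seq[start:end]
        best_label, best_mm = None, max_mm + 1
        for label, bc in design.barcodes.items():
            probe = bc if unit_plus else revcomp_iupac(bc)
            mm = hamming_distance(window, probe)
            if mm < best_mm:
                best_label, best_mm = label, mm
        if best_label is not None:
            barcode_hits.append(
                MotifHit(f"barcode:{best_label}", hit.strand, start, end, best_mm)
            )
    out = primer_hits + barcode_hits
    out.sort(key=lambda h: h.start)
    return out


def _pair_units(
    hits: list[MotifHit], design: AmpliconDesign
) -> list[tuple[int, int, str]]:
    """Greedy nearest-downstream pairing of unit-start with unit-end primers.

    A forward-oriented unit runs fwd_primer(+) ... rev_primer(-); a
    reverse-oriented one runs rev_primer(+) ... fwd_primer(-).  The unit
    interval extends one barcode length outward of each primer, and must
    lie within expected_length +/- tolerance.
    """
    primer_hits = [h for h in hits if not h.motif.startswith("barcode")]
    blen = design.barcode_length
    lo = design.expected_length - design.length_tolerance
    hi = design.expected_length + design.length_tolerance
    units: list[tuple[int, int, str]] = []
    used = [False] * len(primer_hits)
    for i, h in enumerate(primer_hits):
        if used[i]:
            continue
        if h.motif == "fwd_primer" and h.strand == "+":
            end_motif, end_strand, orientation = "rev_primer", "-", "+"
        elif h.motif == "rev_primer" and h.strand == "+":
            end_motif, end_strand, orientation = "fwd_primer", "-", "-"
        else:
            continue
        for j in range(i + 1, len(primer_hits)):
            tail = primer_hits[j]
            if used[j] or tail.motif != end_motif or tail.strand != end_strand:
                continue
            start = max(0, h.start - blen)
            end = tail.end + blen
            if lo <= end - start <= hi:
                used[i] = used[j] = True
                units.append((start, end, orientation))
                break
            if end - start > hi:
                break  # further rev hits are even farther
    units.sort()
    return units


def classify_read(
    hits: list[MotifHit], read_length: int, design: AmpliconDesign, read_id: str = ""
) -> SegmentAnnotation:
    """Classify a read as intact / concatemer / out_of_size / unclassifiable.

    Length is the sufficient condition — any read at or beyond twice the
    expected amplicon length (minus tolerance) is a concatemer, since
    sequences outside the expected amplicon size are to be removed — and
    multi-unit motif evidence classifies shorter multi-unit reads and
    yields the order annotation.
    """
    units = _pair_units(hits, design)
    lo = design.expected_length - design.length_tolerance
    hi = design.expected_length + design.length_tolerance
    in_size = lo <= read_length <= hi
    length_says_concatemer = read_length >= 2 * design.expected_length - design.length_tolerance
    ann = SegmentAnnotation(
        read_id=read_id, read_length=read_length, hits=hits, segments=units
    )
    ann.order = len(units)
    if len(units) >= 2 or length_says_concatemer:
        # length dominates: a read of ~2x amplicon size is removed as a
        # concatemer even when only one complete unit could be paired
        ann.classification = "concatemer"
    elif len(units) == 1 and in_size:
        ann.classification = "intact"
    elif not in_size:
        ann.classification = "out_of_size"
    else:
        ann.classification = "unclassifiable"
    return ann


def annotate_read(
    record: SeqRecord, design: AmpliconDesign, max_mm: int = 1
) -> SegmentAnnotation:
    """scan_motifs + classify_read in one call."""
    hits = scan_motifs(record, design, max_mm)
    return classify_read(hits, len(record), design, read_id=record.id)


def split_concatemer(
    record: SeqRecord, annotation: SegmentAnnotation
) -> list[SeqRecord]:
    """Salvage the complete units of a concatemer as independent records.

    Each complete unit becomes a record id-suffixed ``/seg<i>`` with its
    qualities sliced alongside; units found on the minus strand are left
    as-is (the orientation stage downstream unifies strands).  Requires a
    concatemer classification; with no complete unit the result is empty.
    """
    if annotation.classification != "concatemer":
        raise ValueError("split_concatemer requires a concatemer classification")
    return [
        record.slice(start, end, f"{record.id}/seg{i}")
        for i, (start, end, _orientation) in enumerate(annotation.segments)
    ]


def annotation_report_row(ann: SegmentAnnotation) -> str:
    """One tab-separated report line: id, length, class, order, hit tokens."""
    tokens = ",".join(
        f"{h.motif}{h.strand}@{h.start}-{h.end}:{h.mismatches}" for h in ann.hits
    )
    return "\t".join(
        [ann.read_id, str(ann.read_length), ann.classification, str(ann.order), tokens or "-"]
    )


#: Signature of an external PCR-chimera hook: record -> True if chimeric.
PcrChimeraHook = Callable[[SeqRecord], bool]
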