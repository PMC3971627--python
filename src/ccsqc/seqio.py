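"""Sequence records, Phred arithmetic and FASTQ/FASTA/QUAL input-output.

PacBio circular-consensus (ccs) reads arrive as Sanger FASTQ: one ASCII
character per base, code point = Phred score + 33.  PacBio scores span the
full printable range, 0 ('!') up to 93 ('~'), so everything here treats 93
as a hard ceiling and refuses anything outside the printable Phred+33
alphabet rather than clamping — a clamped value would silently hide an
encoding-dialect mistake (e.g. Phred+64 input).

Structural parsing and writing of FASTQ/FASTA/QUAL is delegated to
Biopython; decoding and validation of the quality alphabet is done here so
that errors can name the offending record, character and position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator, PairedFastaQualIterator

#: Highest Phred score representable in Phred+33 with printable ASCII ('~').
MAX_PHRED = 93

_NUC = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class EncodingError(ValueError):
    """A quality character falls outside the printable Phred+33 range."""


class ParseError(ValueError):
    """A FASTQ/FASTA/QUAL stream violates the format's record structure."""


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


@dataclass(eq=False)
class SeqRecord:
    """One read: identifier, nucleotide string and per-base Phred scores.

    Invariants (checked on construction): ``len(seq) == len(quals)`` and
    every score lies in ``[0, 93]``.
    """

    id: str
    seq: str
    quals: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise ParseError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            bad = int(np.argmax((self.quals < 0) | (self.quals > MAX_PHRED)))
            raise EncodingError(
                f"record {self.id!r}: Phred score {int(self.quals[bad])} at "
                f"position {bad} outside [0, {MAX_PHRED}]"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeqRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.seq == other.seq
            and np.array_equal(self.quals, other.quals)
        )

    @property
    def mean_quality(self) -> float:
        return float(self.quals.mean()) if len(self.quals) else float("nan")

    def slice(self, start: int, end: int, new_id: str | None = None) -> "SeqRecord":
        """Return the sub-record over the 0-based half-open window [start, end)."""
        return SeqRecord(new_id or self.id, self.seq[start:end], self.quals[start:end])


def decode_phred33(character: str) -> int:
    """Decode one FASTQ quality character to its integer Phred score."""
    cp = ord(character)
    if cp < 33 or cp > 126:
        raise EncodingError(
            f"character {character!r} (code point {cp}) outside printable "
            "Phred+33 range [33, 126]"
        )
    return cp - 33


def encode_phred33(q: int) -> str:
    """Inverse of :func:`decode_phred33` for q in [0, 93]."""
    if not 0 <= q <= MAX_PHRED:
        raise EncodingError(f"Phred score {q} outside [0, {MAX_PHRED}]")
    return chr(q + 33)


def phred_to_error_prob(q: float) -> float:
    """Per-base error probability for Phred score q: 10^(-q/10).

    Q=60 is one miscall in a million; Q=23 is 99.5% accuracy; Q=0 is a
    certain error.
    """
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def error_prob_to_phred(p: float) -> float:
    """Phred score for error probability p: -10*log10(p); p=0 maps to 93."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p == 0.0:
        return float(MAX_PHRED)
    return -10.0 * math.log10(p)


def _decode_qual_string(qual: str, read_id: str) -> np.ndarray:
    arr = np.frombuffer(qual.encode("ascii", errors="surrogateescape"), dtype=np.uint8)
    if len(arr) and (arr.min() < 33 or arr.max() > 126):
        bad = int(np.argmax((arr < 33) | (arr > 126)))
        raise EncodingError(
            f"record {read_id!r}: quality character {qual[bad]!r} at position "
            f"{bad} outside printable Phred+33 range"
        )
    return (arr.astype(np.int16) - 33)


def read_fastq(handle: IO[str] | str) -> Iterator[SeqRecord]:
    """Yield SeqRecords from a Sanger (Phred+33) FASTQ stream or path.

    Input order is preserved; sequence/quality length agreement and the
    quality alphabet are verified per record.
    """
    for title, seq, qual in FastqGeneralIterator(handle):
        read_id = title.split()[0] if title else title
        if len(seq) != len(qual):
            raise ParseError(
                f"record {read_id!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        yield SeqRecord(read_id, seq.upper(), _decode_qual_string(qual, read_id))


def _to_bio(record: SeqRecord) -> _BioSeqRecord:
    out = _BioSeqRecord(_BioSeq(record.seq), id=record.id, description="")
    out.letter_annotations["phred_quality"] = [int(q) for q in record.quals]
    return out


def write_fastq(records: Iterable[SeqRecord], handle: IO[str]) -> int:
    """Write records as Sanger FASTQ; returns the number written."""
    return _BioSeqIO.write((_to_bio(r) for r in records), handle, "fastq")


def write_fasta_qual(
    records: Iterable[SeqRecord], fasta_handle: IO[str], qual_handle: IO[str]
) -> int:
    """Split records into a FASTA stream and a matching .qual stream.

    The .qual file repeats each FASTA header and carries the integer Phred
    scores space-separated, the legacy layout consumed by mothur/QIIME-era
    tooling (the std2qual conversion).
    """
    records = list(records)
    n = _BioSeqIO.write((_to_bio(r) for r in records), fasta_handle, "fasta")
    _BioSeqIO.write((_to_bio(r) for r in records), qual_handle, "qual")
    return n


def read_fasta_qual(fasta_handle: IO[str], qual_handle: IO[str]) -> Iterator[SeqRecord]:
    """Re-join a FASTA stream with its .qual companion into SeqRecords."""
    for rec in PairedFastaQualIterator(fasta_handle, qual_handle):
        yield SeqRecord(
            rec.id,
            str(rec.seq).upper(),
            np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
        )


def reverse_complement(record: SeqRecord) -> SeqRecord:
    """Reverse-complement the sequence and reverse the qualities in step."""
    return SeqRecord(record.id, revcomp(record.seq), record.quals[::-1].copy())


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N string."""
    bad = set(seq) - _NUC
    if bad:
        raise AlphabetError(f"non-nucleotide character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]
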