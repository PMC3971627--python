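"""Plain key=value config files for designs and QC parameters.

Lines are ``key = value``; blank lines and ``#`` comments are ignored.
Barcodes use ``barcode:<label> = SEQUENCE``.  Example design file::

    fwd_primer = AGAGTTTGATCMTGGCTCAG
    rev_primer = ATTACCGCGGCTGCTGG
    barcode:bc01 = TCAGACGATGCGTCAT
    barcode:bc02 = CTATACATGACTCTGC
    expected_length = 584
    length_tolerance = 50
    adapter = ATCTCTCTCTTTTCCTCCTCCTCCGTTGTTGTTGTTGAGAGAGAT
"""

from __future__ import annotations

from pathlib import Path

from .qc import AmpliconDesign, QCParams


def _parse_kv(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def load_design(path: str | Path) -> AmpliconDesign:
    kv = _parse_kv(path)
    barcodes = {
        key.split(":", 1)[1]: value.upper()
        for key, value in kv.items()
        if key.startswith("barcode:")
    }
    return AmpliconDesign(
        fwd_primer=kv["fwd_primer"].upper(),
        rev_primer=kv["rev_primer"].upper(),
        barcodes=barcodes,
        expected_length=int(kv["expected_length"]),
        length_tolerance=int(kv["length_tolerance"]),
        adapter=kv.get("adapter", "").upper(),
    )


_QC_FIELD_TYPES = {
    "min_avg_qual": float,
    "max_homopolymer_run": int,
    "min_length": int,
    "max_length": int,
    "max_primer_mismatches": int,
    "max_barcode_mismatches": int,
    "window_threshold": float,
    "window_override": int,
    "window_min_run": int,
    "window_floor": int,
    "primer_search_span": int,
}


def load_qc_params(path: str | Path) -> QCParams:
    kv = _parse_kv(path)
    kwargs = {}
    for key, value in kv.items():
        if key not in _QC_FIELD_TYPES:
            raise ValueError(f"unknown QC parameter {key!r}")
        kwargs[key] = _QC_FIELD_TYPES[key](value)
    return QCParams(**kwargs)


def write_design(design: AmpliconDesign, path: str | Path) -> None:
    lines = [
        f"fwd_primer = {design.fwd_primer}",
        f"rev_primer = {design.rev_primer}",
    ]
    lines += [f"barcode:{label} = {bc}" for label, bc in design.barcodes.items()]
    lines += [
        f"expected_length = {design.expected_length}",
        f"length_tolerance = {design.length_tolerance}",
        f"adapter = {design.adapter}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
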