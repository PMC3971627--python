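"""Pipeline orchestration and aggregate reporting.

Runs the full PacBio-adjusted QC over a batch of ccs reads — orientation,
demultiplexing, the filter battery, ligation-concatemer detection — and
produces a partition-consistent accounting: every read is either a
survivor or appears in the union of failing reads, multi-failure reads
increment every violated filter's count, and the unique-removed total is
reported separately so percentages stay unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from . import chimera as chimera_mod
from .qc import (
    FILTER_NAMES,
    AmpliconDesign,
    FilterDecision,
    QCParams,
    apply_filters,
)
from .seqio import SeqRecord

logger = logging.getLogger("ccsqc")

#: Diagnostic threshold for the long-read anomaly fraction: the share of
#: otherwise-clean reads at >= this length flags surviving concatemers.
DEFAULT_ANOMALY_THRESHOLD = 700


@dataclass
class QCReport:
    """Aggregate per-filter accounting over one pipeline run."""

    total_reads: int
    survivors: int
    per_filter_failures: dict[str, int]
    removed_unique: int
    per_barcode_counts: dict[str, int]
    length_histogram_before: dict[int, int]
    length_histogram_after: dict[int, int]
    fraction_ge_anomaly: float
    anomaly_threshold: int = DEFAULT_ANOMALY_THRESHOLD

    @property
    def percent_removed(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return 100.0 * (1.0 - self.survivors / self.total_reads)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [("total_reads", self.total_reads), ("survivors", self.survivors)]
        rows += [(f"failed:{name}", self.per_filter_failures.get(name, 0)) for name in FILTER_NAMES]
        rows += [
            ("removed_unique", self.removed_unique),
            ("percent_removed", round(self.percent_removed, 3)),
            (
                f"fraction_ge_{self.anomaly_threshold}bp_percent",
                round(100.0 * self.fraction_ge_anomaly, 3),
            ),
        ]
        rows += [(f"barcode:{label}", n) for label, n in sorted(self.per_barcode_counts.items())]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def summary(self) -> str:
        lines = [
            f"reads in            : {self.total_reads}",
            f"survivors           : {self.survivors}",
            f"removed (unique)    : {self.removed_unique}",
            f"percent removed     : {self.percent_removed:.2f}%",
            "per-filter failures (multi-failure reads count in each):",
        ]
        for name in FILTER_NAMES:
            lines.append(f"  {name:<15} {self.per_filter_failures.get(name, 0)}")
        lines.append(
            f"reads >= {self.anomaly_threshold} bp among quality-clean reads: "
            f"{100.0 * self.fraction_ge_anomaly:.2f}%"
        )
        lines.append("per-barcode survivors:")
        for label, count in sorted(self.per_barcode_counts.items()):
            lines.append(f"  {label:<8} {count}")
        return "\n".join(lines)


def _histogram(lengths: Sequence[int], bin_width: int = 50) -> dict[int, int]:
    hist: dict[int, int] = {}
    for length in lengths:
        b = (length // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items()))


@dataclass
class PipelineResult:
    report: QCReport
    decisions: list[FilterDecision]
    annotations: list[chimera_mod.SegmentAnnotation]
    survivors_by_barcode: dict[str, list[SeqRecord]] = field(default_factory=dict)
    discards: list[SeqRecord] = field(default_factory=list)

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [d.read_id for d in self.decisions],
                "passed": [d.passed for d in self.decisions],
                "failures": [",".join(d.failures) or "-" for d in self.decisions],
                "barcode": [d.barcode or "-" for d in self.decisions],
                "strand": [d.strand or "-" for d in self.decisions],
            }
        )


def run_pipeline(
    records: Iterable[SeqRecord],
    design: AmpliconDesign,
    params: QCParams,
    pcr_chimera_hook: Callable[[SeqRecord], bool] | None = None,
    max_motif_mismatches: int = 1,
    anomaly_threshold: int = DEFAULT_ANOMALY_THRESHOLD,
) -> PipelineResult:
    """Run orientation, demultiplexing, filters and chimera detection.

    Deterministic given its inputs: no stage draws randomness.  The
    chimera verdict for each read is the ligation-concatemer classifier's,
    OR-ed with an optional external PCR-chimera hook.
    """
    records = list(records)
    decisions: list[FilterDecision] = []
    annotations: list[chimera_mod.SegmentAnnotation] = []
    survivors_by_barcode: dict[str, list[SeqRecord]] = {}
    discards: list[SeqRecord] = []
    failure_counts = {name: 0 for name in FILTER_NAMES}
    clean_lengths: list[int] = []  # quality/primer/barcode-clean, any length

    for record in records:
        ann = chimera_mod.annotate_read(record, design, max_motif_mismatches)
        annotations.append(ann)
        verdict = ann.is_chimeric
        if pcr_chimera_hook is not None:
            verdict = verdict or bool(pcr_chimera_hook(record))
        decision = apply_filters(record, design, params, verdict)
        decisions.append(decision)
        for name in decision.failures:
            failure_counts[name] += 1
        if not set(decision.failures) - {"length", "chimera"}:
            clean_lengths.append(len(record))
        if decision.passed:
            survivors_by_barcode.setdefault(decision.barcode, []).append(record)
        else:
            discards.append(record)

    survivors = sum(len(v) for v in survivors_by_barcode.values())
    ge = sum(1 for L in clean_lengths if L >= anomaly_threshold)
    report = QCReport(
        total_reads=len(records),
        survivors=survivors,
        per_filter_failures=failure_counts,
        removed_unique=len(discards),
        per_barcode_counts={k: len(v) for k, v in survivors_by_barcode.items()},
        length_histogram_before=_histogram([len(r) for r in records]),
        length_histogram_after=_histogram(
            [len(r) for recs in survivors_by_barcode.values() for r in recs]
        ),
        fraction_ge_anomaly=(ge / len(clean_lengths)) if clean_lengths else 0.0,
        anomaly_threshold=anomaly_threshold,
    )
    assert report.survivors + report.removed_unique == report.total_reads
    logger.info(
        "pipeline: %d reads in, %d survivors (%.2f%% removed)",
        report.total_reads,
        report.survivors,
        report.percent_removed,
    )
    return PipelineResult(
        report=report,
        decisions=decisions,
        annotations=annotations,
        survivors_by_barcode=survivors_by_barcode,
        discards=discards,
    )
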