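"""Circular-consensus construction from raw multi-pass long reads.

A raw PacBio read traverses the SMRTbell-circularised amplicon many times,
so it contains alternating-strand copies of the molecule separated by
adapter copies.  Because per-pass errors are randomly distributed, a
plurality vote across aligned passes cancels them: per-pass accuracy of
~90% becomes consensus accuracy well above 99% at typical pass counts.

The pipeline here is: locate adapter copies (edit-distance infix search on
both strands), cut the read into passes, re-orient all passes to one
strand, align them against a centre pass (centre-star), and vote per
alignment column.  Consensus quality per base is derived from the column
agreement: q = min(93, round(-10*log10(max(eps, 1 - k/n)))) with k the
plurality count, n the column depth and eps = 1/(n+1)^2, so unanimous
columns saturate at a depth-dependent ceiling rather than a fake certainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqio import MAX_PHRED, SeqRecord, revcomp

_VOTE_ORDER = "ACGT-"  # tie-break: fixed symbol order, gap last


@dataclass
class AdapterHit:
    start: int
    end: int  # 0-based half-open
    mismatches: int
    strand: str


@dataclass
class PassSet:
    """Adapter-free pass fragments of one long read, forward-oriented.

    Fragments whose length deviates more than 50% from the median are
    partial (terminal truncations or split artifacts) and are kept apart
    rather than silently mixed into the consensus.
    """

    passes: list[SeqRecord]
    source_id: str
    n_full_passes: int
    partial: list[SeqRecord] = field(default_factory=list)
    low_confidence: bool = False


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def find_adapters(seq: str, adapter: str, max_rate: float) -> list[AdapterHit]:
    """Non-overlapping adapter occurrences on either strand.

    Infix edit-distance search at threshold ``floor(max_rate *
    len(adapter))``; overlap conflicts resolve by lower edit distance then
    leftmost position.  Found iteratively best-first, masking accepted
    intervals so weaker copies surface on later rounds.
    """
    if len(adapter) < 10:
        raise ValueError("adapter length must be >= 10")
    k = int(max_rate * len(adapter))
    motifs = [(adapter, "+"), (revcomp(adapter), "-")]
    accepted: list[AdapterHit] = []
    work = seq
    while True:
        candidates: list[AdapterHit] = []
        for motif, strand in motifs:
            res = edlib.align(motif, work, mode="HW", task="locations", k=k)
            if res["editDistance"] == -1:
                continue
            seen_starts = set()
            for start, end in res["locations"]:
                if start in seen_starts:  # edlib may emit several end points
                    continue
                seen_starts.add(start)
                candidates.append(
                    AdapterHit(start, end + 1, res["editDistance"], strand)
                )
        if not candidates:
            break
        candidates.sort(key=lambda h: (h.mismatches, h.start))
        progressed = False
        for hit in candidates:
            if all(hit.end <= a.start or hit.start >= a.end for a in accepted):
                accepted.append(hit)
                work = work[: hit.start] + "#" * (hit.end - hit.start) + work[hit.end :]
                progressed = True
        if not progressed:
            break
    accepted.sort(key=lambda h: h.start)
    return accepted


def _orient_fragment(frag: SeqRecord, reference: str) -> SeqRecord:
    """Flip the fragment iff its reverse complement is closer to `reference`."""
    fwd = edit_distance(frag.seq, reference)
    rc = revcomp(frag.seq)
    rev = edit_distance(rc, reference)
    if rev < fwd:
        return SeqRecord(frag.id, rc, frag.quals[::-1].copy())
    return frag


def split_passes(
    long_read: SeqRecord,
    adapter: str,
    max_adapter_mismatch_rate: float = 0.3,
) -> PassSet:
    """Cut a raw long read at adapter copies and orient the passes.

    Fragments between adapter hits become passes; all passes are re-
    oriented to the strand of the longest fragment by comparing the edit
    distance of each fragment and of its reverse complement to that
    reference.  With no adapter hit at all the whole read is returned as a
    single low-confidence pass.
    """
    hits = find_adapters(long_read.seq, adapter, max_adapter_mismatch_rate)
    if not hits:
        return PassSet(
            passes=[long_read],
            source_id=long_read.id,
            n_full_passes=1,
            low_confidence=True,
        )
    bounds = [0] + [p for h in hits for p in (h.start, h.end)] + [len(long_read.seq)]
    fragments = [
        long_read.slice(bounds[i], bounds[i + 1], f"{long_read.id}/pass{i // 2}")
        for i in range(0, len(bounds), 2)
        if bounds[i + 1] > bounds[i]
    ]
    if not fragments:
        return PassSet([long_read], long_read.id, 1, low_confidence=True)
    reference = max(fragments, key=len).seq
    oriented = [_orient_fragment(f, reference) for f in fragments]
    median = float(np.median([len(f) for f in oriented]))
    is_full = [0.5 * median <= len(f) <= 1.5 * median for f in oriented]
    full = [f for f, ok in zip(oriented, is_full) if ok]
    partial = [f for f, ok in zip(oriented, is_full) if not ok]
    return PassSet(
        passes=full,
        source_id=long_read.id,
        n_full_passes=len(full),
        partial=partial,
    )


def _column_quality(k: int, n: int) -> int:
    eps = 1.0 / (n + 1) ** 2
    p_err = max(eps, 1.0 - k / n)
    return min(MAX_PHRED, int(round(-10.0 * math.log10(p_err))))


def _vote(symbols: list[str], n: int) -> tuple[str, int]:
    counts = {s: 0 for s in _VOTE_ORDER}
    for s in symbols:
        if s in counts:  # 'N' and other foreign symbols abstain
            counts[s] += 1
    counts["-"] += n - len(symbols)  # passes not covering this column
    best = max(_VOTE_ORDER, key=lambda s: (counts[s], -_VOTE_ORDER.index(s)))
    return best, counts[best]


def consensus_from_aligned(seqs: list[str]) -> tuple[str, np.ndarray]:
    """Plurality-vote consensus of pre-aligned equal-length sequences.

    Gap characters '-' are allowed; a gap plurality deletes the column.
    Ties break by the fixed symbol order A < C < G < T < gap.  Returns the
    consensus string and its per-base Phred qualities.
    """
    if not seqs:
        raise ValueError("no sequences to vote on")
    n = len(seqs)
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must share one length")
    out, quals = [], []
    for column in zip(*seqs):
        best, k = _vote(list(column), n)
        if best == "-":
            continue
        out.append(best)
        quals.append(_column_quality(k, n))
    return "".join(out), np.asarray(quals, dtype=np.int16)


def _align_to_center(query: str, center: str) -> tuple[str, str]:
    res = edlib.align(query, center, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, center)
    return nice["query_aligned"], nice["target_aligned"]


def _vote_against_reference(
    seqs: list[str],
    reference: str,
    reference_votes: bool,
    ins_threshold: int | None = None,
) -> tuple[str, np.ndarray]:
    """Stack pairwise alignments of `seqs` onto `reference` and vote.

    Columns are keyed by reference coordinates, with insertion columns
    between reference positions.  With ``reference_votes`` the reference
    itself contributes one vote per match column (centre-star round);
    without, it only provides the coordinate frame (polish round).

    Deletion and insertion are not symmetric here: a base present in the
    reference is anchored (all passes vote at its column), while a base
    missing from it must be restored from insertion columns whose keys
    scatter when passes carry nearby errors.  ``ins_threshold`` therefore
    relaxes the insertion rule for intermediate rounds: an inserted base
    is accepted whenever at least that many passes agree on it, letting
    true bases become incumbents; spuriously accepted bases are reliably
    voted out as match columns in the next standard round.
    """
    n = len(seqs) + (1 if reference_votes else 0)
    # columns[(c, 0, offset)] = insertion column before reference position c
    # columns[(c, 1, 0)]     = match column at reference position c
    columns: dict[tuple[int, int, int], list[str]] = {}
    for c, base in enumerate(reference):
        columns[(c, 1, 0)] = [base] if reference_votes else []
    for seq in seqs:
        q_aln, r_aln = _align_to_center(seq, reference)
        inserts: list[tuple[int, str]] = []
        c_pos = 0
        for qc, rc in zip(q_aln, r_aln):
            if rc == "-":
                # canonicalise: a base inserted next to / inside a run of
                # itself belongs at the run's left edge, so that every
                # pass restoring the same missing base votes in the same
                # column regardless of its own nearby errors
                key = c_pos
                while key > 0 and reference[key - 1] == qc:
                    key -= 1
                inserts.append((key, qc))
            else:
                columns[(c_pos, 1, 0)].append(qc)
                c_pos += 1
        seen: dict[int, int] = {}
        for key, qc in sorted(inserts, key=lambda t: t[0]):
            offset = seen.get(key, 0)
            seen[key] = offset + 1
            columns.setdefault((key, 0, offset), []).append(qc)
    out, quals = [], []
    for key in sorted(columns):
        symbols = columns[key]
        if key[1] == 0 and ins_threshold is not None:
            counts = {b: 0 for b in "ACGT"}
            for s in symbols:
                if s in counts:
                    counts[s] += 1
            best = max("ACGT", key=lambda b: (counts[b], -"ACGT".index(b)))
            if counts[best] >= ins_threshold:
                out.append(best)
                quals.append(_column_quality(counts[best], n))
            continue
        best, k = _vote(symbols, n)
        if best == "-":
            continue
        out.append(best)
        quals.append(_column_quality(k, n))
    return "".join(out), np.asarray(quals, dtype=np.int16)


def _run_length_repair(
    pass_seqs: list[str],
    ref: str,
    min_run: int = 2,
    loss_rate: float = 0.10,
    gain_rate: float = 0.01,
) -> str:
    """Re-estimate homopolymer run lengths by maximum likelihood.

    Column voting estimates a run's length poorly: any error inside the
    run (substitution or deletion alike) shortens the run a pass reports,
    so for long runs the majority of passes can disagree with the true
    length.  Per reference run of base B, each pass's count of B within
    the aligned span is modelled as the true length minus a binomial loss
    (per-base probability ``loss_rate``), with spurious gains at
    ``gain_rate`` per extra base; the ML length replaces the run.  The
    repaired sequence is a *proposal*: a standard vote round afterwards
    keeps only the repairs the passes actually support.
    """
    n = len(pass_seqs)
    qidx = np.zeros((n, len(ref) + 1), dtype=np.int32)
    for p, seq in enumerate(pass_seqs):
        q_aln, r_aln = _align_to_center(seq, ref)
        qoff = 0
        c = 0
        for qc, rc in zip(q_aln, r_aln):
            if rc == "-":
                qoff += 1
            else:
                qidx[p, c] = qoff
                if qc != "-":
                    qoff += 1
                c += 1
        qidx[p, len(ref)] = len(seq)

    log_q = math.log(loss_rate)
    log_1q = math.log1p(-loss_rate)
    log_g = math.log(gain_rate)

    def loglik(m: int, counts: list[int]) -> float:
        total = 0.0
        for c_p in counts:
            if c_p <= m:
                k = m - c_p
                total += math.log(math.comb(m, k)) + k * log_q + (m - k) * log_1q
            else:
                total += (c_p - m) * log_g
        return total

    out = []
    i = 0
    while i < len(ref):
        j = i
        while j < len(ref) and ref[j] == ref[i]:
            j += 1
        m = j - i
        base = ref[i]
        if m >= min_run:
            counts = [
                pass_seqs[p][qidx[p, i] : qidx[p, j]].count(base) for p in range(n)
            ]
            best_m = max(
                range(max(1, min(counts)), max(counts) + 2),
                key=lambda mm: (loglik(mm, counts), mm == m),
            )
            out.append(base * best_m)
        else:
            out.append(ref[i:j])
        i = j
    return "".join(out)


def _single_edit_variants(window: str) -> set[str]:
    """All sequences within one edit of `window` (deletions, substitutions,
    insertions) — the local hypothesis space around the current consensus."""
    out: set[str] = set()
    for i in range(len(window)):
        out.add(window[:i] + window[i + 1 :])
        for b in "ACGT":
            if b != window[i]:
                out.add(window[:i] + b + window[i + 1 :])
    for i in range(len(window) + 1):
        for b in "ACGT":
            out.add(window[:i] + b + window[i:])
    return out


def _window_repair(
    pass_seqs: list[str], ref: str, min_dissent: int = 2
) -> str:
    """Locally re-estimate low-agreement regions of the consensus.

    Column stacking of independent pairwise alignments is ambiguous near
    repeats: the same underlying base can surface as a substitution in one
    pass's alignment and as an indel in another's, splitting its votes.
    For every region where >= `min_dissent` passes disagree with the
    consensus (or >= 2 passes insert), the candidate set {current window}
    U {each pass's corresponding segment} is scored by summed edit
    distance to all pass segments and the minimiser replaces the window —
    a local centre-sequence estimate that needs no column bookkeeping.
    """
    n = len(pass_seqs)
    dissent = np.zeros(len(ref), dtype=np.int32)
    ins_votes = np.zeros(len(ref) + 1, dtype=np.int32)
    # qidx[p][c] = index into pass p of the first base at/after ref column c
    qidx = np.zeros((n, len(ref) + 1), dtype=np.int32)
    for p, seq in enumerate(pass_seqs):
        q_aln, r_aln = _align_to_center(seq, ref)
        qoff = 0
        c = 0
        for qc, rc in zip(q_aln, r_aln):
            if rc == "-":
                ins_votes[c] += 1
                qoff += 1
            else:
                qidx[p, c] = qoff
                if qc != ref[c]:
                    dissent[c] += 1
                if qc != "-":
                    qoff += 1
                c += 1
        qidx[p, len(ref)] = len(seq)
    # insertion evidence scatters over neighbouring keys when passes carry
    # their own errors nearby, so pool it over a +/-2 column neighbourhood
    kernel = np.ones(5, dtype=np.int32)
    ins_pooled = np.convolve(ins_votes, kernel, mode="same")
    hot = sorted(
        set(np.nonzero(dissent >= min_dissent)[0])
        | set(np.nonzero(ins_pooled[: len(ref)] >= 2)[0])
    )
    if not hot:
        return ref

    # A window boundary must be an anchor: a column where every pass agrees
    # with the reference, no insertion evidence touches it, and it is not
    # mid-homopolymer — there the per-pass coordinate mapping is exact, so
    # candidate scoring by global alignment is not biased by ragged ends.
    def is_anchor(c: int) -> bool:
        return (
            dissent[c] == 0
            and ins_votes[c] == 0
            and ins_votes[c + 1] == 0
            and (c == 0 or ref[c] != ref[c - 1])
        )

    max_extend = 15
    windows: list[tuple[int, int]] = []
    for c in hot:
        s = c
        while s > 0 and not is_anchor(s) and c - s < max_extend:
            s -= 1
        e = c + 1
        while e < len(ref) and not is_anchor(e) and e - c < max_extend:
            e += 1
        if windows and s <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], e))
        else:
            windows.append((s, e))

    pieces = []
    cursor = 0
    for s, e in windows:
        pieces.append(ref[cursor:s])
        current = ref[s:e]
        segments = [seq[qidx[p, s] : qidx[p, e]] for p, seq in enumerate(pass_seqs)]
        candidates = {current, *segments} | _single_edit_variants(current)

        def score(cand: str) -> int:
            return sum(edlib.align(cand, seg)["editDistance"] for seg in segments)

        best = min(candidates, key=lambda cand: (score(cand), cand != current, cand))
        pieces.append(best)
        cursor = e
    pieces.append(ref[cursor:])
    return "".join(pieces)


def build_consensus(pass_set: PassSet, polish_rounds: int = 2) -> SeqRecord:
    """Centre-star consensus of a pass set, iteratively polished.

    Round 0 is classic centre-star: the centre is the pass with minimal
    summed edit distance to the others, every other pass is pairwise-
    aligned to it, and stacked columns are decided by plurality vote
    (quality from the column agreement).  Because the centre carries its
    own errors and pairwise gap placement is ambiguous around repeats,
    the draft is then refined: each polish round proposes local fixes
    (window repair at low-agreement regions, ML homopolymer run-length
    repair) and re-votes all passes against the proposal, which keeps
    only supported changes and yields the per-base qualities.  A single
    pass is returned as-is with its own qualities.
    """
    passes = pass_set.passes
    if not passes:
        raise ValueError("empty pass set")
    if len(passes) == 1:
        only = passes[0]
        rec = SeqRecord(f"{pass_set.source_id}/ccs", only.seq, only.quals.copy())
        rec.flags["n_passes"] = 1
        rec.flags["low_confidence"] = pass_set.low_confidence
        return rec

    n = len(passes)
    dists = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(passes[i].seq, passes[j].seq)
            dists[i, j] = dists[j, i] = d
    center_idx = int(np.argmin(dists.sum(axis=1)))
    center = passes[center_idx].seq
    others = [p.seq for i, p in enumerate(passes) if i != center_idx]
    pass_seqs = [p.seq for p in passes]

    # draft: centre-star with liberal insertion acceptance (restorations
    # are fragile, removals are robust — see _vote_against_reference)
    seq, quals = _vote_against_reference(
        others, center, reference_votes=True, ins_threshold=2
    )
    repaired = _window_repair(pass_seqs, seq)
    seq, quals = _vote_against_reference(
        pass_seqs, repaired, reference_votes=False, ins_threshold=2
    )
    # propose-and-filter polish: repairs suggest edits, a standard vote
    # round keeps those the passes support
    for _ in range(polish_rounds):
        proposal = _window_repair(pass_seqs, seq)
        proposal = _run_length_repair(pass_seqs, proposal)
        seq, quals = _vote_against_reference(pass_seqs, proposal, reference_votes=False)
    rec = SeqRecord(f"{pass_set.source_id}/ccs", seq, quals)
    rec.flags["n_passes"] = n
    return rec


def ccs_from_long_read(
    long_read: SeqRecord, adapter: str, max_adapter_mismatch_rate: float = 0.3
) -> SeqRecord:
    """Convenience: split passes and build the consensus in one call."""
    return build_consensus(split_passes(long_read, adapter, max_adapter_mismatch_rate))


def single_molecule_coverage(long_read_length: float, unit_length: float) -> float:
    """Fold coverage of the molecule by one long read: length / unit length.

    Whether `unit_length` is the bare amplicon or amplicon-plus-adapter
    share is the caller's convention; a 4944 nt read over a ~520 nt unit
    is ~9.5x either way.
    """
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    return long_read_length / unit_length
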