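# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `ccsqc`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Quality model and I/O

Reads are Sanger FASTQ, Phred+33, with per-base scores in [0, 93] — 93
('~') is the printable ceiling and is treated as a hard bound: any code
point below 33 or a score above 93 is an error, never clamped, because
silent clamping would hide an encoding-dialect mistake (e.g. Phred+64
input).  `N` is accepted in input sequences so foreign data parses; it is
handled by the ambiguous-base filter downstream.  FASTA/QUAL output
reproduces the legacy split format (sequence file plus space-separated
integer scores under matching headers) consumed by mothur/QIIME-era tools.
Biopython performs the structural parsing and writing; score decoding and
validation are done in this package so that errors can name the offending
record, character and position.

## Synthetic library model

The simulator emulates the statistical structure the QC stages must
handle, not platform physics.

**Templates.** `template_length` defaults to 515 nt (a bacterial V1–V3
amplicon insert).  Base composition is drawn with an exact GC count and
then permuted, so the realized GC fraction is tight.  `homopolymer_boost`
(default 3) runs of length 4–8 are planted at well-separated positions —
homopolymers are where ccs quality dips, and the windowed filter needs
them present.  Natural runs longer than 8 are broken so that the
homopolymer filter's ground truth is exactly the planted structure.

**Constructs.** A molecule is `barcode + fwd_primer + insert +
revcomp(rev_primer) + barcode`.  Degenerate (IUPAC) primer positions are
instantiated with a uniform concrete base per molecule, as in a real
synthesized primer batch.  The default design uses the 27F/534R bacterial
primer pair, four 16-nt barcodes, expected construct length 584 nt and a
±50 nt tolerance.

**Errors.** Each pass of the polymerase corrupts each base independently
with `per_pass_error_rate` (default 0.10, matching raw long-read quality
that averages about Phred 10).  An error is a substitution with
probability `1 − indel_fraction_of_errors`, otherwise an insertion or a
deletion with equal probability.  `indel_fraction_of_errors` defaults to
0.5: the error process is specified only as uniform and random, so errors
are split evenly between substitutions and indels, and indels evenly
between insertions and deletions.  There is no context dependence — that
uniformity is precisely the property that makes plurality consensus work,
and it is the stated premise this package builds on.

**Long reads.** A raw read is `pass₀ adapter pass₁ adapter …` with passes
alternating strand (rolling-circle replication reads the two strands
alternately) and adapter copies in matching orientation.  The number of
full passes is Poisson around `passes_mean` (default 9.5, the coverage a
~5-kb read achieves over a ~520-nt unit), minimum 1, followed by a
uniformly truncated partial terminal pass.  Long-read per-base qualities
are drawn around the Phred equivalent of the per-pass error rate (mean
~10, clipped to [0, 15] at the default rate).  The SMRTbell adapter
sequence is proprietary; a synthetic 45-nt stand-in is shipped as a
configurable constant (`DEFAULT_ADAPTER`) — only its role as a fixed
separator matters here.

**Concatemers.** With probability `chimera_fraction` (default 0.02,
reflecting the ~1–2% incidence reported for real libraries) a molecule is
a ligation concatemer of 2+ complete barcoded units drawn from distinct
templates.  Units after the first are ligated in random orientation —
blunt adapter ligation has no strand preference.  Truth records (template
indices, per-unit barcodes and strands, order, read strand, planted
defects) are sufficient to score every downstream classifier exactly.

**What the simulator does not model:** ZMW loading bias, polymerase
kinetics, chemistry-specific error spectra, context-dependent quality, or
PCR chimeras.  Passing tests therefore demonstrate correctness of the
*algorithms* under the stated error model, not performance on any
particular instrument run.

## Consensus construction

`split_passes` finds adapter copies by iterative best-first infix
edit-distance search (threshold `max_adapter_mismatch_rate ×
len(adapter)`, default 0.3) on both strands, masking accepted hits so
weaker copies surface in later rounds; overlap conflicts resolve by lower
distance, then leftmost.  Fragments between hits become passes.  Each
fragment is re-oriented against the longest fragment by comparing the
edit distance of the fragment and of its reverse complement — this is
equivalent to blind alternation when every adapter is found, and robust
when one is missed.  Fragments deviating more than 50% from the median
length are kept aside as partials rather than silently mixed into the
vote.

`build_consensus` proceeds in rounds:

1. **Centre-star draft.** The centre is the pass with minimal summed edit
   distance to the others.  Every other pass is pairwise-aligned to it
   (edlib, global) and the alignments are stacked into columns keyed by
   centre coordinates, with insertion columns between positions.
   Inserted bases adjacent to a homopolymer run of the same base are
   re-keyed to the run's left edge, so passes restoring the same missing
   base vote in one column regardless of their own nearby errors.
2. **Vote.** Per column the plurality symbol wins; a gap plurality
   deletes the column; ties break by the fixed order A<C<G<T<gap.
   Reference-relative voting is asymmetric: bases present in the
   reference are anchored and robust, while missing bases must be
   restored from insertion columns whose support scatters.  Draft rounds
   therefore accept an inserted base once ≥2 passes agree on it —
   spurious acceptances are reliably voted out as anchored columns in the
   next standard round, while true restorations become incumbents.
3. **Window repair.** Regions where ≥2 passes disagree (or ≥2 insertion
   votes pool within ±2 columns) are re-estimated locally: window
   boundaries snap to anchor columns (full agreement, no insertion
   evidence, not mid-run) so each pass's corresponding segment has exact
   coordinates, and the candidate set {current window} ∪ {pass segments}
   ∪ {all single-edit variants} is scored by summed edit distance to the
   pass segments; the minimiser (ties prefer the current window) replaces
   the window.  This resolves the cases where pairwise alignments encode
   the same underlying base as a substitution in one pass and an indel in
   another, splitting its votes.
4. **Run-length repair.** Homopolymer run lengths are what column voting
   estimates worst: any error inside a run shortens the length a pass
   reports, so for long runs most passes can disagree with the truth.
   For each reference run (length ≥2) the count of the run base in each
   pass's aligned span is modelled as `m − Binomial(m, 0.10)` with
   spurious gains at 0.01 per extra base, and the maximum-likelihood `m`
   replaces the run.
5. Two final rounds interleave repairs (as proposals) with standard
   plurality votes; the vote keeps only the repairs the passes support
   and produces the per-base qualities.

Consensus quality per base is `min(93, round(−10·log₁₀(max(ε, 1 − k/n))))`
with `k` the plurality count, `n` the column depth and `ε = 1/(n+1)²` —
monotone in column agreement, saturating at a depth-dependent ceiling
rather than claiming false certainty.  The formula is this package's
choice; no published form exists for the conceptual workflow it
implements.

Measured behaviour (computed by `tests/test_ccs.py`): with 7 passes at
10% error including indels on 515-nt templates, the consensus recovers
the template with median edit distance ≤1 and ≥96% of reads within 2
edits.  The residual tail is information-limited, not algorithmic: an
8-nt homopolymer has a ~57% chance per pass of being corrupted somewhere,
so all 7 passes misreport it in ~2% of reads, and no estimator can
recover a length that no pass retains.  Substitution-only accuracy
matches the plurality-vote multinomial closed form exactly (within
binomial noise; `tests/test_acceptance.py`).

## Filters

Defaults follow the established PacBio-adjusted battery: mean quality
≥25; no `N`; no zero-quality base; no homopolymer run longer than 8 nt
("more than 8 distinct runs" would remove essentially every 16S read, so
the run-length reading is used); read length within `expected_length ±
tolerance`; ≤1 mismatch to each primer; ≤1 mismatch to a barcode; not
chimeric.  All filters are evaluated per read with no short-circuit, so
aggregate reports attribute every failure; survival is independent of
evaluation order.

The window filter's threshold has no defensible universal default and is
off until set (`window_threshold`).  Its window size defaults to twice
the read's mean homopolymer run length, counting runs ≥2 (length-1 "runs"
are every base), with a floor of 4 nt; an explicit override is supported.
The filter removes the read rather than trimming it.  A documented
counterexample in the tests shows the windowed minimum is *not* monotone
in window size, so no such invariant is relied on.

Primer and barcode matching is anchored Hamming with IUPAC expansion (a
read `N` matches only a primer `N`); "mismatches" is what practitioners
count, and anchored Hamming is exactly testable against brute force.
Orientation searches the forward primer within `primer_search_span`
(default 60 nt) of the 5′ end on both strands; equal best matches on both
strands are an ambiguity (read removed, counted), no match routes the
read to the primer filter.  Coordinates are 0-based half-open throughout.

The length window defaults to `expected_length ± length_tolerance`.  Both
bounds are explicit parameters because a fixed published cutoff cannot
serve amplicons of ~515 nt and their ≥2× concatemers simultaneously.

## Concatemer detection

Two signals are combined: anomalous length is the sufficient removal
condition (any read at or beyond `2×expected − tolerance` is a
concatemer), and internal primer/barcode motifs reconstruct the unit
structure.  Unit pairing is greedy nearest-downstream with spans
constrained to `expected ± tolerance`; a unit read on the plus strand
runs `fwd(+) … rev(−)`, a reversed unit `rev(+) … fwd(−)`, and adjacent
barcode copies are probed in the unit's orientation.  `order` reports the
honest count of complete units — a length-flagged read with one paired
unit is still a concatemer (removal is size-based), with order 1.
Salvaging concatemer units as independent reads (`split_concatemer`) is
available but disabled by default in the pipeline.  PCR-chimera detection
is out of scope; the pipeline accepts an external per-read verdict
through a hook and ORs it with the ligation-artifact call.

## Reporting

`run_pipeline` is deterministic given its inputs.  Multi-failure reads
increment every violated filter's count and the unique-removed total is
reported separately, so percentages are unambiguous
(`survivors + removed_unique == total` is asserted).  The long-read
anomaly fraction (share of reads at ≥700 nt, configurable) is computed
over reads that are clean apart from length/chimera — the diagnostic that
originally exposed ligation artifacts surviving a pipeline without a size
filter.

## Problem sizes

Module tests run libraries of 50–1,000 molecules and consensus
experiments of 100 seeded trials at 7 passes; the acceptance script uses
20,000 simulated columns per pass count and 1,000-molecule libraries.
These sizes give binomial standard errors well below the asserted
tolerances while keeping the whole suite fast on one CPU.

## Known limitations

* The consensus builder is a centre-star/polish scheme, not a partial
  order aligner; its residual error (~0.5 edits per 515-nt read at 7
  passes, 10% error) is dominated by long-homopolymer reads where the
  passes themselves carry no intact copy.
* Barcode assignment uses the 5′ barcode only by default (the 3′ copy can
  be checked via `match_barcode(..., check_suffix=True)`).
* The quality model of simulated ccs reads (normal around a target mean)
  does not reproduce homopolymer-localized quality dips; planted
  low-quality windows stand in for them when the window filter is
  exercised.
* Native PacBio formats (bas.h5 / unaligned BAM) are not parsed; input is
  FASTQ.
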