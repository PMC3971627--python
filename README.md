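# ccsqc — quality control for PacBio circular-consensus amplicon reads

`ccsqc` implements the quality-control workflow that makes PacBio
circular-consensus sequencing (ccs) usable for 16S rRNA gene amplicon
profiling.  Raw PacBio reads are long and error-rich (~10% per base,
randomly distributed), but the SMRTbell adapters circularize each amplicon
so one polymerase traverses it many times; aligning the passes and voting
per column turns ~Phred 10 raw quality into consensus reads routinely above
Phred 60 (one error per million bases).  Standard amplicon QC then needs
several PacBio-specific adjustments, all provided here:

* **Zero-quality culling** — PacBio assigns an actual nucleotide (never
  `N`) to bases with Phred score 0, so ambiguous-base filters must search
  the quality scores instead of the sequence.
* **Rolling-window quality filtering** — ccs quality does not decay along
  the read; low-quality stretches sit on homopolymers and are masked in
  the read-average by the many very high (≤93) scores.  A read is removed
  when the mean quality over a sliding window (sized to twice the read's
  average homopolymer length) drops below a threshold.
* **Strand unification and demultiplexing** — the instrument sequences
  either template strand; reads are re-oriented by locating the forward
  primer (IUPAC-aware, ≤1 mismatch by default) and assigned to samples by
  barcode (≤1 mismatch).
* **Ligation-concatemer ("PacBio chimera") detection** — adapter ligation
  can join two or more complete barcoded amplicons end to end.  The
  resulting reads are multiples of the amplicon length and carry internal
  primer/barcode copies; UCHIME-style PCR-chimera detectors miss them.
  `ccsqc` flags them by size and reconstructs their unit structure from
  internal primer motifs.

A synthetic-data module generates amplicon templates with planted
homopolymer runs, barcoded constructs in mixed strand orientation, raw
multi-pass long reads with uniformly distributed substitution/indel
errors, and ligation concatemers — with full truth records — so the whole
pipeline is testable without sequencing data.  A consensus builder
(`ccsqc.ccs`) turns the raw multi-pass reads back into ccs reads:
adapter-split, per-fragment strand normalization, centre-star alignment
with plurality voting, and iterative polish (window repair plus
maximum-likelihood homopolymer run-length re-estimation).

## The core quantities

Phred score and error probability: `Q = −10·log₁₀(p)`, encoded in FASTQ as
ASCII `Q+33`.  Q60 means one error in 10⁶ bases; Q23 is 99.5% per-base
accuracy.  For a plurality vote over *n* independent passes each wrong
with probability *p* (spread over the 3 alternative bases), the per-column
consensus error is the multinomial tail probability that some wrong base
ties or beats the true one — at *n* = 9, *p* = 0.10 it is about 10⁻⁴,
which is how single-molecule coverage buys accuracy.  Consensus base
quality is reported as `min(93, round(−10·log₁₀(max(ε, 1−k/n))))` with
*k* the agreeing passes, *n* the column depth and `ε = 1/(n+1)²`.

## Worked example

```bash
# simulate a 200-molecule barcoded library, 5% ligation concatemers
ccsqc simulate --n-molecules 200 --seed 1 --chimera-fraction 0.05 \
      --design-out design.cfg --out reads.fastq --truth-out truth.tsv

# run the full QC pipeline and print the aggregate report
ccsqc report --design design.cfg reads.fastq
```

which prints (seed 1):

```
reads in            : 200
survivors           : 184
removed (unique)    : 16
percent removed     : 8.00%
per-filter failures (multi-failure reads count in each):
  zero_quality    0
  ambiguous_base  0
  avg_quality     0
  window_quality  0
  homopolymer     0
  length          16
  primer          10
  barcode         0
  chimera         16
reads >= 700 bp among quality-clean reads: 3.16%
per-barcode survivors:
  bc01     43
  bc02     48
  bc03     48
  bc04     45
```

All 16 planted order-2 concatemers are flagged by both the chimera and
length filters (10 of them also fail the primer check because their
second unit was ligated in reverse orientation); every intact molecule
survives.  `ccsqc qc` additionally writes per-barcode FASTQs of the
survivors, a discard FASTQ and a per-read decision table; `ccsqc ccs`
builds consensus reads from simulated raw long reads (`ccsqc simulate
--long-reads`), and `ccsqc chimera` emits the motif-level annotation that
diagnoses each concatemer.

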