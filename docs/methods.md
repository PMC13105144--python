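# Methods

## The measurement model

A NaP-TRAP experiment compares, for every reporter mRNA, sequencing-based
abundance in a ribosome pulldown fraction against a matched input fraction.
The pipeline assumes:

- each sequenced **molecule** is one reverse-transcribed cDNA carrying a
  random 10-nt UMI; reads sharing a (reporter, UMI) pair are PCR duplicates
  of one molecule and must count once;
- replicate identity is carried by a 6-nt in-line barcode in the RT primer
  (read 2), not by Illumina indices; the two 4-nt anchors flanking the UMI
  validate read register;
- read 1 starts at the first base of the variable insert (or after a fixed
  sequence plus 0–2 untemplated stagger bases, when the i5 adapter cannot
  sit against the insert) and alone identifies the reporter;
- pulldown sampling intensity is proportional to input abundance × TE, so
  the ratio of normalized pulldown to normalized input counts estimates TE.

## Read-structure processing

Read 2 is consumed segment-by-segment in declared order — by default
[anchor 4 nt][UMI 10 nt][anchor 4 nt][barcode 6 nt][binding region] — with
the segment order fully configurable, since published designs may place the
binding region differently. Anchors are positional: their width is consumed
whether or not they match, and a failure (>1 mismatch by default) routes the
pair to *discarded*. Barcode matching is exact by default; a 1-mismatch
budget can be enabled and is safe only because whitelist construction
rejects barcode pairs within twice the budget. Unknown barcodes go to
*undetermined*. The UMI is appended to both mates' names after `#`, which is
where counting later finds it. Quality strings pass through untouched — no
quality filtering is performed at this stage.

Read 1 is 3′-trimmed at the leftmost occurrence (≤1 mismatch) of the
downstream fixed sequence when one is configured; if absent the read is kept
full length, since the insert may simply be longer than the read. Stagger
detection returns the smallest allowed offset at which the 5′ fixed sequence
matches within budget.

Accounting is exact by construction: every input pair lands in exactly one
of a barcode bin, undetermined, or discarded, and the report asserts the sum.

## Assignment and counting

The built-in assigner maps a read to the unique library record whose
(possibly truncated) insert matches the read prefix with at most
`max_mismatch` substitutions, comparing over min(read length, insert
length); `N` in a library sequence never matches. Two records within budget
means unassigned — no best-hit tie-breaking, because a truncated tiled
library can make near-ties common and silent misassignment is worse than a
dropped read. Exact hits short-circuit through a hash map whenever the
library's minimum pairwise Hamming distance exceeds twice the budget (which
makes an exact hit provably unique); everything else goes through a
vectorized Hamming scan. Assignments serialize as SAM with an all-match
CIGAR and an NM tag, so the counting module treats them exactly like
external aligner output. Indel-containing reads are out of scope — they are
an external aligner's job.

Counting includes a mapped, primary, non-supplementary alignment iff its
CIGAR match-base total (M and `=` operations; `X` excluded, since bowtie2
emits M and NM bounds mismatches separately) is at least `m1` and its NM
value at most `d1`; both comparisons are inclusive. The published default
`m1=100, d1=4` suits 124-nt inserts read at ≥104 nt; for the 75-nt reads the
simulator emits, the evaluation harness scales the floor to the aligned
length minus the mismatch budget. UMI deduplication is exact-match only (no
directional clustering): each distinct (reporter, UMI) pair counts once,
which makes counting order-invariant and idempotent. The read-cutoff report
uses inclusive thresholds (count ≥ T); a strict mode exists because
descriptions of the filter vary between "minimum of" and "more than".

## Normalization and TE

The spike-in scale factor is the median over ladder members of
count/expected-amount. No formula is prescribed for the assay beyond "use
the spike-ins"; median-of-ratios is this package's choice because it reduces
to the obvious answer on exact ladders, survives a single spike-in dropout
(zero-count members are excluded), and makes TE exactly invariant to
rescaling any sample's counts. The fallback without usable spike-ins is CPM
over reporter (non-spike-in) counts.

Per-replicate TE divides paired pulldown by input normalized counts;
replicate i of pulldown pairs with replicate i of input within a condition
(explicit overrides allowed — the assay barcodes replicates identically
across fractions). A zero normalized input yields a missing TE, never 0 or
infinity. Mean TE is the arithmetic mean of per-replicate ratios by default;
a log2 mode reports and averages log-ratios instead, since whether the
original tables average ratios or log-ratios is not documented. No
pseudocounts by default: the selector's raw-count floor on every input
replicate (100 reads by default) is the assay's stated mechanism for taming
ratio noise. Tables export as CSV with reporters sorted lexicographically
(byte-identical re-runs) and optionally into a single-file SQLite store,
whose path must be absolute.

## Groups and k-mer enrichment

Groups are rank-based and therefore invariant to monotone transforms of TE,
with ties broken by reporter name for determinism. Single condition: bottom
and top `rnum` fraction (default 0.1) of filtered reporters. Two conditions:
per-condition top/bottom fractions intersected into four quadrant groups,
which may be smaller than `rnum`·N or empty.

The enrichment statistic is this package's own definition (the assay's
figures show enrichment but no formula): for each of the 4^k k-mers
(k = 5 by default), presence frequency — a reporter counts once regardless
of occurrence multiplicity — in the group versus the background of **all**
filtered reporters, group members included;
log2 enrichment = log2((g+pc)/(G+2pc)) − log2((b+pc)/(B+2pc)) with
pseudocount 0.5; p-value = hypergeometric upper tail (the group as a draw
without replacement from the background); BH correction across all k-mers
within a group. Reporting can transliterate to the RNA alphabet.

## qPCR module

Technical replicates are averaged arithmetically on the Cq scale (a spread
above 0.5 cycles warns, but nothing is rejected). Sign convention, fixed
here because Cq arithmetic is error-prone: ΔΔCq = ΔCq_pulldown − ΔCq_input,
so translation value 2^−ΔΔCq exceeds 1 for well-translated reporters;
stability between input timepoints is t1 − t2 analogously. Amplification
efficiency is fixed at 2; per-primer efficiency correction and melt-curve
analysis are out of scope.

## Design calculators

Tiling emits windows at 0, step, 2·step, … while they fit (default 124-nt
window, 25-nt step, matching a 170-nt oligo with the default 24- and 22-nt
flanks); an optional final window anchored at the 3′ end covers UTR tails
not divisible by the step, off by default since the basic scheme is plain
sliding windows. Dilutions read "1:R" as 1 part in R total (2 µL + 1998 µL
is 1:1000). Mastermix volumes come from C1V1 = C2V2 with the remainder as
water, and error if the components alone exceed the final volume. The PCR
rule returns (first cycle reaching half of the observed curve maximum) − 4,
floored at 1, with first-crossing semantics on the raw curve — no smoothing.

## The simulator

`naptrap.simulate` draws true input abundance (log2-normal, σ = 0.5) and
true TE (log2-normal, σ = 1) per reporter, then samples molecules per
(fraction, replicate) multinomially — input weights ∝ abundance, pulldown
weights ∝ abundance × TE — with spike-ins injected binomially at the
configured read fraction (default 1%, constrained to the recommended
0.1–2% band) and split 1:5:25:50:125 across the ladder. Each molecule gets
a UMI (unique per reporter within a sample: a colliding UMI would be
indistinguishable from a PCR duplicate and would make the truth table
inconsistent), a geometric number of PCR duplicate reads at the configured
rate, and per-base substitution errors (default 0.001) on both mates.
`reads_per_sample` counts unique molecules per (fraction, replicate) before
duplication, which makes UMI-dedup correctness exact by construction.
Read names encode the generating reporter, barcode, UMI and stagger offset,
so any stage can be scored without side tables. All outputs are
byte-identical given (config, seed).

What the simulator does **not** model — and hence what passing tests do not
show about real data: indels and quality-correlated errors, UMI errors
biased toward duplicates, overdispersed counting beyond the multinomial,
sequence-dependent capture or RT efficiency, and any mechanistic link
between insert sequence and TE (truth TE is assigned, not caused).

## Problem sizes and numerical choices

The end-to-end evaluation in the test suite and acceptance script uses 500
reporters × 3 replicates × 200,000 molecules per sample (1.2 M read pairs),
at which the log2 TE recovery correlation is ≈ 0.997; the calibration of the
k-mer null runs 100–200 random groups over a 200-reporter background at
k = 3. Floating-point invariants (normalization invariance, ΔΔCq
identities, Pearson against the textbook formula) are asserted at 1e-12
relative. CSV determinism relies on lexicographic reporter ordering and
sorted JSON keys.

## Known limitations

- The exact assigner handles substitutions only; real indel-bearing reads
  need an external aligner (any SAM/BAM with NM tags drops in).
- UMI collapsing is exact-match; at extreme depth per reporter
  (approaching 4^10 molecules) deduplication would undercount.
- No differential-translation statistics between conditions; the output
  tables are the intended interface to downstream testing.
- Zstandard-compressed I/O requires the optional `zstandard` package;
  gzip and plain text are always available.
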