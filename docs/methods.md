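# Methods

## The reference model

Coordinates are 1-based CDS positions (position 1 = the A of ATG),
intervals closed, and every sequence, mutation name and artifact class is
expressed in coding/sequenced-strand orientation; the barcoded (antisense)
strand enters only through complement mapping. The packaged ROIs are the
first 18 codons of *HBB* and *HBD*: both carry the Bsu36I site `CCTGAGG`
at 16–22 and differ in the gene-sorting hexamer at 33–38 (`CGTTAC` vs
`TGTCAA`).

The recognition motif defaults to the enzyme's degenerate site `CCTNAGG`,
not the literal wild-type heptamer. This is deliberate: substitutions at
the degenerate position (CDS 19) leave the molecule cleavable, so they are
invisible to the method, and only under the degenerate motif does the
observable set come out at 12 point mutations over 6 informative positions
— 18 site-breaking substitutions minus the 6 that fall in excluded
artifact classes (coding-strand C→A at 16–17, G→A and G→T at 21–22). Both
the motif and the artifact classes are configurable.

Observability is decided on the mutated product, not the mutation label: a
window of ± one motif length around the coordinate-mapped site locale is
rescanned, so deletions whose junction re-forms the site (e.g. removing
CDS 15–16 yields `…ACCTGAGG…`) are correctly classed as non-observable.
Deletions are left-normalized over repeats, so equivalent representations
(`19_21delGAG` ≡ `22_24delGAG`; `16delC` ≡ `17delC`) share one canonical
name. Deletion enumeration reports two counts — outcomes deduplicated by
product sequence (14 for the study ROI at ≤3 bp) and positional
representations (22) — because published tallies of "potential deletions"
do not state their convention; neither count is privileged by the code.
Insertions are classified (observable iff they disrupt the motif) but not
enumerated, the alphabet being unbounded.

## Read processing

Merged single-end reads have the fixed layout
`[14 nt primary barcode][4 nt ID-1][insert][5 nt secondary barcode][4 nt ID-2]`.
Processing steps, in order:

1. **Quality trimming** — sliding window of 3, Phred threshold 30,
   Trimmomatic semantics: cut at the first window whose mean falls below
   threshold, then retain individually good bases at the cut point.
2. **Structure parsing** — reads with unknown ID-1 or ID-2, a wrong
   3-base gene prefix, an empty insert, or identifiers that disagree on
   (donor, treatment) are rejected with a named reason; nothing is
   silently dropped.
3. **Gene sorting** — the hexamer at CDS 33–38 is tested at frame shifts
   −3..+3 with ≤1 mismatch against both discriminators; unique best match
   wins, ties are unassigned.
4. **Spike-in classification** — inserts carrying a configured replacement
   heptamer (`TTATGTT` or `ACGAGAC`) at the site span are resistant
   spike-ins; everything else is genomic.
5. **Variant calling** — global alignment against the ROI reference.
   Equal-length inserts with ≤6 mismatches take a Hamming fast path;
   otherwise a banded affine-gap Gotoh aligner runs (match +1, mismatch −1,
   gap open −3, gap extend −1, band ±10 around the length-difference
   diagonal). SNVs require base quality ≥28; indels are left-normalized
   through the reference model. Alignments below 80% identity raise an
   unalignable flag. The gap penalties and identity floor are package
   defaults exposed in configuration — no published values exist for them.

Primary barcodes are matched exactly; no barcode error correction is
applied (an error in a barcode creates a shallow family that the depth
filter discards, at a small yield cost).

## Consensus rules

Families are keyed by (donor, treatment, gene, primary barcode). Defaults:
a family needs ≥3 reads and ≥2 distinct secondary barcodes to be called at
all; a mutation is confirmed iff it appears in reads from ≥2 distinct
secondary barcodes *and* in ≥80% of the family's reads. These thresholds
are declared package defaults (config-exposed), chosen to make a sporadic
error unrepeatable across linear-amplification events; they are not claimed
to be the original workflow's exact decision tree, which is not public.
Because the amplicon is short, every read in a family is taken to cover
every insert position, so the support denominator is the family depth.

Two well-supported conflicting alleles at one position — or well-supported
spike-in and genomic reads under one primary barcode — mean two molecules
collided on one barcode; such families are `ambiguous` and excluded from
all counts. This is conservative and cheap at 14-nt barcode diversity
(4¹⁴ ≈ 2.7×10⁸ barcodes). A sporadic discordant read does *not* outvote a
well-supported spike-in family: the conflict itself must clear the
distinct-secondary bar.

Counting: each non-discarded, non-ambiguous family contributes exactly one
molecule. W = wild-type genomic, M per confirmed mutation, S = genomic
molecules whose consensus retains the recognition motif (the digestible
pool), R per resistant spike-in variant. Artifact-class SNVs are stripped
after consensus and logged; a family whose only mutations were artifact
class reverts to wild type for counting.

## Quantification

E = (f_S/f_D)·(S_u/R_u)/(S_t/R_t) with defaults f_D = 0.05 and f_S = 6
(their ratio, 120, follows from the stated mixture amounts); both are
per-sample configuration. The two resistant spike-in variants are summed
into R for estimation and reported separately for QC (the equal-mix design
implies ≈1:1). N = E·W + M. E < 1 warns (digestion failure) but computes.

Rates are x/N with Clopper–Pearson exact intervals; above n = 10⁶ trials
the equivalent Poisson/gamma bounds are used (relative error <10⁻⁶ at
these scales). N is treated as a known constant when forming CIs — the
calibration is designed so that E depends only on precisely known
quantities — and a delta-method standard error of E (independent-Poisson
counts) is available for simulation recovery bands. Per-base averages
divide by the number of informative positions (6); an optional
observability correction (×18/12) compensating for artifact-class
exclusions is off by default, matching the magnitudes of published
per-base averages. Pooling sums counts and exposures; pooling across
different ROIs is an error.

## Exact statistics

Implemented from first principles over scipy primitives (log-gamma, beta/
gamma quantiles, chi-square tails, root bracketing):

- **Fisher exact**: hypergeometric point-probability sums; two-sided = sum
  of outcomes no more likely than observed (the convention standard
  software uses).
- **Conditional odds-ratio bounds**: tail inversion of the noncentral
  hypergeometric likelihood, solved by bracketed root-finding on log ψ to
  relative tolerance 10⁻⁶. The published one-tailed bound for the carrier
  table ("1.5077–Inf") is the `greater` alternative at 95%; both
  conventions are exposed.
- **Exact binomial**: Clopper–Pearson CI and two-sided test; a Poisson
  path handles astronomically large n without enumerating the support, the
  far-flank crossover located by bisection on the monotone side of the pmf.
- **Rank-sum**: midranks for ties; full enumeration of group assignments
  for combined n ≤ 20 (two-sided = deviation of the rank sum from its
  permutation mean, symmetric under group swap); normal approximation with
  tie correction beyond.
- **Multisample proportion test**: Pearson score statistic against the
  pooled proportion, chi-square df = k−1; a Monte-Carlo mode conditions on
  the total count (multinomial over samples with probabilities ∝ exposure)
  for small expected counts.
- **Multinomial omnibus**: log-likelihood-ratio statistic against expected
  mutation-type proportions renormalized over the observable (non-artifact)
  types; Monte-Carlo tail. Expected rates are consumed as an external
  table; deriving genome-wide or context-adjusted expectations is out of
  scope.

Monte-Carlo p-values are reported with +1 smoothing, (k+1)/(n_sim+1), under
caller-supplied seeds. No multiple-testing correction is applied anywhere;
comparisons are reported unadjusted.

## The simulator

`SimConfig` defaults state the study conditions: 7×10⁷ genomes per donor
(the 60–80 million-cell regime), 65% material loss before amplification,
mean family size 5, untreated mix at f_D = 0.05 and f_S = 6, two resistant
spike-in variants. Error processes: per-copy polymerase errors, per-base
sequencing errors at a flat Phred score (default 37) — deliberately
pessimistic, since miscalled bases are *not* flagged by low quality and
must be removed by the consensus rule alone — and strand-aware damage
artifacts injected at the molecule level so they recur across all copies
of a molecule, exactly like real damage and unlike sporadic errors.

Desk-scale presets shrink cells to 10⁵–10⁶ and raise mutation rates to
10⁻⁵–10⁻⁴ so that expected event counts match the real experiment's
single-digit regime in seconds-to-minutes. The scales used by the shipped
tests: the error-suppression check runs 2.1×10⁵ molecules × ~5 reads
(≈10⁷ consensus bases); enrichment recovery pools 25 replicates per φ at
10⁵–10⁶ cells; CI coverage uses 200 replicates at 3×10⁵ cells. A
molecule-level fast path (`simulate_called_counts`) reproduces the called-
molecule tallies a perfect consensus stage would yield, for calibration
experiments where read-level noise is irrelevant.

What the simulator does **not** emulate: PCR amplification bias and
resampling (copies are sequenced once each), Illumina-specific error
profiles and quality distributions, barcode-synthesis biases, and chimera
formation. Passing tests therefore demonstrate the pipeline's logic and
calibration under a clean generative model, not robustness to every real
artifact.

## Numerical and degenerate-input choices

Two-sided exact sums use a 10⁻⁷ relative slack when comparing outcome
probabilities, guarding against float noise in ties. Degenerate Fisher
margins give p = 1 and (0, ∞) bounds. Zero denominators in E raise a
diagnostic error rather than returning infinity. Empty reads after
trimming are rejected, not processed. Consensus tables are ordered
lexicographically by family key, making every output independent of input
read order; all simulator randomness flows from the config seed, and a
fixed seed yields a byte-identical FASTQ stream.

## Known limitations

- Exposure uncertainty in E is not propagated into rate CIs (N is treated
  as known, as the calibration design intends); a bootstrap would be the
  natural extension.
- The consensus support denominator assumes full-length inserts; datasets
  with partial-coverage reads would need per-position coverage tracking.
- Clonal dependence during spermatogenesis is deliberately not corrected:
  the raw sperm fraction is the evolutionarily relevant quantity.
- The relabeling-control oligo is not modeled; secondary-barcode
  relabeling is assumed negligible.
- Duplex (two-strand) consensus and cross-family mutation phasing are out
  of scope.
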