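# Methods

## Study design being emulated

Six bulk RNA-Seq libraries — primary (PR), crown (CR) and seminal (SR)
maize roots, each untreated or exposed to 100 mM NaCl for 24 h — with one
library per root × condition and on the order of 10⁶–10⁷ uniquely
gene-mapped reads each. All inference is therefore between two single
libraries: there is no replicate structure anywhere in the design, which
dictates both the choice of test and the simulation model.

## Clean-read filtering

Three rules in fixed order, a read being removed by the first rule it
violates: adaptor contamination, N fraction, low-quality fraction.
Decisions taken where the procedure leaves room:

* **Adaptor detection is exact substring match** of the full adaptor, no
  mismatches or partial-prefix mode. It is the simplest verifiable
  criterion; adaptor sequences are a required input since none are fixed by
  the procedure itself.
* **Both thresholds are strict inequalities** ("greater than 10 %",
  "greater than 50 %"): a 100-base read with exactly 10 Ns, or exactly 50
  bases at quality ≤ 5, is retained.
* Attribution of a multiply-defective read to the *first* violated rule
  makes the per-rule removal counts well defined.
* Quality encoding is Phred+33 by default with a Phred+64 dialect flag.

## RPKM

RPKM = 10⁶·C/(N·L/10³) with N the total of reads uniquely aligned *to
genes* (the formula's own definition of N), not to the genome. Within a
library, Σ over genes of RPKM·L/10³ is exactly 10⁶ — asserted as a
conservation test. Printed-table percentages are rounded half-away-from-zero
to two decimals (one decimal for down-regulated fractions), the convention
consistent with the published tables.

## Exact between-library test

The point mass p(y|x) above is evaluated in log-gamma space; the two
gammaln(·+1) terms are combined in sorted order so that x↔y symmetry at
N₁ = N₂ holds exactly in floating point. The two-sided p doubles the
smaller of the cumulative tails around the observed y, capped at 1. The
lower tail is a cumulative sum via the multiplicative recurrence
p(k+1|x) = p(k|x) · r/(1+r) · (x+k+1)/(k+1), r = N₂/N₁; the upper tail is
1 − (lower tail below y), refined by direct truncated summation from y
upward whenever that subtraction would be ill-conditioned (tail below
10⁻⁶). p-values within 10⁻¹² of 1 are snapped to 1. A vectorised whole-table
path uses the identity of p(·|x) with the negative-binomial pmf
NB(x+1, N₁/(N₁+N₂)), whose tails are regularized incomplete beta functions;
tests pin the scalar, vectorised, exact-rational and brute-force-summation
routes together.

Calling: q ≤ 0.001 (Benjamini–Hochberg step-up per comparison by default;
Benjamini–Yekutieli selectable) and |log₂(salt/control)| ≥ 1, both
boundaries inclusive. The log₂ ratio is computed from RPKM, so library size
and gene length cancel consistently; raw counts enter the test itself. A
gene with zero counts in either library is `undetected` rather than
pseudocounted, matching the "no expression in at least one sample" gray
class, and genes absent from both libraries are not tested at all (they
carry no information and would only inflate the correction family).
q-values are adjusted separately per root comparison because DTG sets are
reported per root.

## Cross-root summaries

"Regulated" means called up or down; `undetected` and `not_significant`
never enter the set logic. A gene regulated in several roots counts once in
the union and is not root-specific, even when its directions conflict.
Down-regulated fraction = 100·down/(up+down), one decimal, half-away-from-zero.

## Clustering

Genes × comparisons matrices of log₂ ratios are clustered with Euclidean
distance and complete linkage. The agglomeration is implemented in the
package (rather than delegated) because leaf order is pinned by a
deterministic tie-break — among minimum-distance pairs, the lexicographically
lowest pair of cluster indices merges first — which generic linkage routines
do not guarantee; on tie-free data the merge heights coincide with SciPy's
complete linkage, asserted in tests. No row scaling or centering is applied:
the profiles are already log ratios and the display semantics color raw
regulation direction.

Missing ("gray") cells: distances use positions observed in both profiles.
Under the default `complete-rows` policy, genes with any missing value are
excluded from the dendrogram and appended, gray-masked, after the ordered
leaves; the `pairwise` policy clusters partially observed genes on their
shared positions, iteratively dropping genes that share no observed position
with the rest. Merge heights are checked non-decreasing on every run.

## GO over-representation

One-sided hypergeometric upper tail per term (equivalent to one-sided
Fisher), the standard test behind annotation tools of this kind; the
correction is Bonferroni with m = the number of terms annotating at least
one background gene, and significance means corrected p ≤ 0.05. The default
background is every annotated gene present in the count table. Annotations
are used as given — no propagation up the GO graph.

## qPCR

ΔCt = mean target Ct − combined reference Ct per condition, with the three
reference genes combined by the arithmetic mean of their per-replicate mean
Cts; ΔΔCt = ΔCt_treated − ΔCt_control; relative abundance 2^−ΔΔCt with
amplification efficiency fixed at 2 (classical method, no efficiency
correction). Concordance counts a gene as agreeing when the sign of the
log₂ qPCR ratio matches the RNA-Seq call direction; a ratio of exactly 1
agrees with nothing.

## Synthetic-data generator

The generator produces the *inputs* of the pipeline with planted ground
truth; its defaults are the emulated study conditions.

* **FASTQ**: 49-base reads (matching the study's reads-to-basepairs ratio);
  planted defect classes are mutually exclusive per read and exact in count
  (round(n·fraction)), so retained-read arithmetic has no sampling slack.
  Default contamination 5 % adaptor + 3 % high-N + 7 % low-quality.
* **Counts**: 5 000 genes × six libraries at baseline mean 400
  (≈ 2·10⁶ reads per library, inside the study's 10⁶–10⁷ range); gene
  lengths uniform on 200–5 000 bp. Per-gene means are lognormal
  (σ = 1 on the log scale, mean-corrected) and shared across libraries;
  planted genes sit exactly at the baseline mean so their effect size is
  exact, with the salt library of their root scaled by 2^log₂FC. Sampling
  is negative binomial with overdispersion α (variance μ + αμ²);
  **the default is α = 0, the Poisson limit**, because the exact test models
  Poisson tag sampling from single libraries — under that matched model the
  null false-call rate is controlled at the nominal FDR, while α > 0 is
  exposed as a sensitivity knob for studying the test's anti-conservatism
  under biological overdispersion. The default planting is 30 DTGs per root
  at |log₂FC| = 3, half down-regulated.
* **Annotations**: each of 50 terms annotates each gene independently at
  5 %; the planted term annotates the planted-DTG set at 10× the baseline
  odds.
* **qPCR**: Ct tables around 26 cycles (targets) / 18 cycles (references)
  with 0.1-cycle replicate noise; the treated target Ct is shifted by
  −log₂-ratio so ΔΔCt encodes the intended fold-change. The pipeline flips
  the sign for 30 % of assayed genes to emulate the imperfect (~70 %)
  confirmation rate such validations show.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: sequencing-error profiles and alignment ambiguity
(counts are drawn, not mapped), biological overdispersion under the default,
correlated gene expression, GO-term dependence from the ontology graph, and
amplification-efficiency variation in qPCR. Results on real libraries
additionally depend on the upstream aligner and annotation, which are
outside this package's scope (counts and annotations are inputs).

## Problem sizes

The analysis scripts and acceptance measurements use 10⁴ reads, 5 000 genes
(≈ 2·10⁶ counts per library), and 50-seed replicates of 1 000–2 000-gene
two-library simulations — sizes chosen so the complete study emulation,
including the 100 000-gene-test null calibration, runs in seconds on one
core while keeping per-library totals within the emulated study's range.

## Known limitations

* The exact test is anti-conservative under overdispersion; with single
  libraries per condition this is a property of the design, not fixable by
  the test. Replicate-aware models are deliberately out of scope.
* The published union/specific gene counts (444, 183/94/101) depend on the
  original raw data and are not reproduction targets; only the printed
  percentage and tally arithmetic is.
* "About 70 percent" concordance of 16 genes is ambiguous (11/16 or 12/16);
  the generator's 30 % discordance default realises 11/16 and the number is
  reported, not asserted.
* Complete linkage with the lowest-index tie-break makes dendrograms
  deterministic but means exact-tie layouts can differ from other tools'.
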