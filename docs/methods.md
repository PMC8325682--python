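# Methods

## Scope and model

`qpcrkit` models the analysis side of a stepwise SYBR-green qPCR protocol
for genes with close homologs. The underlying assumptions are the usual
ones for Ct-based analysis: Ct is linear in log template quantity over the
exponential phase, a perfectly efficient reaction doubles product each
cycle (so a twofold expression difference is one cycle), and reference
genes chosen for normalization must themselves be validated for stability
under the conditions of the study. Wet-lab steps (RNA extraction, cDNA
synthesis, melting curves, instrument control) are out of scope; the
toolkit consumes sequences and Ct tables and produces designs, fits,
fold changes, and rankings.

## Homolog ranking and SNP calling

Pairwise alignment is global (Needleman–Wunsch via Biopython's
`PairwiseAligner`): match +1, mismatch −1, gap −2 (linear) for DNA;
BLOSUM62 with −11/−1 affine gaps for protein. When several optimal
alignments exist the aligner's first is used, making results deterministic
for fixed inputs. Identity is defined as matching columns divided by
**total** alignment columns, so gap columns count against identity; this
is conservative and well defined without choosing a denominator sequence.
Candidates below `min_identity` (default 0.5 — a configurable stand-in,
since "lacks homology" has no canonical cutoff) are dropped; ties in
identity are broken by candidate id so the "most similar homolog" is
unique. SNPs are columns where both characters are non-gap and differ;
indel columns are never SNPs because a primer 3′ terminus over a gap has
no discriminating mismatch. Coordinates are 0-based half-open internally
and printed 1-based in reports. The protein-guided manual adjustment of
cDNA alignments that a human curator would do is deliberately not
modelled; the nucleotide alignment is used as-is.

## Primer design

The designer enumerates, for each SNP and each length in 20–23 nt, the
unique window whose 3′ terminal base is the SNP, on both strands, and
filters on GC 45–55% (inclusive bounds) and homopolymer runs ≤ 4. The
discriminating SNP is anchored on the final base by default; anchoring on
the penultimate base as well is not enabled because a terminal mismatch is
the stronger extension blocker. Melting temperature is intentionally not
filtered — annealing temperature is optimized empirically downstream — but
could be added as advisory metadata.

"Two primers next to each other" is operationalized as the unordered pair
of passing candidates minimizing (terminal-G/C preference, start-position
distance, leftmost start, total length); the terminal-G/C criterion is a
soft ranking bonus, never a hard filter. Selection is
feasibility-aware: the forward pool is first restricted to candidates that
can form a valid amplicon (85–125 bp on the plus strand including both
primers, at least one SNP strictly between the 3′ ends) with *some*
reverse candidate, and the reverse duo is chosen from candidates reachable
from the selected forwards. Without this restriction, an adjacency-only
choice frequently selects two forwards that no reverse can pair with, and
the assay comes back empty even when valid designs exist. When no
combination fits the standard bounds and extension is allowed, the upper
amplicon bound relaxes to `extension_cap` (default 200 bp). Assembled
pairs are labeled F1/R1 … F2/R2 by template position.

Degenerate inputs: a gene identical to its nearest homolog raises an
"indistinguishable" error; a template where every window fails the filters
returns an empty list plus a structured warning with per-constraint
rejection counts.

## Standard curves

The dilution series defaults to the canonical layout: 50 ng/µl stock
(1000 ng reverse-transcribed in 20 µl), stepwise factors 10, 20, 40, 80,
160, 1 µl per reaction, giving log₁₀(ng/reaction) values 0.69897 …
−0.50515. Fits are ordinary least squares of mean Ct on log input
(technical replicates averaged first, ND values never entering means);
R² is the squared Pearson correlation; efficiency is
(10^(−1/A) − 1) × 100. Acceptance defaults are R² ≥ 0.99 and E = 100 ± 5;
a stricter R² can be configured. Subrange search trims at most two points
from the high and/or low end (never interior points), keeps at least
three, and prefers (most points, highest R², smallest |E − 100|); a
subrange containing an ND mean is ineligible. A non-negative slope yields
`passes=False` with a "non-amplifying slope" warning rather than an
exception, and a slope numerically indistinguishable from zero reports
infinite efficiency. Condition optimization is sequential — temperature at
fixed concentration, then concentration at the chosen temperature, then
the dilution range — with ties broken toward the lower level. Primer
concentrations are treated as opaque ordered labels and never entered into
arithmetic, because reported units for such values are not always
trustworthy; ordering falls back to numeric value when a label parses as a
number.

## Quantification

Multi-reference normalization takes the **geometric mean of Ct values**
(the n-gene generalization of multiplying two reference Cts and taking the
square root). This is a deliberate fidelity choice: geometric averaging of
quantities, as geNorm normalization factors do, is not the same operation,
and the toolkit follows the Ct-space rule stated for the protocol it
implements. Each biological replicate is quantified independently against
the calibrator sample's mean ΔCt; the per-sample fold change is computed
from the sample's mean ΔCt, which makes the calibrator's reported fold
exactly 1, and the standard error is taken across the replicate-level
folds. The efficiency-calibrated method uses the Pfaffl ratio
b_target^ΔCt_target / b_ref^ΔCt_ref with per-gene bases b = 1 + E/100
restricted to (1, 2.5]; for a multi-gene reference the base is the
geometric mean of the member bases. With all bases equal to 2 the ratio
reduces algebraically to 2^−ΔΔCt, and the test suite verifies this to
1e−12.

## Stability methods

All five methods consume the bio-rep-mean Ct matrix (technical replicates
collapsed first). Each observation column is one (sample, biological
replicate).

* **CV%**: 100 × sample SD (n−1) / mean per gene.
* **Delta-Ct**: mean over partner genes of SD across samples of the
  pairwise Ct difference; ND observations are dropped pairwise.
* **BestKeeper**: per-observation geometric mean of Ct over genes is the
  index (observations with any ND excluded from the index); per gene the
  Ct SD (n−1), CV, and Pearson r against the index are reported, ranked
  by SD. SD rather than the original's median absolute deviation is used
  as the dispersion measure, keeping all five methods on the same (n−1) SD
  footing; a zero-variance gene has undefined r, reported as NaN and
  ranked by SD alone.
* **NormFinder**: a simplified form of the model-based estimator. Cts are
  sample-centered (per-observation mean across genes subtracted), then
  ρ_g = mean over groups of (|group mean residual deviation| + within-group
  residual SD / √n). The original publication's variance-shrinkage
  corrections are not reproduced; this simplification preserves the
  estimator's structure (inter- plus intra-group variation) and its
  ranking behaviour on planted effects, and the output is labeled
  accordingly. Note that sample-centering leaks 1/G of any single-gene
  shift into all genes, so a +δ group shift of one of G genes yields a
  group deviation of ±δ(1 − 1/G)/2, not ±δ/2; the tests assert this exact
  structure. Without groups, ρ is the residual SD.
* **geNorm**: quantities Q = base^(minCt − Ct) with per-gene bases from
  curve fitting when supplied (default 2.0); M_g is the mean SD of log₂
  pairwise quantity ratios; the worst-M gene is removed iteratively (ties
  removed by id, descending, for determinism), and the final two genes
  share average rank 1.5. At base 2, log₂(Q_g/Q_h) equals (Ct_h − Ct_g)
  plus a constant, so the initial M equals the Delta-Ct statistic exactly
  — an identity the tests check to 1e−10. V_{n/n+1} is the SD over
  observations of log₂ of the ratio of normalization factors (geometric
  means of Q) built from the n and n+1 top-ranked genes; the optimal panel
  size is the smallest n with V < 0.15.

Aggregation is RefFinder-style: each method's ranks (average ranks on
ties) are combined per gene by geometric mean; the final order is
ascending by score with ties broken by CV% then gene id.

## Synthetic data

The Ct generator writes Ct = baseline + group effect + dilution term +
N(0, noise_sd) + N(0, tech_rep_sd), with noise Gaussian on the Ct scale
(Ct is a log quantity, so this corresponds to log-normal expression
noise). The dilution term is log_base(factor/first factor), so a
noise-free series at base 2 fits to exactly 100% efficiency — a closed
form the acceptance checks exploit. Defaults: baseline 25 cycles (mid
assay range), technical jitter 0.1 cycles, 3 technical replicates. One
seeded generator is consumed in a documented order (genes outer, samples
middle, technical replicates inner), so a spec plus seed is byte-
reproducible. Each simulated sample is one biological replicate; the
generator does not model a separate within-sample biological-replicate
axis.

What the simulation does *not* emulate: pipetting covariance between
wells, plate and batch effects, Ct-dependent heteroscedasticity, PCR
inhibitors, primer-dimer artifacts, or genuinely ND reactions. Passing
tests therefore demonstrate the correctness of the algorithms under the
declared noise model, not robustness to every pathology of real plates.

The family generator draws an i.i.d. base sequence at the target GC
(G and C each at gc/2) and substitutes a shared set of SNP positions in
every copy, each copy drawing its own alternate base, positions kept
≥ 25 nt from the termini so anchored windows always fit; indels are not
planted because the SNP caller deliberately ignores indel columns.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path while remaining quick on one core: 600-nt families with 6 SNPs
(100 replicates), 5-point dilution series (500 randomized replicates for
the subrange oracle), stability panels of 7–8 genes × 12 observations
(50 seeded replicates for planted-gene recovery). The whole suite runs in
well under a minute.

## Known limitations

* NormFinder is the simplified estimator described above, not the full
  published variance decomposition.
* BestKeeper uses SD, not MAD, as its dispersion measure.
* Identity uses a gap-inclusive denominator; tools that divide by the
  shorter sequence length will report higher identities.
* The designer considers primer pairs only through the constraint set
  above; it does not screen for secondary structure, self-dimers, or
  cross-dimers.
* The simplex "two adjacent primers" heuristic picks one duo per strand;
  it does not enumerate all four-pair layouts to globally maximize the
  number of valid pairs.
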