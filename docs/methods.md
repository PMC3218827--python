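# Methods

This note documents the models, conventions, parameters and validation
design behind `idrsel`, in the order data flows through the pipeline.

## Codon substitution model

All likelihood machinery works on the 61 sense codons of the standard
nuclear code under MG94×HKY85: instantaneous change is allowed only between
codons one nucleotide apart, with rate

q_ij = (κ if transition else 1) · π_p(target nt) · m_ij,

where π_p is the position-specific target-nucleotide frequency and m_ij a
synonymous (α) or non-synonymous (β) multiplier.  Stop codons are excluded
from the state space, so no explicit rejection is needed.  The chain is
reversible; its stationary law is the product of positional nucleotide
frequencies restricted to sense codons.  Generators are normalized so one
unit of branch length equals one expected substitution per codon for a
neutral (α = β = 1) site; sites with other rates evolve proportionally
faster or slower.  Matrix exponentials use the symmetric eigendecomposition
of D^{1/2} Q D^{-1/2} (D = diag π), verified against dense `expm`.

* κ default 2.0 (a typical nuclear transition/transversion ratio).
* Positional frequencies: uniform (¼ each) in the simulator — this keeps
  synonymous/non-synonymous opportunity counting analytically checkable —
  and F3×4 estimated from the observed alignment in inference.

## Synthetic strain panels

`make_two_clade_tree` builds one ultrametric random-coalescence clade per
species (root-to-tip depth `within_depth`) joined through the root by stems
of length `between_depth` each; `simulate_gene` draws the root sequence from
the stationary law and evolves it along the tree.  Each codon carries its
own ω; the two stem branches may use a separate `omega_divergence` track.
The latter is what lets fixation and polymorphism be placed under different
selective regimes — without it a time-homogeneous simulator cannot produce
fixation-index contrasts at all, since FI depends only on the *ratio* of
divergence to polymorphism ω.

Confidence tracks emulate predictor output: truly structured residues get
state H/E with integer confidence ≥ 8 (flip probability `noise_flip_prob`
sends them below 8), truly disordered residues a score uniform on
[0.8, 1.0] (flips land uniform on [0, 0.5)).  The emitted score distribution
is therefore bimodal: cutoffs between 0.5 and 0.8 are equivalent on
synthetic tracks, while real predictor scores fill the whole interval.
Sweeps across {0.3, 0.5, 0.8, 0.9} still exercise the monotone-threshold
property.  Functional sites are Bernoulli per residue with class-dependent
rates.  A single integer seed drives a splittable generator
(`numpy.random.SeedSequence`); per-gene derived seeds are recorded in
alignment metadata and the fixture manifest.

What the generator deliberately does **not** emulate: indels (and hence
alignment uncertainty), recombination, realistic yeast base composition or
codon bias, predictor-correlated errors, and selection as a population
process (it writes selection directly into rates).  Passing tests therefore
demonstrate that the analysis recovers the signals the inference model is
built around, not that it is robust to everything real data contains.

## Alignment QC and masking

Mean pairwise protein identity uses positions ungapped in both rows of a
pair; the filtering funnel keeps genes at identity ≥ threshold (default
0.70, the study convention; 0.6/0.8 supported) and drops blacklisted genes
(recombination verdicts enter only as a list).  Low-frequency SNPs —
alleles carried by < 15% of a species' strains — are *replaced by the
species-majority allele* rather than deleted, preserving frame and
coordinates; ties break toward the species' first row.  If masking would
assemble a stop codon from alleles that never co-occurred, that codon
reverts to its original state.  An alternative exclusion mode
(`low_frequency_positions` + `ignore_positions` in `mk_counts`) treats such
positions as invariant instead.

## FEL site tests

Per gene: Tajima–Nei (1984) distances on comparable sites → neighbor-joining
tree (scikit-bio; negative branch lengths clamped to 0) → gene-wide ML fit
of κ, ω and a single branch-length scale (Nelder–Mead on log parameters,
F3×4 frequencies) → per-codon LRT.  The per-site alternative maximizes the
column likelihood over (α, β) via a profile in ω = β/α (bounded Brent on
log₁₀ω ∈ [−4, 4]) with a nested 1-d optimization of the overall rate
(bounded Brent on log-rate, with the rate → 0 boundary checked explicitly);
the null constrains α = β.  This parameterization handles the frequent
boundary optima (α̂ = 0 or β̂ = 0) more robustly than a 2-d quasi-Newton
start grid and is oracle-tested against an exhaustive 0.05-resolution grid.
P-values come from χ²(1); boundary effects make the test conservative, which
the neutral calibration study quantifies.  Gapped leaves contribute a
uniform partial likelihood; fully gapped and invariant columns are reported
neutral without optimization; identical column patterns within a gene share
one optimization.

## McDonald–Kreitman counting

Counting uses full strain panels, per nucleotide position of each codon
column: a position is a *fixed difference* iff both species are internally
monomorphic and differ, a *polymorphism* iff either species segregates (a
segregating position is never also fixed).  Changes are classified in codon
context; codons with several changed positions are scored by averaging
synonymous/non-synonymous tallies over all orderings of the single-
nucleotide steps, excluding orderings whose intermediates are stop codons
(if none survive, all are used).  Divergence paths run between the two
species' majority codons and are averaged over both species' codon
contexts, making counts invariant to species relabelling; codons holding a
position with more than two alleles in one species fall back to classifying
each minority change in the majority context.  Counts stay fractional for
FI and are rounded half-up for Fisher's exact test (scipy's two-tailed
exact p, verified against full hypergeometric enumeration).  FI is reported
only when dS, pN and pS are all positive; windows and composites without a
defined FI are non-informative and dropped.  Outlier removal drops FI
values more than 3 SD from the mean of the full defined set in a single
pass.  No multiple-testing correction is applied anywhere, deliberately:
the analyses are about aggregate associations, not individual-gene
discovery.

At high divergence multiple hits saturate the apparent dN/dS of fast sites
toward the random-codon-pair ratio; the validation studies keep stem depths
where this compression is mild (and it is one reason composite FI, not
per-site recovery, is the tested quantity).

## Enrichment, windows, correlations

Randomization enrichment compares the observed count n of selected sites of
one type in a scope of N codons to the count in repeated draws of N codons
from the pooled universe.  Drawing N exchangeable codons without replacement
and counting hits is distributionally identical to one hypergeometric draw,
so the null sample is generated as `rng.hypergeometric` (binomial for the
with-replacement variant) — bit-reproducible given the seed and fast enough
for calibration studies.  Two significance measures are reported: the
conventional z/t-style comparison of n to the null mean/SD, and the exact
empirical two-tailed p ( #{|n′−med| ≥ |n−med|}+1 )/(reps+1), which is the
preferred quantity.  Default reps = 10,000; class panels use P ≤ 0.001,
category panels P ≤ 0.01.

Sliding windows are non-overlapping 25-codon blocks (trailing remainder
discarded).  The selection series keeps windows with ≥ 1 positive site and
needs ≥ 5 points for a verdict; the FI series keeps windows with defined FI
and needs more than 5.  Spearman's r_s uses midranks; significance follows
the sample-size rules: n > 30 → z = r_s·√(n−1) against the standard normal
(the standard large-sample approximation), 5 < n ≤ 30 → the published
two-tailed α = 0.05 critical-value table (Zar's), n ≤ 5 → not assessed.
Category IDR ranking averages per-protein class fractions over members,
descending, ties lexicographic.

## Functional-sites index

Within mapped domain regions, residues are cross-classified functional ×
IDR; the index (LI/nLI)/(LnI/nLnI) is the odds ratio of functional-site
occurrence in IDRs versus non-IDRs, with a χ² test on the table.  Residues
not confidently disordered count as non-IDR (the dichotomy is IDR vs
everything else; an option restricts to confidently classified residues).
Duplicate domains can be filtered to the first-seen region.  Note the index
is an odds ratio: it equals the placement-rate ratio only in the rare-site
regime, which is where the recovery study operates.

## Validation studies and problem sizes

All study scales were fixed once, for statistical resolution at desk scale:

* **FEL calibration** — 200 genes × 100 codons, 3+3 strains, ω = 1,
  depths 0.02/0.2.  20,000 sites bound the positive-call rate at
  0.1 + 2·SE ≈ 0.104; the observed rate is far lower (boundary
  conservatism).
* **Disorder contrast** — 36 genes × 120 codons, 8+8 strains, depths
  0.08/0.8; structured classes ω = 0.4 within / 0.08 on stems, disordered
  background 0.3/0.3, one ≤ 30-codon adaptive disordered segment per gene at
  ω = 1 within / 4 on stems.  Yields concentrated positive calls in IDRs
  (enrichment ratio > 2 at empirical p ≤ 10⁻³) and composite FI ordering
  IDR > helix, strand.
* **Neutral MK recovery** — 100 genes × 200 codons, 8+8 strains, ω = 1,
  depths 0.04/0.4: thousands of pooled counts put the composite FI within a
  few percent of 1; the defined per-gene FI median lands in [0.8, 1.2].
* **Functional-site recovery** — 50,000-residue domain sets at rates 0.05
  (IDR) / 0.025 (other): rare-site regime, expected index ≈ 2.07.  A single
  draw has sampling SD ≈ 0.12, so the study reports the geometric mean over
  10 independent placements (Monte-Carlo error ≈ 0.016 on the log scale).
  The equal-rate control uses 200,000 residues at rate 0.1 so its SD sits
  well inside the ±5% band.
* **Randomization calibration** — 200 repetitions of uniform placement
  (universe 20,000, scope 5,000, 1,000 positives) at reps = 2,000.

The default full-scale fixture (`ProteomeConfig()`: 37+27 strains, 200
genes of 100–500 codons, ≈ 23% disordered residues, a fifth of genes with an
adaptive segment) mirrors the strain-panel scale of a real yeast
resequencing study and is used for file-based pipeline runs, not for the
timed validation studies.

## Numerical conventions

Coordinates are 0-based half-open internally and 1-based inclusive in all
written files.  Codon i encodes residue i; a shared terminal stop column is
stripped on read.  Likelihood scaling divides partial vectors by their
maximum per column and accumulates logs.  Optimizer tolerances: global fit
xatol 10⁻⁴ / fatol 10⁻⁷ on log parameters; site tests xatol 5·10⁻³ on
log₁₀ω and 2·10⁻³ on log-rate; LRT values are clamped at 0 and α̂ = β̂ ties
are called neutral.  All randomness flows from explicit integer seeds below
2³¹ derived via `SeedSequence`.

## Known limitations

Per-site FEL power at small panel sizes is low (a few percent inside
adaptive segments at the study scale); conclusions should rest on the
aggregate statistics.  The MK conventions (majority-codon contexts,
equal-weight path averaging) are one defensible resolution of choices the
field's tools leave unstated; they are oracle-tested, not claimed identical
to any particular legacy program.  The simulator's missing realism is
listed above; in particular identity filtering is nearly vacuous on
indel-free synthetic data, so the QC funnel is exercised mainly through
constructed low-identity fixtures in the tests.
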