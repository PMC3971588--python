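# Methods

This note records the statistical models, parameter choices, numerical
conventions and known limitations of `paleodup`.

## Strict-duplicate calling

Input is three collinearity anchor tables (focal–focal "Gr–Gr", and
focal–outgroup "Gr–Tc", "Gr–Vv"), each row an anchored gene pair with its
block IDs. The caller does **not** detect collinear blocks — that is
upstream tooling (MCScan-class software); its contribution is the
strictness filter:

1. candidate pairs are Gr–Gr anchors whose two genes lie in *different*
   blocks (tandem anchors within one block are not WGD pairs);
2. a gene anchored to more than one distinct partner has more than two
   focal copies (or is ambiguous under rearrangement) and is dropped with
   all its pairs — "strictly duplicated" means exactly two copies;
3. both genes must map to exactly one outgroup block each, and to the
   *same* block, in both outgroups. Region identity is block-ID equality,
   the only machine-checkable reading of "traced to a single region".

The output is deterministic, unique, and canonically ordered
(`gene1_id < gene2_id`). Coordinates (1-based inclusive, GFF3 convention;
BED input is converted) are attached from the annotation, and a
Circos-style links TSV can be written for plotting elsewhere.

## Normalization

RPKM: `value = count × 10⁹ / (length_bp × total_mapped)`; totals default
to column sums but can be supplied (e.g. genome-wide totals for a gene
subset). UQ: the per-sample factor is the 75th percentile of that sample's
*nonzero* counts; normalized values are `count / factor × G`, where `G` is
the geometric mean of all factors. The geometric-mean rescaling keeps the
output on a count-like scale and is stable under taking sample subsets;
the exposition of upper-quartile scaling leaves this global constant free,
so it is fixed here by convention.

## Per-pair log-ratio tests

Both paralogs of a pair are measured in the same libraries, so the
within-sample ratio cancels library effects. Per replicate,
`r = log2((x1 + c)/(x2 + c))` with pseudocount `c = 0.5` on normalized
values; the pseudocount prevents infinite ratios at zero counts while
preserving antisymmetry under paralog swap. With three replicates the
one-sample t-test of the mean ratio against 0 has df = 2. Pairs in which
*both* paralogs fall below a minimum-expression floor (mean normalized
value < 1 in the tissue) are excluded from testing rather than reported as
unreliable non-calls. Base-2 logs are used throughout so fold thresholds
(1.5/2/5×) convert cleanly. Zero replicate variance is flagged: p = 0 for
a nonzero mean, p = 1 for an all-zero ratio vector.

BH correction is applied per tissue across the pair family (per-tissue
families match per-tissue reporting); the DE universe for silencing
detection requires per-condition significance (the stricter reading of
"among differentially expressed paralogs").

## Reciprocal silencing and complementary expression

For a condition pair (A, B), the paralog-1 share is the mean over
replicates of `x1/(x1 + x2)` on normalized values (zero-total replicates
ignored; a pair with no expressed replicate in a condition is excluded
with a warning). A call requires BH significance in both conditions and a
share ≥ 0.95 in one condition and ≤ 0.05 in the other, boundaries
inclusive. Complementary expression is the GLM-side analogue without the
silencing requirement: per-tissue gene contrasts significant in both
tissues of a pair (q ≤ FDR) and the model-based dominant paralog
(proportion > 0.5) reversed between them; an exact 0.5 proportion yields
no dominant paralog and no call.

## Per-pair negative-binomial GLM

Counts (not pre-divided values) enter an NB2 likelihood with log link:

    log μ = β₀ + gene + tissue + gene:tissue + offset,  Var = μ + φμ²

with reference coding (gene 1 and the alphabetically first tissue are
references) and offsets `log(UQ factor)` so normalization happens inside
the count model. With 2 genes × T tissues the mean model is saturated over
cells (2T parameters), so fitted means barely depend on φ; the per-pair
dispersion MLE is found by alternating a GLM fit at fixed φ with a 1-D
profile maximization of the NB log-likelihood at fixed means (bounded on
log φ ∈ [log 10⁻⁸, log 50], converged when log φ moves < 10⁻³; typically
2–3 rounds). A boundary estimate (φ ≤ 2×10⁻⁸) falls back to Poisson with a
`poisson_fallback` flag. Separation (a gene unexpressed in a tissue)
yields large negative coefficients and a `near_boundary` flag rather than
a failure.

Contrasts are Wald tests on the fitted coefficient vector:

* **G** (1 df): gene coefficient plus the mean of the interaction terms —
  the paralog difference averaged over tissues;
* **T** (T−1 df): jointly, `tissue_t + ½·interaction_t` — the difference
  in pooled-paralog means between tissues;
* **G×T** (T−1 df): all interaction terms jointly;
* **G|T_t** (1 df): the paralog difference within tissue t.

Wald statistics are referred to `F(rank, n_obs − p)` rather than χ²: with
three replicates and an estimated dispersion the χ² reference is markedly
anti-conservative (empirically ~0.10–0.28 type-I at α = 0.05 in null
simulations), while the F form with the per-pair residual degrees of
freedom (12 for the 3-tissue, 3-replicate design) restores ~0.05. BH is
applied across pairs separately within each effect family (all p_G
together, etc., and per tissue for G|T). Each pair's category is the
unique combination of the three significance indicators: i = none,
ii = G, iii = T, iv = G×T, v = G+T, vi = G+G×T, vii = T+G×T,
viii = G+T+G×T; missing q-values withhold the category with a flag.

The pooled two-way ANOVA is a separate, classical Gaussian analysis on
log2(UQ + 0.5) values with gene (2·n_pairs levels) and tissue as fixed
factors, computed by direct mean decomposition (exact for the balanced
designs it requires and far cheaper than a design-matrix fit with
thousands of columns; cross-checked against an OLS ANOVA on a small
layout in the tests). At the reference scale of 1,971 pairs × 3 tissues ×
3 replicates the df are 3,941 (gene), 2 (tissue), 7,882 (interaction).

## dN/dS

NG86-style counting under the standard genetic code: at each codon
position the synonymous-site fraction is the number of the three
single-nucleotide mutations preserving the amino acid divided by the
number not creating a stop codon (so S + N = 3 per codon even next to
stops); differences between codons are averaged over all minimal
mutational pathways (1, 2, or 6 orderings), excluding pathways through
stop codons and renormalizing over the rest. Site counts are averaged over
the two sequences. Codons with gaps or N in either sequence, stop codons,
and codon pairs with all pathways blocked are excluded pairwise with
warnings; exclusion is additive (it never changes other codons'
contributions). Proportions are corrected with Jukes–Cantor,
`d = −(3/4)·ln(1 − 4p/3)`; p ≥ 0.75 sets a saturation flag with `d = NaN`
rather than infinity arithmetic, and ω is undefined when dS = 0. Results
are symmetric under swapping the two sequences.

## Downstream statistics

Categories are compared on ω with the two-sample Wilcoxon rank-sum test
(the groups are disjoint sets of pairs, so a paired signed-rank test is
undefined); W is reported on the rank-sum scale, exact null distribution
for min(n) ≤ 10 without ties, normal approximation with tie correction
otherwise. Pairs with undefined ω are excluded and counted. Positional
bias: every DE pair contributes its two gene locations, each labelled by
whether the local gene is the higher-expressed member; per chromosome,
sliding windows of 20 consecutive locations (50% overlap, configurable)
are tested against a fair coin with the exact two-sided binomial test and
BH-corrected across windows within each tissue. The window scheme is a
design choice — "chromosomal region" admits several readings and the
windowed one is deterministic and annotation-driven.

## Synthetic data

The count generator emulates a 2-species-style design reduced to one
species: paralog pairs × tissues (default petal, leaf, seed) × 3
replicates, NB2 counts with mean
`μ = q · (length/10³) · (libsize/10⁶) · 2^(tissue effect ± gene lfc/2)`.
Defaults, chosen once as the package's study conditions: expression levels
`q` log-uniform 50–1,000; shared-within-pair lengths 0.5–3 kb (isolating
expression from length effects); library sizes 0.2–0.4 M (20–40 M-read
libraries scaled down 100× for desk-scale runs); dispersion φ = 0.05;
scenario mix {null 0.08, G_only 0.22, G×T 0.25, G+T+G×T 0.25,
reciprocal_silencing 0.05, complementary 0.15}, mirroring a population in
which nearly all pairs show some expression divergence and silencing is
rare; gene/interaction effects 2 log2 units, tissue effects 1. Planted
tissue effects are randomized per pair (shuffled ramp, random interaction
sign): a tissue shift shared by every gene is indistinguishable from
sequencing depth and would be absorbed by normalization, so only
gene-specific tissue effects are plantable. The gene main effect keeps a
fixed positive sign so the planted mean log2 ratio equals the design
value. Silencing plants a 99%/1% split (safely beyond the 95% rule) in
the first two tissues and its mirror image; complementary plants 65%/35%
reversed. The `tissue_log2fc` magnitude is an addition to the design
surface — planting a T effect for the all-effects scenario requires one.

The codon-pair generator draws from fourfold-degenerate codon families
(GC*, GG*, CC*, CG*, CT*, GT*, TC*, AC*), placing each planted
substitution in its own codon: synonymous changes at the third position
within the family, nonsynonymous ones at positions 1–2 to a sense codon
with a different amino acid. Counting therefore recovers the planted
(Sd, Nd) exactly — the fixture validates the counter, not the biology of
multiple hits. The synteny generator builds per-ancestral-region block
structures with a planted strict fraction and decoy classes (focal
triplicates, outgroup-duplicated orthologs, tandem duplicates) for which
the correct caller output is the planted list exactly.

What the generator does **not** emulate: read-level artifacts (mapping
bias, multireads, the SNP-index correction used for cross-species
mapping), allopolyploid homeolog-specific expression, correlated
dispersion–expression trends, unbalanced designs, or batch effects.
Passing tests therefore demonstrate correctness of the statistics on
idealized NB data, not robustness to those real-data phenomena.

## Determinism and problem sizes

All generators take explicit seeds (NumPy `default_rng`); identical seeds
give byte-identical outputs, and the pipeline writes TSVs with a fixed
float format so re-runs checksum identically. Simulation-based checks use
desk-scale sizes chosen to make Monte-Carlo error small relative to the
tested margins: 10,000 pairs for t-test calibration, 800–1,000 pairs per
GLM condition, 200–400 pairs for detector logic, 500–1,000 random codon
fixtures.

## Known limitations

* The per-pair dispersion is estimated from 18 observations with no
  information sharing across pairs; it is noisy, and the F-referenced
  Wald tests compensate for calibration, not efficiency. Moderated
  (shrinkage) estimators are deliberately out of scope.
* The t-test's df = 2 gives limited power for pairs whose minor paralog
  sits near zero counts; some truly silenced pairs fail the DE
  precondition and are invisible to the silencing detector by
  construction.
* Time points are treated as conditions; no time-series model is fit.
* The strict-duplicate caller trusts the anchor tables; internal block
  rearrangements are resolved by dropping ambiguous genes, not by
  re-anchoring.
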