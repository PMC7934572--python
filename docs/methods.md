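# Methods

## Scope and data model

The package analyses diploid biallelic variant panels from inbred crop
collections.  The central container is a samples × variants dosage matrix
(0/1/2 copies of the alternate allele, NaN for missing) with per-variant
chromosome/position/allele metadata and an optional sample → subgroup map.
Coordinates are 1-based inclusive at the interfaces (VCF convention) and
0-based half-open internally for windowing.  Multiallelic records are
dropped at read time (counted, not split): every downstream statistic
assumes biallelic dosages.  Half-calls are treated as missing.

## Variant filtering and imputation

A variant is retained iff MAF ≥ `maf_min` (default 0.025) **and** missing
fraction ≤ `missing_max` (default 0.05), both computed over non-missing
genotypes; boundary values are retained, so the printed thresholds are the
edges of the retained region.  A variant failing both is counted once under
the MAF removal (fixed precedence so the report partitions the input).
Imputation (needed only for the GRM/GWAS path) replaces missing entries
with the per-variant mean dosage (fractional) or the modal dosage class.
Diversity statistics always use the unimputed matrix.  Haplotype-based
imputation is intentionally out of scope; the mean/major substitute is
adequate at ≤5 % missingness because the GRM and per-marker GLS are linear
in the dosages.

## Windowed diversity statistics

Windows are non-overlapping, width W = 500 kb by default, tiling each
chromosome; the trailing partial window is retained and flagged.

**π** per subgroup: Σ over segregating sites of the unbiased per-site
heterozygosity [n/(n−1)]·2p̂(1−p̂), divided by the *nominal* W (per-bp units;
resequencing convention — the denominator is genome span, not callable
sites; partial windows also divide by W, a documented bias toward small π
there).  Group-local p̂ and allele count n are computed per site over
non-missing genotypes; sites with n < 2 are skipped.  By default only SNPs
enter (indels optional via a flag).

**F_ST**: the Weir & Cockerham (1984) method-of-moments estimator θ with
per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals), computed from group allele
frequencies, sample sizes and observed heterozygote fractions.  Windowed
θ = Σa / Σ(a+b+c) (ratio of sums).  "Total" uses all subgroups; "pairwise"
restricts the components to each subgroup pair.  Sites monomorphic across
the compared groups, or with a group missing all data, are unusable;
windows with no usable site report NaN.  Negative windowed θ (small-n
noise; E[θ̂] has a −1/(n−1) component) is reported as-is, never clamped.

**r²**: squared Pearson correlation between unphased dosage vectors
(composite LD — phasing is out of scope), pairwise-complete over samples,
averaged over all intra-window variant pairs per subgroup, subsampled to
`max_pairs` (default 10,000) with a seeded generator when exceeded.  Pairs
with < 3 shared samples or a zero-variance member are skipped.

**Sharing**: a variant is "observed" in a group iff its alternate-allele
count there is > 0 — no frequency floor, matching the plain definition of a
private variant.  The exact set of observing groups defines the mutually
exclusive categories (private-G, shared-pair, shared-all, absent).
Per-accession private variants are those whose only alt carrier is that
accession.

## Structure analysis

**Distances**: pairwise genotype mismatch proportion p with weights 1
(opposite homozygotes), 0.5 (het vs hom; the expected allele-sharing under
a random allele draw) and 0 (identical), over sites non-missing in both
samples, then Jukes–Cantor corrected d = −¾ ln(1 − 4p/3); p ≥ 0.75 is
flagged infinite.  p is computed over variant sites only; a
`monomorphic_inflation` factor ≥ 1 optionally emulates dilution by
invariant genome positions (the choice does not affect tree topology, only
the scale).

**Neighbour joining**: the canonical O(n³) Saitou–Nei agglomeration on the
Q criterion; ties break to the lexicographically smallest active-node index
pair, making the output deterministic on degenerate inputs.  Negative limb
lengths are truncated to zero with the deficit moved to the sibling branch
(the pair's path length is preserved).  With an outgroup, the root is
placed at the midpoint of the outgroup's pendant edge; otherwise the
unrooted trifurcation is kept.  Trees are returned as scikit-bio TreeNode
objects and serialize to newick losslessly.

**Ordination**: classical MDS (PCoA) — double-centering of squared
Euclidean distances on mean-imputed, variant-centered dosages,
eigendecomposition, coordinates = eigenvector·√eigenvalue.  Negative
eigenvalues (possible for non-Euclidean inputs) are excluded from the
percent-variance denominator; requested axes beyond the positive-eigenvalue
count are truncated with a warning.  The leading two axes double as GWAS
fixed-effect covariates, computed on the same filtered/imputed marker set
used for the scan.

## Mixed-model association

Model y = Xβ₀ + g + e, g ~ N(0, σg²K), e ~ N(0, σe²I), with K the VanRaden
method-1 GRM (ZZᵀ / 2Σp(1−p), Z column-centered dosages) and X an intercept
plus the two ordination axes.  Variance components are estimated by REML
profiled over δ = σe²/σg²: after rotating by K's eigenvectors the
likelihood is a 1-D function of δ, maximized on a 100-point grid over
log₁₀δ ∈ [−5, 5] refined by bounded Brent search to 10⁻⁶ — deterministic,
no starting-value sensitivity.  Per-marker tests reuse the null components
(the EMMAX/P3D approximation; exact per-marker REML changes nothing
detectable at these scales): marker and phenotype are whitened by
(s_i + δ)^−1/2 in the rotated basis, residualized against X, and tested
with Wald (β̂/se)² ~ χ²₁, two-sided.  Markers with zero whitened variance
get p = 1 and a flag.  Significance: Benjamini–Hochberg step-up at q = 0.01
(largest i with p(i) ≤ i·q/m); the reported threshold is p(i).  No genomic
control is applied — the null simulations show the scan is well calibrated
with the two ordination covariates (KS distance ≈ 0.01 at m = 5,000).

Null-REML caveat: with an unstructured panel K ≈ I and h² is weakly
identified, so the null distribution of ĥ² is a boundary spike at 0 plus a
broad positive tail.  The tests assert this concentration behaviour on a
structured panel rather than an arbitrary point bound.

## Effect annotation

One canonical transcript per gene.  Classification order: splice site
(within 2 bp inside an intron boundary — standard convention) → CDS →
exon/UTR → intron → intergenic.  Coding SNVs mutate the affected codon
(strand-aware) and translate with the standard nuclear code: stop_gained,
stop_lost, start_lost (High); missense (Moderate); synonymous (Low).  CDS
indels: net length change % 3 ≠ 0 → frameshift (High), else inframe_indel
(Moderate).  UTR/intronic/intergenic → Modifier.  Functional classes
(coding SNVs and stop events): stop_gained → Nonsense; missense, stop_lost
and start_lost → Missense; synonymous → Silent.  Overlapping gene models
resolve by impact severity, ties by lowest gene id.  The annotator is
verified against an oracle that rebuilds the entire mutated CDS, translates
both proteins and diffs them, across simulated plus- and minus-strand gene
models.  Because one effect is counted per variant (no per-transcript
multiplicity), genome-scale effect totals are not comparable to annotators
that report one effect per transcript.

## SV and CNV

SV records carry accession, coordinates, SVTYPE ∈ {INS, DEL, DUP, INV,
TRA, INVDUP} and absolute SVLEN.  The length filter keeps the linear types
(INS/DEL/DUP by default) with 1 kb ≤ SVLEN ≤ 50 kb, bounds inclusive;
translocations and inverted duplications have no meaningful linear length
and are excluded from the filter but kept in summaries.  Windowed SV
density bins records by start position per subgroup.

CNV detection compares windowed read counts (100 kb default) between a
test and a reference sample.  The normalized ratio r = (x₁/μ₁)/(x₂/μ₂) is
transformed with Geary–Hinkley, t = (μ₂r − μ₁)/√(μ₂r² + μ₁), using
μᵢ = σᵢ² (Poisson approximation), and tested two-tailed against N(0, 1).
By default μᵢ is the *median* window count rather than totalᵢ/n_windows:
total-count normalization is biased whenever CNV segments occupy a visible
fraction of the genome (as they do on desk-scale test chromosomes), and the
median keeps neutral windows centered; pure total-count normalization
remains available.  P-values are BH-corrected across windows before the
alpha decision (alpha is a required, study-specific parameter); gain/loss
follows the sign of log₂r.  Windows with x₂ = 0 are flagged
"loss-candidate/undefined" rather than erroring.  Non-overlapping windows
by default; the simulator produces matching paired counts.

## Synthetic-data generator

The generator emulates the statistical structure of a three-subgroup
inbred collection, not its biology:

- **Genotypes**: per variant, ancestral frequency p ~ Uniform(0.05, 0.95)
  (guarantees polymorphism at desk scale); subgroup frequencies
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols model, mean p,
  variance F·p(1−p) — clipped to [0.001, 0.999] against degenerate draws.
  Haplotypes are drawn per site with first-order copying (probability rho
  of repeating the previous site's allele state), giving LD that decays
  geometrically with inter-site index distance; diploids pair consecutive
  haplotypes; missingness is uniform.  Defaults: 3 groups × 50 diploids,
  20,000 variants on a 50 Mb chromosome, F = 0.1, rho = 0 (independent
  sites — state-copying shrinks between-group frequency variance by
  (1−rho)/(1+rho), so LD is opt-in), 2 % missing.  Seeds are explicit
  everywhere; fixed seed ⇒ bit-identical output.
- **Phenotypes**: y = Σβ_j·dosage_j (+ optional GRM-distributed polygenic
  term) + Gaussian noise scaled from the realized genetic variance so the
  phenotypic variance fraction equals the configured h²; h² = 0 gives pure
  noise, h² = 1 returns the genetic value exactly.
- **SV calls**: per accession and type, counts ~ Poisson(rate·genome
  length), log-uniform lengths in [50 bp, 100 kb].
- **CNV counts**: reference window counts ~ Poisson(λ) with
  λ = depth·window/read_length (default 30× coverage, 100 kb windows,
  100 bp reads → λ = 30,000); test counts scaled by copy-number/2.  The
  per-window λ, not a per-window "depth of 30", is what makes the ratio
  test operate in its realistic regime.
- **Gene models**: 1–4 exons, ATG…stop CDS (length divisible by 3, no
  internal stops), UTRs, introns ≥ 30 bp, both strands, exon cuts at
  arbitrary transcript positions (codons straddle exon junctions).

Not emulated: recombination maps and coalescent genealogies (the LD model
is a Markov chain, sufficient to exercise the r² machinery but not decay
curves in bp), mutation-rate heterogeneity, genotyping error beyond
missingness, linked selection.  Passing tests therefore demonstrate
estimator correctness under the stated models, not robustness to every
property of real resequencing data.

## Numerical choices and degenerate inputs

- REML search bounds log₁₀δ ∈ [−5, 5]; h² at a bound means an effectively
  pure-noise or pure-genetic fit.
- PSD tolerance for K: eigenvalues ≥ −10⁻⁸·max; small negatives clipped
  to 0 in the spectral transform.
- NJ ties break to lowest node index; equal-distance inputs give a
  deterministic, documented topology.
- All-missing variants: frequency NaN, excluded from diversity statistics;
  imputation refuses them by name.
- BH with no passing p-value returns an empty set and an undefined
  threshold, never an error.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale:
differentiation recovery at 3×50 samples × 20,000 variants over 10 seeds,
GWAS calibration/power at n = 300, m = 5,000 over 20 seeds, CNV operating
characteristics over 10,000 null windows and 20 seeded duplication
replicates.  These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while completing in seconds.
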