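# Methods

## Screen simulator

The generator models the physical screen stage by stage.

**Cells and guides.** Each of `n_genes × guides_per_gene` targeting guides
and `n_nt_guides` non-targeting guides is carried by `cells_per_guide`
cells per replicate; replicates are independent cell populations. A
non-null gene (fraction `frac_nonnull`, default 0.10) shifts the latent
staining phenotype of all its cells by ±`effect_mean` (default 2, in units
of the per-cell noise SD `cell_noise_sd = 1`; sign chosen at random, gene
jitter `effect_sd` optional). All guides of a gene are equally effective —
variable knockdown efficiency is not modeled, which makes the simulated
per-gene signal somewhat cleaner than a real 5-guide library.

**Staining and gating.** Observed log-intensity is
`z + β·size + ε` with a standard-normal per-cell size covariate,
`β = size_coupling_beta` (default 1) and a small measurement noise ε
(SD 0.1). The sorter's size correction is modeled as ordinary
least-squares: the gate value is the residual of intensity regressed on
size, and the top and bottom `bin_fraction` (default 0.25, quartiles)
of the residual are sorted into the high and low bins — exactly
`⌊bin_fraction·N⌋` cells per bin. The functional form the actual
instrument used for its size correction is not public; OLS-residual
gating is the simplest model that removes the size–staining correlation,
and `gate_bins(..., gate_on_residual=False)` exposes the uncorrected gate
so the induced size bias can be demonstrated.

**Sequencing.** Within each bin, reads are multinomial over guides at
depth `reads_per_bin` (default 10⁶) with probabilities proportional to the
bin's guide composition; a Dirichlet-multinomial layer
(`overdispersion` = concentration scale) is available but off by default,
since amplification noise beyond multinomial sampling is not characterized.
Dead-cell exclusion, infection MOI, selection, and PCR bias are not
modeled.

Default problem sizes (1,000 genes × 5 guides, 500 NT guides, 250 cells
per guide, 2 replicates) are a scaled-down rendering of a genome-wide
library (~10⁵ targeting and ~4.6×10³ NT guides) chosen so that a full
simulated screen plus fit runs in about a second; effect sizes and the
non-null fraction match the conditions used throughout the error-control
studies.

## Gene-level test

Median-of-ratios size factors are computed over guides detected in every
sample (the DESeq-style estimator; the sample factor is exp of the median
log ratio to the per-guide geometric mean). Guide LFCs use pseudocount 0.5
in both bins and replicates are averaged with equal weight. The gene
statistic is the median guide LFC — robust to one or two inert guides in a
five-guide set. The null resamples NT-guide LFCs with replacement (medians
of k draws for a k-guide gene, shared across genes of equal k), giving a
two-sided permutation p with floor 1/(n_perm+1); BH runs over all tested
genes. This is a deliberate, documented alternative to MAGeCK's α-RRA —
numerical identity with MAGeCK output is not claimed, and a reader for
MAGeCK-style gene summaries (collapsing `neg|fdr`/`pos|fdr` to a single
two-sided FDR, direction from the LFC sign) is provided for ingesting
externally analyzed screens.

## Ranking score, hit rules, GSEA

The prerank score standardizes |LFC| and nlFDR = log10(1/FDR) by their
sample SDs (n−1 denominator, computed over the full gene table) and adds
them, signed by the LFC (D = +1 at LFC exactly 0). FDR values are floored
before the log: at 1/(n_perm+1) when they come from this pipeline's
permutation test, at 1e−12 when ingesting external tables that report 0 —
this keeps the log finite without reordering genes.

Two hit rules coexist because screens report both: the plain FDR < α
filter, and the volcano product rule |LFC|·(−log10 FDR) ≥ −log10 α whose
boundary is the constant-product hyperbola through (1, α). The product
rule admits large-effect/moderate-confidence genes that the plain filter
misses; both are monotone in effect size and confidence.

GSEA follows the standard preranked procedure: descending-score ranking
with ties broken by gene identifier (deterministic), weight exponent
p = 1 (hit steps ∝ |score|, normalized; miss steps 1/(N−N_hit)), ES = the
running-sum deviation of largest magnitude, a gene-label permutation null
(random same-size sets, shared across sets of equal size), NES = ES
divided by the mean |null ES| of the same sign, nominal p sign-stratified
with a +1 floor correction, and FDR from the pooled same-sign null NES
tail mass over the observed tail mass, clipped to [0,1]. Permutation
count, weighting, and set-size bounds (5–500) are the conventional
preranked defaults. If every member of a set scores exactly zero the hit
steps fall back to uniform rather than dividing by zero.

## Lipidome simulator and class enrichment

Species s in class c under perturbation j has log-abundance
`α_s + γ_s·phenotype_j + N(0, noise_sd)`, `γ_s ~ N(γ_class, jitter_sd)`;
the phenotype is standard normal across perturbations. Values emulate
replicate-averaged, NT-normalized log measurements, so replicate collapse
happens upstream of the regression, as in the deposited form of such data.
Defaults: 12 perturbations (the scale of a focused panel of lipid-pathway
knockdowns), noise SD 0.3, and a five-class panel in which SM (γ = 1.0)
and CE (γ = 0.8) are coupled while Cer, LacCer, and HexCer are null —
the structure the class-enrichment procedure is meant to detect. What the
generator does not emulate: compositional closure of lipidomics
measurements, heteroscedastic measurement error across abundance ranges,
and correlated species within a class beyond the shared γ; passing tests
therefore show correct behaviour of the estimator under its own model, not
robustness to those artifacts.

Per-species fits are OLS with intercept (R² = squared Pearson r; constant
abundance returns R² = 0 with a warning, a constant phenotype is an
error). The class test compares each class's R² sample against the R² of
*all* lipids — the class's own members included, taking the reporting
convention literally; `inclusive=False` gives the class-vs-complement
variant. Because the inclusive samples overlap, the textbook exact
two-sample K-S distribution does not apply; the exact p is instead
computed by enumerating every C(n, k) assignment of k class labels to the
n pooled values and counting assignments whose D(class, all) reaches the
observed one. Enumeration is used when the class has ≤ 10 members, the
values are tie-free, and C(n, k) ≤ 200,000; otherwise the asymptotic
two-sample p is used (ties always fall back to asymptotic). The exclusive
variant uses the standard exact distribution under the same small-sample
tie-free condition. No correction across classes is applied — raw K-S
p-values are reported.

## Cytometry and imaging formulas

Event intensities are summarized by medians throughout (robust to the
heavy right tails of fluorescence distributions). Relative ProteoStat is
(sample treated/sample spike-in) ÷ (control treated/control spike-in):
scale-invariant within each sample's pair, so staining-batch intensity
drift cancels. The pH-reporter ratio subtracts the cognate non-reporter
background median per channel and requires background < signal (no
clamping — a clamped value would silently hide a gating problem). The LMP
score is puncta per average-cell-area equivalent
(`count/(total_area/mean_cell_area)`), averaged over fields within a time
point, with the sample score the maximum over the time course; fields are
averaged after normalization, and pooling sub-fields before normalization
is equivalent (tested). Puncta counts and segmented areas are inputs —
image segmentation is out of scope. The pH calibration generator uses a
Henderson–Hasselbalch sigmoid (pKa 5.9) for the pH-sensitive channel so
generated ratios are strictly monotone in pH; inversion of the calibration
to absolute pH is deliberately not provided beyond this monotone
relationship, since measured ratios are the reported quantity.

## Numerical and design notes

- All generators and tests are deterministic under a fixed seed
  (`numpy.random.default_rng`); permutation nulls are seeded.
- GSEA ranking ties break by gene identifier; the permutation null for the
  inclusive K-S enumeration includes the observed assignment, so p ∈ (0, 1].
- Pipeline outputs are plain TSV/CSV; each file carries a 12-hex config
  hash and reruns with an identical config are byte-identical (no
  timestamps in outputs).
- Known limitations: no guide-efficacy heterogeneity, no copy-number or
  position effects, no paired-sample designs, no α-RRA reproduction, no
  compensation/spillover handling for real cytometry files.
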