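# Methods

This note records the models implemented in `chromden`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want to know.

## 1. The density sphere

For a gene whose TSS falls in bin *j* of an intra-chromosomal
interaction-frequency matrix, the chromatin density is the count of bins
strictly inside a sphere of radius R in model-distance units:

    Γ_j = Σ_{i≠j, IF_ij>0}  1[ (1/IF_ij)^e < R ].

Decisions baked into `hic.compute_gamma`:

* **Inside-sphere semantics.** The density counts loci *inside* the
  sphere. A `literal_form` flag evaluates the opposite
  (distance > R) count for audit purposes only.
* **Strict boundary.** A locus exactly at distance R is excluded; the
  characteristic function is 1 only for strictly positive argument.
  With e = 1 this makes Γ of a uniform chain equal 2⌊R⌋ per interior
  locus for non-integer R.
* **Zero-IF discard.** Bins with zero interaction frequency carry no
  distance estimate (quality control typically zeroes insignificant
  contacts) and never enter the count.
* **Diagonal excluded** by default: the self-bin IF is assay-dominated
  and is not an interaction. `include_diagonal` exposes the alternative.
* **Inter-chromosomal contacts are never consulted**; each chromosome's
  matrix is self-contained.
* **TSS approximation.** At 40-kb bins the TSS is the gene start ('+'
  strand) or end − 1 ('−' strand) under BED 0-based half-open
  coordinates; the bin index is floor(TSS / resolution) relative to the
  matrix's first bin.

Defaults R = 2, e = 1. The distance exponent e is only known to be
sensible in 1–3 (cross-validated in the 3D-reconstruction literature);
tests verify that the sign and significance of cross-condition density
shifts are unchanged for R ∈ {1, 2, 3}.

**Units.** Γ is measured in bins; one unit is `resolution_bp` (40,000 bp
default) of DNA inside the sphere. `physical_radius` inverts the sphere
volume at the measured human nuclear DNA density 0.0123 bp/nm³:
Γ = 20 bins of 40 kb corresponds to a ≈250 nm sphere, the scale of an
average TAD — so R ≈ 1–3 model units probe sub-TAD to TAD
neighbourhoods.

**Radial profile.** c(R) = Γ(R)/(4πR³/3). For the unfolded-chain control
(IF = 1/|i−j|), Γ grows linearly in R, so c ∝ 1/R². The acceptance check
fits the log–log slope on a grid of radii in (10, 49): below R ≈ 10 the
integer bin lattice makes Γ(R) = 2⌊R⌋ visibly staircase-like and biases
the slope upward (at R ≥ 10 the bias is < 0.03); above the grid the
chain ends would truncate the sphere.

**Density shift test.** Cross-condition comparison uses the paired
two-sided Wilcoxon signed-rank test on per-gene ΔΓ (zeros dropped, the
scipy default). The reported direction follows the median of the
*nonzero* changes: condensation confined to hotspots leaves most genes
untouched, and the all-gene median would read 0 even for a decisively
one-sided signal.

## 2. Crowding-scaled telegraph model

Reactions (single promoter copy; the TF molecule is sequestered while
bound):

    TF + P_off → P_on        propensity k_on · [TF]
    P_on → TF + P_off        k_off
    P_active → P_active + M  s_A
    P_silent → P_silent + M  s_R      (leaky transcription)
    M → ∅                    δ_M

For an activating TF the bound state is the active one; for a repressing
TF the bound state is silent and the free promoter transcribes at s_A.
Crowding scales the binding constants with the local density,

    k_on = k_on⁰ Γ^(−γ),  k_off = k_off⁰ Γ^(−γ−1),  γ = 0.36,

so K(Γ) = K(1)·Γ exactly (binding events become rarer but much longer
lived). Simulation is the exact Gillespie direct method (numba-compiled;
per-trajectory seeds drawn from a user seed, bit-reproducible).

**Defaults** (all per minute; k_on⁰ per molecule per minute):

| parameter | value | role |
|---|---|---|
| k_on⁰ | 0.01 | basal association |
| k_off⁰ | 5.0 | basal dissociation |
| n_TF | 10 | TF copy number |
| s_A | 10 | active transcription |
| s_R | 0.1 | leaky transcription |
| δ_M | 0.1 | mRNA decay (10-min lifetime) |

Rationale: at Γ = 1 the promoter switches fast relative to the mRNA
lifetime (ON dwell 0.2 min), giving a unimodal, low-CV steady state; by
Γ ≈ 100 both dwell times exceed the mRNA lifetime with ON occupancy
K·n_TF·Γ/(1 + K·n_TF·Γ) ≈ 0.66, giving a clearly two-state ensemble.
This traverses the unimodal → bursting → bimodal sequence inside
Γ ∈ (0, 100) robustly across seeds, with scaled k_on in
10⁻³–10⁻² /molecule/min and k_off in 10⁻³–5 /min — within the range
reported for DNA-binding proteins. With n_TF = 10 and one promoter, TF
depletion while bound changes the effective on-rate by ≤ 10%.

**Ensemble summaries.** The steady-state sample is the mRNA copy number
at t_end, one value per trajectory (1000 min, 1000 trajectories at full
scale; tests use 200). A "pulse" is an entry into the transcriptionally
active state; pulse frequency is counted after a 500-min burn-in.
Stationary-mean and Poisson (fixed-promoter) closed forms serve as
exactness oracles in the tests.

**Dip on copy numbers.** mRNA counts are lattice-valued; Hartigan's dip
against a continuous null reads heavy ties as spurious multimodality.
Sweep samples are therefore dequantized with seeded U(−½, ½) dither
before the dip test — modality at scales below one molecule is
meaningless. (The scRNA census needs no dither: CPM division by
variable per-cell totals already moves counts off the lattice.)

**Bifurcation scan.** Mode locations are peaks of a Gaussian KDE over
the steady-state sample (Scott bandwidth, peaks above 5% relative
prominence). An activating gene starts in a single low state and gains a
second, *higher* state under condensation; a repressing gene starts high
and gains a lower state.

## 3. Hartigan's dip test

The dip of an empirical CDF F_n is min over unimodal CDFs G of
sup|F_n − G|. The implementation (`_dipcore`) works on unique values
with band half-width c: a unimodal G within c/n of F_n must satisfy node
band constraints, be convex left of the mode and concave right of it,
with a single jump allowed at the mode. Per candidate mode placement,
side feasibility reduces to greatest-convex-minorant /
least-concave-majorant certificates that scale linearly in c (so the
per-junction minimum is closed-form), plus a coupling constraint — the
convex side's minimal terminal value must not exceed the concave side's
maximal initial value — resolved by bisection on c with
tangent-propagation passes. The junction min–max without coupling is a
lower bound that is already exact in most cases; bisection runs only
when it is not.

The test suite validates the implementation against an independent
brute-force oracle that solves the defining minimization as one linear
program per mode placement (`tests/_dip_oracle.py`); during development
the two agreed to < 10⁻⁸ on 4000+ random samples (uniform, normal,
separated mixtures, lattice/tied, U-shaped) up to n = 80. Closed forms:
dip of an equal-mass two-point sample is exactly 0.25; dip of n evenly
spaced points is 1/(2n), the universal minimum.

**P-values** are Monte Carlo against the uniform null (the standard
conservative reference): 10,000 uniform samples per n, generated from a
fixed internal seed independent of pipeline seeds, memoised per n;
p = (1 + #{null ≥ observed})/(B + 1). Exact-n tables are used rather
than interpolation across n — the workloads touch few distinct sample
sizes and exactness near the 0.01 threshold matters.

## 4. Single-cell heterogeneity cascade

* **CPM**: each cell scaled to 10⁶ total; zero-total cells are an error.
* **Per-gene stats**: mean and CV = sd/mean across cells (sample sd,
  n−1); zero-mean genes get CV = NaN and leave the analysis.
* **Intervals**: 50 logarithmically spaced boundaries between the
  smallest and largest positive mean; half-open [lo, hi), last interval
  closed.
* **High-CV rule**: the "CV < 3 stdev" exclusion is read as a
  within-interval z-score — flag genes with CV > interval mean + 3
  interval SDs — since genes in an interval share a mean and hence a
  technical-noise level; a literal CV > 3·SD variant is exposed as
  `literal_3sd`. Intervals with < 3 genes flag nothing (no meaningful
  SD). The rule is vulnerable to masking: if outliers make up more than
  ~1/(1+3/√k) of a k-gene interval they inflate the interval SD and hide
  themselves; at census scale (hundreds of genes per interval, a few
  percent variable) this is immaterial, but tiny gene panels cannot
  support the rule.
* **Equal-mean filter**: per-gene two-sided Wilcoxon rank-sum across
  cells + Benjamini–Hochberg; genes with q > 0.01 are retained
  (distribution-free against long-tailed CPM; standard FDR machinery).
* **Census**: dip p < 0.01 per condition over all shared genes, without
  the high-CV filter; reports per-condition counts, percent change,
  unimodal→bimodal switchers, and retention violations (bimodal in the
  stem state but not after differentiation) as explicit bookkeeping.

## 5. Synthetic worlds

**Polymer matrices.** Pair distances d_ij = |i−j|^ν in bin units,
IF = 1/d. Default ν = 1 — the fractal-globule-like contact decay
IF ∝ 1/s, and with e = 1 the analysis recovers exactly the generated
distances. Condensation multiplies distances *within* hotspot blocks by
a compaction factor in (0, 1] before inversion, so hotspot densities are
non-decreasing by construction and bins outside blocks are untouched
(pairs straddling a block boundary keep their distance). No ligation
noise, mappability bias, or matrix balancing is simulated: inputs model
the already-normalized matrices the analysis expects. A green recovery
test therefore establishes that the density machinery sees planted
condensation, not that it is robust to Hi-C artefacts.

**Gene annotations.** One gene per equal genome slot with jittered
start, so placements are non-overlapping and deterministic under a seed;
strands are Bernoulli(strand_fraction).

**Counts.** Gene means are log-normal (default log₁₀ mean 1.7, sd 0.6);
counts are negative binomial with variance μ + φμ² (default φ = 0.05),
scaled per cell by log-normal size factors (σ = 0.35) emulating
capture-efficiency variation. The Poisson term gives the decreasing
mean–CV technical trend; the size factors are what keeps CPM values of
low-count genes off the integer lattice, as in real data (the source
single-cell matrices are RSEM expected counts with widely varying
library sizes). Planted high-CV genes get φ multiplied by 10 in the
second condition at unchanged mean; planted bimodal genes are
two-component NB mixtures (per-condition component means and mixing
fraction; the default archetype 5 vs 500 at 50/50 mixing is decisively
bimodal at 300 cells). Planted genes draw their means uniformly from the
central ±1 SD of the mean law so their intervals have enough peers for
the 3-SD rule — an atom at a range boundary would concentrate planted
genes into one interval and mask them. Not emulated: batch effects,
dropout beyond NB zeros, gene–gene correlation, cell-cycle structure;
recovery results say nothing about those.

**Compositionality caveat.** CPM is compositional: mixtures planted only
in one condition add counts to that condition's cell totals and deflate
every other gene's CPM. At realistic gene numbers (≥ ~1000) the planted
mass is diluted below the rank-sum filter's detection level; toy worlds
with few genes and heavy planting will see the equal-mean filter reject
broadly. The pipeline's default synthetic world uses 1200 genes with
~5% planted for this reason.

## 6. Integration

* **Arrows**: per-gene (Γ, CV) in both conditions; quadrant from the
  sign pair (ΔΓ, ΔCV). Arrows with a zero component are "ties", reported
  separately and excluded from quadrant normalization (on real data at
  integer Γ ties are rare but not absent). Genes missing any coordinate
  are listed, never silently dropped; retained + ties + missing
  reconciles with the input exactly.
* **Quartile comparison**: Γ quartiles per CV class with seeded
  percentile-bootstrap CIs (default 1000 resamples) and a two-sided
  rank-sum p-value between classes.
* **Clustering**: Ward linkage on Euclidean distances between per-gene
  standardized Γ profiles; deterministic; cluster count is a user cut.
  Standardization is regularized — (x − μ)/(σ + 0.05|μ| + 10⁻¹²) — since
  a plain z-score maps flat profiles to amplified noise vectors and
  scatters the "no change" genes across clusters; the ridge keeps them
  near the origin. The externally supplied differentially-expressed gene
  list is removed before clustering (computing DE calls from bulk
  RNA-seq is out of scope).

## 7. Pipeline and reproducibility

`workflow.PipelineConfig` holds every path, threshold and seed (YAML
loadable, unknown fields rejected, missing inputs named per field).
Stages write TSV/JSON artifacts plus a JSON log with package versions,
seed, thresholds and SHA-256 input digests; a failed stage removes its
partial outputs. All randomness flows from explicit seeds
(`numpy.random.default_rng`; per-trajectory SSA seeds below 2³¹), and
reruns are byte-identical — the test suite asserts it.

## 8. Known limitations

* Γ is resolution-bound: at 40-kb bins, promoter-scale (sub-bin)
  structure and TF sliding are invisible; the TSS-bin approximation is
  the best available at this resolution.
* The crowding law is a mean-field power law; γ = 0.36 is taken as
  given, and no attempt is made to derive it from diffusion physics.
* The telegraph defaults are regime-representative, not gene-calibrated;
  absolute Γ thresholds for bimodality depend on them (only the
  qualitative sequence is asserted).
* The dip test calibrated on the uniform null is conservative for
  smooth unimodal alternatives and anticonservative for heavily
  discretized data; the dither/CPM arguments above address the lattice
  case but extreme zero-inflation is genuinely flagged as bimodal.
* Real-data headline figures (quadrant percentages, census growth,
  cluster sizes) depend on the specific datasets; synthetic worlds
  validate machinery and recovery, not those numbers.
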