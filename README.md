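# chromden

Chromatin density from Hi-C, crowding-scaled transcriptional bursting, and
single-cell expression heterogeneity — an integrated, testable pipeline for
asking how local chromatin condensation shapes cell-to-cell variability
during stem-cell differentiation.

The package is aimed at computational biologists who have binned
intra-chromosomal Hi-C interaction matrices, a gene annotation, and
single-cell RNA-seq count matrices for two (or more) cell states, and who
want locus-level density metrics, a mechanistic bursting model, and
heterogeneity statistics that join cleanly. Everything is driven from
Python; a synthetic-data module generates all three input kinds with planted
ground truth, so the full analysis is reproducible without external
downloads.

## The model

**Local chromatin density.** For a gene with TSS in genomic bin *j* of a
normalized interaction-frequency matrix IF (40-kb bins by default), the
density is

    Γ_j = #{ i ≠ j : IF_ij > 0 and (1 / IF_ij)^e < R }

i.e. the number of bins whose model distance 1/IF^e falls strictly inside a
*density sphere* of radius R around the locus (defaults R = 2, e = 1;
zero-IF entries are discarded). One Γ unit corresponds to one bin —
40,000 bp — of chromatin inside the sphere; at the nuclear DNA density of
0.0123 bp/nm³, twenty units fill a sphere of ≈250 nm, the scale of a TAD.
The cumulative radial distribution c(R) = Γ(R)/(4πR³/3) diagnoses folding:
an unfolded polymer gives c ∝ 1/R².

**Crowding-scaled telegraph model.** Transcription is a two-state promoter
(TF binding/unbinding, transcription at s_A when active and leaky s_R when
not, first-order mRNA decay) whose binding kinetics feel macromolecular
crowding through the local density:

    k_on = k_on⁰ · Γ^(−γ),   k_off = k_off⁰ · Γ^(−γ−1),   γ ≈ 0.36

so the equilibrium constant grows exactly linearly in Γ while both rates
slow. Exact Gillespie SSA ensembles show the consequences: pulse frequency
falls, the mRNA CV rises and then falls, and the steady-state distribution
bifurcates from one expression state to two as chromatin condenses.

**Heterogeneity cascade.** Counts are CPM-normalized; per-gene mean and CV
are discretized into 50 logarithmically spaced mean intervals; genes whose
CV exceeds their interval mean by 3 interval SDs are called highly variable
(the technical CV of scRNA-seq falls with mean, so only interval peers are
comparable); genes with differing mean expression between conditions are
removed (rank-sum q > 0.01 retained); and Hartigan's dip test (p < 0.01,
Monte-Carlo-calibrated, exact in-house implementation) counts bimodal genes
per condition.

**Integration.** Per-gene (Γ, CV) coordinates in two states become
*differentiation arrows*; quadrant fractions, bootstrap quartile comparisons
of Γ by CV class, and Ward clustering of per-gene density profiles complete
the picture.

## Worked example

`examples/02_crowding_bursting.py` sweeps density through the telegraph
model (200 trajectories × 1000 min per Γ) and prints:

```
 gamma  mean_mrna     cv  pulse_freq_per_min  dip_stat  dip_p  bimodal
   1.0      3.125 0.8463              0.0977    0.0215 0.6912    False
   8.0     14.990 1.1239              0.0406    0.0138 0.9995    False
  22.0     33.975 0.9514              0.0220    0.0208 0.7501    False
  43.0     42.940 0.9238              0.0141    0.0564 0.0005     True
  71.0     55.370 0.7821              0.0091    0.0907 0.0005     True
  99.0     63.545 0.6875              0.0063    0.1045 0.0005     True
```

Reading the table: as the local density Γ rises, the promoter switches ON
less often (pulse frequency 0.098 → 0.006/min — slower rebinding under
crowding), the population CV peaks at intermediate density, and from Γ ≈ 43
the dip test rejects unimodality — a second expression state has emerged.
The bifurcation scan in the same example locates the states (mRNA ≈ 6 and
≈ 88 at Γ = 43): an activating gene gains a second, *higher* state; a
repressing one gains a second, lower state.

`examples/03_scrna_heterogeneity.py` runs the single-cell cascade on a
2000-gene synthetic world and prints:

```
high-CV rule: 100% of planted high-variability genes flagged, 0.00% of null genes
equal-mean filter: 99% of genes retained (genes whose mean shifts between conditions drop out)
bimodality census: 20 -> 29 genes (+45%), 9 unimodal-to-bimodal switchers, 0 retention violations
```

The other examples cover the density metric on a condensing Hi-C pair
(`01`), arrows/quartiles/clustering (`04`), and the artifact-writing
pipeline with run logs (`05`).

## Acceptance script

`scripts/acceptance.py` re-runs the package's headline computations from
scratch — the unfolded-polymer c(R) ∝ 1/R² check, the full synthetic
pipeline (condensation pair → density table → heterogeneity cascade →
arrows/quadrants/census), and the scaled-down density sweep of the
telegraph model — and writes its JSON report to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; progress and summary numbers are
printed to stdout.
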