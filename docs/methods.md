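# Methods

This note records the statistical models implemented in `floraltraits`,
the defaults chosen where the underlying methods leave room, and what the
synthetic generators do and do not emulate.

## Data model

Trait tables are non-negative samples × variables matrices with per-sample
metadata (`species`, optionally `bee_group`) and a units tag. Relative
tables must have unit row sums (tolerance 1e-9) and are stored as fractions
internally; writers can emit percentages for display. Missing cells are
rejected outright: a compound that was looked for and not detected must be
an explicit 0, so a parsing failure can never silently become an absence.
Orientation (samples in rows vs columns) is a reader option, default
samples-in-rows. Reflectance spectra are percent values on one strictly
increasing wavelength grid, canonically 300–700 nm in 5 nm steps; values
above 100% are allowed (specular highlights against the white standard) but
flagged with a warning. Distance matrices must be symmetric to 1e-12 with a
zero diagonal.

## Color-hexagon vision model

Trichromatic bee vision is modelled in the color hexagon. For a reflectance
stimulus I(λ) (fractions; percent inputs are divided by 100):

    Q_i = Σ_λ I(λ) S_i(λ) D(λ) Δλ           (quantum catch)
    P_i = R_i Q_i,  R_i = 1 / Σ_λ I_B(λ) S_i(λ) D(λ) Δλ   (von Kries)
    E_i = P_i / (P_i + 1)                     (hyperbolic transduction)
    x = (√3/2)(E_G − E_UV),  y = E_B − (E_UV + E_G)/2

The adapting background thus always maps to E = (½, ½, ½), the hexagon
origin, and every locus lies within the unit hexagon. Integration is a
rectangle rule on the uniform grid (Δλ = 5 nm by default); spectra on other
grids are linearly interpolated when interpolation is enabled.

Three model components are configuration with shipped defaults:

- **Receptor sensitivities** — generated from the Govardovskii A1
  visual-pigment template (alpha plus beta band), peak-normalised, with
  λmax = 344 nm (UV), 436 nm (blue), 544 nm (green) — honeybee-like values.
  Users can substitute measured curves as CSV spectra.
- **Illuminant** — an analytic 6500 K Planckian spectrum in relative
  quantal flux, normalised at 500 nm: a smooth, data-free stand-in for open
  daylight. Because von Kries adaptation divides out the illuminant's
  interaction with each receptor, hexagon loci are insensitive to the
  broad-band details of this choice, and exactly invariant to its overall
  scale (asserted to 1e-12 in tests).
- **Green-leaf background** — a smooth template reflectance,
  0.05 + 0.10·exp(−((λ−550)/40)²): low in UV/blue with the green bump near
  550 nm.

Color contrast between two loci is their Euclidean distance in hexagon
units, classified against the bee discrimination band: below 0.062
indistinguishable, within [0.062, 0.100] uncertain, above 0.100
discriminable. Achromatic contrast is defined as the green-receptor
excitation difference |ΔE_G|, the convention for the bee long-wavelength
achromatic channel; this is a documented package choice since the hexagon
itself defines no achromatic measure. Species centroids are coordinate-wise
means of their loci; centroid distances use the same units and thresholds.

## perMANOVA and dispersion homogeneity

For a dissimilarity matrix d on N samples in a groups of sizes n_g:

    SS_T = (1/N) Σ_{i<j} d_ij²
    SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²
    SS_A = SS_T − SS_W
    F = (SS_A/(a−1)) / (SS_W/(N−a)),   R² = SS_A/SS_T

The null distribution permutes raw group labels whole (no residual
permutation schemes). Sampled p-values use the add-one convention
p = (1+b)/(1+m) with ties F* = F_obs counting as ≥ (tolerance 1e-12); the
exact option enumerates all distinct assignments of the label multiset and
reports the plain fraction ≥ observed (the observed assignment is part of
the enumeration). Degenerate inputs: SS_T = 0 (all samples identical)
returns F = 0, p = 1; SS_W = 0 returns a flagged result whose p comes from
permuting SS_A alone. Every stochastic operation takes a seed and is
bit-reproducible; pairwise tests reuse the full permutation budget per pair
(seeded per pair from the base seed) and Bonferroni-adjust by the number of
pairs. Degrees of freedom are always reported explicitly so that design
anomalies (e.g. a dropped replicate changing df from (7, 32) to (7, 31))
surface in the output rather than being absorbed.

Dispersion homogeneity follows the betadisper construction: principal
coordinates of the Gower-centred matrix −½ J d² J, with positive- and
negative-eigenvalue axes (eigenvalues within 1e-8 of zero are dropped)
tracked separately because Bray-Curtis is not Euclidean-embeddable. Each
sample's z_i is its distance to the own-group centroid with the squared
negative-axis contribution subtracted and floored at zero; a squared
distance below −1e-8 (relative) raises an embedding-consistency error. The
F statistic is a classical one-way ANOVA on z, tested by permuting z among
groups (the same construction as vegan's `betadisper` with centroid
dispersion). The dispersion result is reported alongside the perMANOVA and
never gates it.

## UPGMA and multiscale bootstrap

UPGMA merges the closest pair of clusters, with the distance from any
cluster C to the merged pair A∪B the size-weighted average
(n_A d(C,A) + n_B d(C,B))/(n_A + n_B), and stores join heights as merge
distance / 2, giving an ultrametric tree. Ties are broken on the
lexicographically smallest pair of cluster representatives (each cluster
represented by its smallest leaf label), so the tree is a pure function of
the labelled matrix, independent of input order. A brute-force oracle that
recomputes all pair averages from leaf members at every step is used in
tests (matrices up to n = 12).

Clade uncertainty uses multiscale bootstrap over *variables* — the
compounds/wavelength bands/analytes whose values feed each pairwise
dissimilarity — resampled with replacement at scales r ∈ {0.5, 0.6, …,
1.4} of the variable count (n' = round(r·n_vars)), n_boot = 1000 resamples
per scale by default. BP_r is the fraction of resampled trees containing
the reference clade. With σ = 1/√r and z_r = Φ⁻¹(1 − BP_r), the model
z = vσ + c/σ is fitted by weighted least squares with binomial
delta-method weights n_boot·φ(z_r)²/(BP_r(1−BP_r)); the approximately
unbiased p-value is AU = 1 − Φ(v − c), and BP at scale 1 is the ordinary
bootstrap proportion. BP values of exactly 0 or 1 are clamped to
1/(2·n_boot) from the boundary before the probit transform; curves
saturated at 1 (or 0) across all scales short-circuit to AU = 1 (or 0).
A clade never recovered at any scale gets AU = 0 with a diagnostic flag.
Newick export writes branch lengths and bracketed node comments
`[&AU=…,BP=…]`; labels containing structural characters are quoted.

## Indicator values

For variable j and group k: specificity A_jk = mean abundance of j in k
divided by the sum of that mean over groups; fidelity B_jk = fraction of
k's samples with j > 0 (presence is strictly > 0; inputs already encode
non-detection as explicit zeros); IndVal_jk = A_jk·B_jk, reported on the
0–1 scale. Each variable's statistic is max_k IndVal_jk; its p-value
permutes sample labels and compares the permuted max to the observed one,
per variable, with the add-one rule (exact enumeration available for tiny
n). No multiplicity adjustment is applied by default, matching common
usage; a Bonferroni column is available on request. Variables absent
everywhere are reported as IndVal 0, p 1, flagged.

## Univariate chemistry

One-way ANOVA on raw replicate concentrations, with group means/sd/n
recoverable from the result. Post-hoc pairwise comparisons default to
Tukey HSD at α = 0.05 (Bonferroni-adjusted pooled-variance t as an
option). The compact letter display uses the insert-and-absorb algorithm:
start from one column holding all groups, split every column containing
both members of a significantly different pair, absorb columns contained
in others, and assign letters in order of ascending group means; two
groups share a letter exactly when their comparison is not significant,
and the display is idempotent under regeneration from its own significance
pattern. Published summary F statistics computed on unavailable raw data
are not promised: when the replication unit or transformation behind a
printed table is ambiguous, this module guarantees only correctness on the
raw replicate data it is given.

## Synthetic data

The generators emulate the study design — 8 plant species (3 hosts of the
*Colletes succinctus* bee group, 3 of the *Melitta leporina* group, 2
outgroup species):

- **Scent**: 5 replicates per species, 80 compounds, relative abundances.
  Each species has a Dirichlet centre (sparse gamma(0.5) compositions);
  replicates are Dirichlet draws with precision 200 around it. A bee-group
  signature can be injected by boosting a designated fraction of compounds
  (default 10%) by a factor `effect_size` before renormalisation.
  `species_separation` blends the species centres with one global centre:
  at 0 every sample is an i.i.d. draw from the same composition — the
  exchangeable null used for permutation-test calibration, since clustered
  (species-structured) data are not exchangeable at the sample level and a
  sample-permutation test is not calibrated for group factors assigned at
  the species level.
- **Reflectance**: 10 flowers per species on the 300–700/5 nm grid, in
  percent: a flat baseline plus per-species Gaussian peaks plus truncated
  Gaussian noise, clipped at 0.
- **Pollen chemistry**: truncated-normal draws (at zero) per species ×
  analyte from given means/sd, n = 3; a built-in fixture carries the
  published per-species means/sd for polypeptide, total and essential
  amino acid, and sterol content (mg/g). Truncated normal rather than
  lognormal honours the symmetric mean/sd reporting of such tables; the
  distribution is pluggable.

All generators are pure functions of (spec, seed). What they do **not**
emulate: compound identities and realistic covariance among volatiles,
instrument drift and detection limits, petal optics (spectra are smooth
single-band caricatures), or correlations among pollen analytes. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the design's sampling structure, not that any biological
conclusion transfers to real measurements.

## Problem sizes and numerical choices

Test and acceptance workloads use the design sizes (8 × 5 scent tables,
199–999 permutations, 1000 bootstrap replicates per scale on 9-sample
3-cluster tables, 200-matrix UPGMA oracle sweeps, 500-replicate
calibration studies) — sizes at which every permutation statistic's
Monte-Carlo error is well inside the asserted tolerances. Ties in
permutation statistics count as exceedances at tolerance 1e-12;
eigenvalues within 1e-8 (relative) of zero are treated as null axes in the
principal-coordinate embedding; probit clamping uses 1/(2·n_boot). The
pipeline writes deterministic artifacts (wall-clock timings go to a
separate log), so identical config + seed reproduces byte-identical
bundles.

## Known limitations

- One-way designs only: no nested/multi-factor perMANOVA, no restricted
  permutation strata.
- The hexagon model is the only color space offered (no receptor-noise
  limited or tetrahedral models), and its default sensitivities/illuminant/
  background are idealised templates, not measurements.
- Bootstrap resamples variables, not samples; with few variables the BP
  curves are coarse and AU values for shallow clades are unstable.
- IndVal covers single-group indicators only (no site-group combinations).
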