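# floraltraits

Multivariate statistics for testing whether host plants of specialist bee
clades converge in floral scent, bee-perceived flower color, or pollen
chemistry.

Oligolectic (pollen-specialist) bees sometimes shift, over evolutionary
time, onto host plants that are phylogenetically and morphologically
unrelated to their ancestral hosts. One way to ask *why* is to compare the
floral traits of the host plants themselves: if the hosts of a bee clade
share scent chemistry, bee-perceived color, or pollen nutritional content,
that trait is a candidate filter guiding the host shift. `floraltraits`
packages the statistical machinery for that comparison:

- **Bee color-hexagon vision model** — reflectance spectra are weighted by
  UV/blue/green receptor sensitivities S_i(λ) and the illuminant D(λ) to
  give quantum catches Q_i = Σ_λ I(λ)S_i(λ)D(λ)Δλ, von Kries-adapted to a
  green-leaf background (P_i = R_i·Q_i with R_i set so the background gives
  P_i = 1), transduced as E_i = P_i/(P_i+1), and projected to hexagon
  coordinates x = (√3/2)(E_G − E_UV), y = E_B − (E_UV+E_G)/2. Distances in
  hexagon units are compared to the 0.062–0.100 bee discrimination band.
- **perMANOVA** — the pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)) on squared
  Bray-Curtis or Euclidean dissimilarities, with whole-label permutation
  p-values (add-one convention), pairwise tests with Bonferroni adjustment,
  and a betadisper-style multivariate dispersion-homogeneity check in
  principal-coordinate space.
- **UPGMA clustering with multiscale-bootstrap supports** — average-linkage
  dendrograms whose clades carry both the plain bootstrap proportion BP and
  the approximately unbiased p-value AU = 1 − Φ(v − c), obtained by
  resampling the variables at scales r ∈ {0.5, …, 1.4} and fitting
  z(σ) = vσ + c/σ to the probit-transformed BP curves (σ = 1/√r).
- **Indicator-value (IndVal) analysis** — Dufrêne–Legendre
  IndVal_jk = A_jk·B_jk (specificity × fidelity) per variable and group,
  with per-variable permutation p-values.
- **Per-analyte ANOVA with compact letter displays** — one-way ANOVA plus
  Tukey HSD (or Bonferroni-t) pairwise comparisons summarised as letters
  (shared letter ⇔ not significantly different).
- **Synthetic-data generators** — compositional scent profiles (8 species ×
  5 replicates × 80 compounds), smooth reflectance spectra (10 flowers per
  species, 300–700 nm / 5 nm), and pollen-chemistry tables, including a
  built-in fixture with the published per-species means/sd for
  polypeptides, amino acids and sterols (n = 3).

## Worked example

```python
from floraltraits import (ScentSimSpec, simulate_scent_profiles,
                          bray_curtis_matrix, permanova,
                          dispersion_homogeneity)

table = simulate_scent_profiles(ScentSimSpec(seed=11, effect_size=2.0))
dm = bray_curtis_matrix(table)
species = table.groups("species")
print(dispersion_homogeneity(dm, species, n_perm=999, seed=1))
print(permanova(dm, species, n_perm=999, seed=2))
```

prints

```
dispersion homogeneity: F_7,32 = 1.597, p = 0.176 (999 permutations)
perMANOVA: F_7,32 = 37.44, R2 = 0.891, p = 0.001 (999 permutations)
```

The dispersion check does not reject (within-species spread is homogeneous,
so the perMANOVA location test is interpretable), and the perMANOVA says
species explain 89% of the Bray-Curtis variation in scent, significant at
the smallest p reachable with 999 permutations (p = 1/1000). The reported
df (7, 32) are the between/within degrees of freedom for 8 groups and 40
samples. Longer narrative scripts — one per analysis track — live in
`examples/`:

```sh
python examples/scent_permanova.py
python examples/reflectance_hexagon.py
python examples/pollen_chemistry_clustering.py
```

A thin CLI wraps the same calls, e.g.

```sh
floraltraits simulate --kind chemistry --out demo --seed 2
floraltraits cluster --input demo/chemistry.csv --distance braycurtis \
    --nboot 1000 --scales 0.5:1.4:0.1 --seed 3 --out tree.nwk
floraltraits permanova --input demo/chemistry.csv --groups species \
    --distance braycurtis --permutations 999 --seed 42
```

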