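"""Synthetic inputs with the statistical structure the analyses assume.

The study design being emulated: eight plant species — three hosts of the
Colletes succinctus bee group, three hosts of the Melitta leporina group,
and two non-host outgroup species — characterised by

* floral-scent profiles: ~80 volatile compounds, 5 headspace replicates per
  species, expressed as relative abundances (compositional);
* flower reflectance spectra: 10 flowers per species, percent reflectance on
  the 300-700 nm / 5 nm grid;
* pollen chemistry: polypeptide, total and essential amino acid, and sterol
  concentrations (mg/g), 3 replicates per species, with the published
  per-species means and standard deviations available as a built-in fixture.

All generators are pure functions of (spec, seed): identical seeds give
bitwise-identical outputs. Scent compositions are Dirichlet draws around a
species-level centre; a bee-group signature is injected by boosting a shared
compound subset before renormalisation, so effect size 0 gives exchangeable
(null) data for calibration tests and large effects give power/recovery
tests. Concentration noise is truncated normal at zero, honouring the
symmetric mean/sd reporting of the source table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trait_io import SpectrumSet, TraitTable

__all__ = [
    "ScentSimSpec",
    "SpectraSimSpec",
    "ChemSimSpec",
    "simulate_scent_profiles",
    "simulate_reflectance_spectra",
    "simulate_pollen_chemistry",
    "table1_fixture",
    "STUDY_SPECIES",
    "STUDY_GROUP_MAP",
]

# the eight study plants and the bee group whose hosts they are
STUDY_GROUP_MAP = {
    "Aster_tripolium": "Colletes_succinctus_group",
    "Calluna_vulgaris": "Colletes_succinctus_group",
    "Hedera_helix": "Colletes_succinctus_group",
    "Lythrum_salicaria": "Melitta_leporina_group",
    "Medicago_sativa": "Melitta_leporina_group",
    "Odontites_luteus": "Melitta_leporina_group",
    "Echium_vulgare": "outgroup",
    "Reseda_lutea": "outgroup",
}
STUDY_SPECIES = list(STUDY_GROUP_MAP)


@dataclass
class ScentSimSpec:
    """Grouped compositional scent-profile generator settings.

    ``within_species_concentration`` is the Dirichlet precision: larger
    values give tighter replicate scatter around the species centre.
    ``between_group_effect`` is the fraction of compounds carrying a shared
    bee-group signature; ``effect_size`` the pre-normalisation boost factor
    applied to that subset (0 disables the signature entirely).
    ``species_separation`` blends each species' own Dirichlet centre with a
    global centre: 1 gives fully distinct species scent profiles (the study
    structure), 0 makes every sample an i.i.d. draw from one composition —
    the exchangeable null used for permutation-test calibration.
    """

    n_species: int = 8
    replicates_per_species: int = 5
    n_compounds: int = 80
    within_species_concentration: float = 200.0
    between_group_effect: float = 0.1
    effect_size: float = 0.0
    species_separation: float = 1.0
    group_map: dict[str, str] = field(default_factory=lambda: dict(STUDY_GROUP_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.replicates_per_species, self.n_compounds) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.between_group_effect <= 1.0:
            raise ValueError("between_group_effect must lie in [0, 1]")
        if not 0.0 <= self.species_separation <= 1.0:
            raise ValueError("species_separation must lie in [0, 1]")


def simulate_scent_profiles(spec: ScentSimSpec) -> TraitTable:
    """Relative-abundance scent table: Dirichlet replicates per species."""
    rng = np.random.default_rng(spec.seed)
    species = list(spec.group_map)[: spec.n_species]
    if len(species) < spec.n_species:
        species += [f"species_{i}" for i in range(len(species), spec.n_species)]
    groups = {sp: spec.group_map.get(sp, "none") for sp in species}
    k = spec.n_compounds
    # species centres: sparse-ish compositions (many rare compounds),
    # blended with a global centre by the species_separation weight
    glob = rng.gamma(shape=0.5, scale=1.0, size=k) + 1e-4
    glob = glob / glob.sum()
    centres = {}
    s = spec.species_separation
    for sp in species:
        base = rng.gamma(shape=0.5, scale=1.0, size=k) + 1e-4
        base = base / base.sum()
        mix = (1.0 - s) * glob + s * base
        centres[sp] = mix / mix.sum()
    # bee-group signature compounds
    n_sig = int(round(spec.between_group_effect * k))
    group_names = sorted(set(groups.values()))
    sig_sets = {}
    pool = rng.permutation(k)
    for gi, g in enumerate(group_names):
        sig_sets[g] = pool[gi * n_sig:(gi + 1) * n_sig]
    rows, sample_ids, meta_rows = [], [], []
    for sp in species:
        centre = centres[sp].copy()
        if spec.effect_size > 0 and n_sig > 0:
            boost = np.ones(k)
            boost[sig_sets.get(groups[sp], [])] = 1.0 + spec.effect_size
            centre = centre * boost
            centre = centre / centre.sum()
        alpha = centre * spec.within_species_concentration
        draws = rng.dirichlet(alpha, size=spec.replicates_per_species)
        for r in range(spec.replicates_per_species):
            rows.append(draws[r])
            sample_ids.append(f"{sp}_r{r + 1}")
            meta_rows.append({"species": sp, "bee_group": groups[sp]})
    values = np.vstack(rows)
    values = values / values.sum(axis=1, keepdims=True)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return TraitTable(
        values, sample_ids, [f"compound_{j + 1:03d}" for j in range(k)],
        meta, units="relative",
    )


@dataclass
class SpectraSimSpec:
    """Smooth flower-reflectance generator settings.

    ``peaks`` maps species -> list of (center_nm, width_nm, amplitude_pct)
    Gaussian reflectance peaks added to ``baseline_pct``; truncated Gaussian
    measurement noise of sd ``noise_sd_pct`` is added per flower.
    """

    n_species: int = 8
    flowers_per_species: int = 10
    grid: np.ndarray = field(
        default_factory=lambda: np.arange(300.0, 700.0 + 1e-9, 5.0)
    )
    peaks: dict[str, list[tuple[float, float, float]]] | None = None
    baseline_pct: float = 5.0
    noise_sd_pct: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.flowers_per_species) < 1:
            raise ValueError("counts must be positive")
        if self.peaks is not None:
            for sp, pk in self.peaks.items():
                if any(p[2] < 0 for p in pk):
                    raise ValueError(f"negative peak amplitude for {sp!r}")


def _default_peaks(species: list[str], rng: np.random.Generator):
    """One dominant reflectance band per species, spread over 380-660 nm."""
    centers = np.linspace(380.0, 660.0, len(species))
    return {
        sp: [(float(c + rng.uniform(-10, 10)), float(rng.uniform(35, 60)),
              float(rng.uniform(30, 60)))]
        for sp, c in zip(species, centers)
    }


def simulate_reflectance_spectra(spec: SpectraSimSpec) -> SpectrumSet:
    """Percent reflectance spectra: baseline + Gaussian peaks + noise >= 0."""
    rng = np.random.default_rng(spec.seed)
    if spec.peaks is not None:
        species = list(spec.peaks)[: spec.n_species]
        peaks = spec.peaks
    else:
        species = STUDY_SPECIES[: spec.n_species]
        if len(species) < spec.n_species:
            species += [
                f"species_{i}" for i in range(len(species), spec.n_species)
            ]
        peaks = _default_peaks(species, rng)
    wl = np.asarray(spec.grid, dtype=float)
    refl, labels, sp_col = [], [], []
    for sp in species:
        clean = np.full_like(wl, spec.baseline_pct)
        for c, w, a in peaks[sp]:
            clean = clean + a * np.exp(-(((wl - c) / w) ** 2))
        for f in range(spec.flowers_per_species):
            noise = rng.normal(0.0, spec.noise_sd_pct, size=wl.size) \
                if spec.noise_sd_pct > 0 else 0.0
            refl.append(np.clip(clean + noise, 0.0, None))
            labels.append(f"{sp}_f{f + 1:02d}")
            sp_col.append(sp)
    return SpectrumSet(wl, np.vstack(refl), labels, sp_col)


@dataclass
class ChemSimSpec:
    """Pollen-chemistry generator: per species x analyte mean and sd (mg/g).

    ``means`` and ``sds`` are DataFrames indexed by species with analyte
    columns; draws are normal truncated at zero.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    n_per_species: int = 3
    group_map: dict[str, str] = field(default_factory=lambda: dict(STUDY_GROUP_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.means.to_numpy() < 0).any() or (self.sds.to_numpy() < 0).any():
            raise ValueError("means and sds must be non-negative")
        if not self.means.index.equals(self.sds.index) or not (
            self.means.columns.equals(self.sds.columns)
        ):
            raise ValueError("means and sds must share species and analytes")


def simulate_pollen_chemistry(spec: ChemSimSpec) -> TraitTable:
    """Concentration table: truncated-normal replicates per species/analyte."""
    rng = np.random.default_rng(spec.seed)
    species = list(spec.means.index)
    analytes = list(spec.means.columns)
    rows, ids, meta_rows = [], [], []
    for sp in species:
        mu = spec.means.loc[sp].to_numpy(dtype=float)
        sd = spec.sds.loc[sp].to_numpy(dtype=float)
        for r in range(spec.n_per_species):
            draw = np.empty(len(analytes))
            for j in range(len(analytes)):
                if sd[j] == 0:
                    draw[j] = mu[j]
                else:
                    a = (0.0 - mu[j]) / sd[j]  # truncate at zero
                    draw[j] = stats.truncnorm.rvs(
                        a, np.inf, loc=mu[j], scale=sd[j], random_state=rng
                    )
            rows.append(draw)
            ids.append(f"{sp}_r{r + 1}")
            meta_rows.append(
                {"species": sp, "bee_group": spec.group_map.get(sp, "none")}
            )
    meta = pd.DataFrame(meta_rows, index=ids)
    return TraitTable(np.vstack(rows), ids, analytes, meta, units="concentration")


# Published per-species means (sd) for the four pollen analytes, mg/g:
# polypeptide, total amino acids, essential amino acids, total sterols.
_TABLE1 = {
    #                 polypeptide    total_aa      essential_aa   sterol
    "Aster_tripolium":   ((139.0, 17.7), (220.8, 7.5), (111.2, 3.9), (3.3, 0.2)),
    "Calluna_vulgaris":  ((133.7, 9.3), (290.0, 2.5), (145.7, 1.1), (9.8, 0.6)),
    "Hedera_helix":      ((135.6, 13.7), (325.4, 41.2), (144.4, 19.9), (4.2, 0.3)),
    "Lythrum_salicaria": ((32.2, 1.3), (315.2, 10.5), (150.8, 4.6), (16.9, 2.4)),
    "Medicago_sativa":   ((177.1, 17.9), (301.5, 13.5), (149.3, 6.5), (4.8, 0.3)),
    "Odontites_luteus":  ((225.9, 14.3), (363.3, 57.6), (167.6, 26.2), (4.8, 0.4)),
    "Echium_vulgare":    ((14.9, 0.8), (361.2, 11.8), (175.9, 6.9), (3.6, 0.3)),
    "Reseda_lutea":      ((84.5, 1.8), (342.7, 5.8), (156.4, 4.1), (8.5, 0.9)),
}
_ANALYTES = ["polypeptide", "total_amino_acid", "essential_amino_acid", "sterol"]


def table1_fixture(seed: int = 0) -> ChemSimSpec:
    """Chemistry generator preloaded with the published 8 species x 4 analyte
    means/sd (mg/g), n = 3 replicates per species."""
    means = pd.DataFrame(
        {a: [_TABLE1[sp][j][0] for sp in STUDY_SPECIES]
         for j, a in enumerate(_ANALYTES)},
        index=STUDY_SPECIES,
    )
    sds = pd.DataFrame(
        {a: [_TABLE1[sp][j][1] for sp in STUDY_SPECIES]
         for j, a in enumerate(_ANALYTES)},
        index=STUDY_SPECIES,
    )
    return ChemSimSpec(means, sds, n_per_species=3, seed=seed)
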