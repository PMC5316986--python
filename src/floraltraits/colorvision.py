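"""Bee color-hexagon vision modelling.

Trichromatic bees (UV / blue / green receptors) are modelled with the color
hexagon: a reflectance spectrum is weighted by each receptor's spectral
sensitivity and the illuminant to give quantum catches Q_i, von Kries
adaptation to a green-leaf background scales these to P_i = R_i * Q_i so the
background itself elicits P = 1 in every receptor, the hyperbolic transduction
E_i = P_i / (P_i + 1) maps catches to relative excitations in [0, 1), and the
three excitations are projected onto the hexagon plane

    x = (sqrt(3)/2) * (E_G - E_UV)
    y = E_B - (E_UV + E_G) / 2

Euclidean distances in (x, y) — "hexagon units" — predict discriminability;
behavioural discrimination thresholds for bees lie between 0.062 and 0.100
hexagon units.

Default receptor sensitivities are generated from the Govardovskii A1
visual-pigment template with peaks at 344 nm (UV), 436 nm (blue) and 544 nm
(green), honeybee-like values; the default illuminant is a 6500 K daylight-
temperature Planckian spectrum in quantal units and the default adaptation
background a smooth green-leaf reflectance template. All three are
configuration: any can be replaced by user-supplied spectra on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trait_io import DistanceMatrix, SpectrumSet

__all__ = [
    "VisionModel",
    "HexagonLocus",
    "DEFAULT_GRID",
    "DEFAULT_THRESHOLDS",
    "govardovskii_template",
    "default_sensitivities",
    "default_illuminant",
    "default_background",
    "build_vision_model",
    "default_vision_model",
    "receptor_excitations",
    "hexagon_locus",
    "spectra_to_loci",
    "color_contrast",
    "achromatic_contrast",
    "species_centroid_distances",
]

DEFAULT_GRID = np.arange(300.0, 700.0 + 1e-9, 5.0)
DEFAULT_THRESHOLDS = (0.062, 0.100)
RECEPTORS = ("UV", "B", "G")
_PEAKS_NM = {"UV": 344.0, "B": 436.0, "G": 544.0}


def govardovskii_template(wavelengths_nm: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band), peak ~1.

    Standard rhodopsin template parameterised only by the peak wavelength;
    used to generate receptor sensitivity curves when measured curves are
    not supplied.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_beta) / b) ** 2))
    s = alpha + beta
    return s / s.max()


def default_sensitivities(grid: np.ndarray = DEFAULT_GRID) -> SpectrumSet:
    """Peak-normalised UV/B/G sensitivity curves on the grid (unitless)."""
    curves = np.vstack(
        [govardovskii_template(grid, _PEAKS_NM[r]) for r in RECEPTORS]
    )
    return SpectrumSet(grid, curves * 100.0, list(RECEPTORS))


def default_illuminant(grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """Daylight-temperature (6500 K) Planckian spectrum, relative quantal flux.

    Normalised to 1 at 500 nm. Broad-band and smooth; von Kries adaptation
    removes any dependence on its overall scale.
    """
    wl_m = np.asarray(grid, dtype=float) * 1e-9
    h, c, k, T = 6.62607015e-34, 2.99792458e8, 1.380649e-23, 6500.0
    # photon (quantal) spectral radiance ~ lambda^-4 / (exp(hc/lambda kT) - 1)
    q = wl_m ** -4.0 / np.expm1(h * c / (wl_m * k * T))
    ref = (500e-9) ** -4.0 / np.expm1(h * c / (500e-9 * k * T))
    return q / ref


def default_background(grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """Smooth green-leaf reflectance template (fraction).

    Low in UV/blue with a chlorophyll-gap bump near 550 nm; plateau ~0.05-0.15.
    """
    wl = np.asarray(grid, dtype=float)
    refl = 0.05 + 0.10 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
    return refl


@dataclass
class VisionModel:
    """Receptor sensitivities + illuminant + adaptation background.

    ``R`` holds the von Kries factors R_i = 1 / sum_l I_B(l) S_i(l) D(l) dl,
    chosen so the adapting background yields P_i = 1 for every receptor.
    """

    wavelengths_nm: np.ndarray
    S: np.ndarray  # (3, n_wl) peak-normalised sensitivities, UV/B/G order
    D: np.ndarray  # illuminant, relative quantal flux
    I_B: np.ndarray  # background reflectance, fraction
    R: np.ndarray  # (3,) von Kries factors
    delta_lambda: float

    def quantum_catches(self, stimulus: np.ndarray) -> np.ndarray:
        """Q_i for a reflectance stimulus given as a fraction (not %)."""
        stim = np.asarray(stimulus, dtype=float)
        if (stim < 0).any():
            raise ValueError("negative reflectance in stimulus")
        return (self.S * (stim * self.D)).sum(axis=-1) * self.delta_lambda


def _interp(grid, wl, vals):
    return np.interp(grid, wl, vals)


def build_vision_model(
    sensitivities: SpectrumSet,
    illuminant: np.ndarray,
    background: np.ndarray,
    *,
    grid: np.ndarray | None = None,
    interpolate: bool = False,
) -> VisionModel:
    """Assemble a hexagon vision model from its three components.

    ``sensitivities`` carries three spectra in UV, B, G order (values may be
    on a 0-100 or 0-1 scale; each curve is re-normalised to peak 1).
    ``illuminant`` and ``background`` are arrays on the sensitivity grid, or
    on any grid with ``interpolate=True`` (linear).
    """
    if sensitivities.n_spectra != 3:
        raise ValueError("need exactly three receptor sensitivity curves")
    wl = sensitivities.wavelengths_nm
    if grid is None:
        grid = wl
    if not np.array_equal(grid, wl):
        if not interpolate:
            raise ValueError("sensitivity grid mismatch; pass interpolate=True")
        S = np.vstack([_interp(grid, wl, s) for s in sensitivities.reflectance])
    else:
        S = sensitivities.reflectance.copy()
    peaks = S.max(axis=1)
    if (peaks <= 0).any():
        raise ValueError("receptor sensitivity curve all-zero over the grid")
    S = S / peaks[:, None]
    D = np.asarray(illuminant, dtype=float)
    I_B = np.asarray(background, dtype=float)
    if D.shape != grid.shape or I_B.shape != grid.shape:
        raise ValueError("illuminant/background not on the model grid")
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0]):
        raise ValueError("model grid must be uniform")
    dl = float(steps[0])
    denom = (S * (I_B * D)).sum(axis=1) * dl
    if (denom <= 0).any() or not np.isfinite(denom).all():
        raise ValueError("background quantum catch not finite and positive")
    R = 1.0 / denom
    return VisionModel(np.asarray(grid, float), S, D, I_B, R, dl)


def default_vision_model(grid: np.ndarray = DEFAULT_GRID) -> VisionModel:
    """The shipped honeybee-like model on the canonical 300-700/5 nm grid."""
    return build_vision_model(
        default_sensitivities(grid), default_illuminant(grid), default_background(grid)
    )


def receptor_excitations(
    stimulus: np.ndarray, m: VisionModel, *, percent: bool = True
) -> np.ndarray:
    """Relative excitations (E_UV, E_B, E_G) for one reflectance spectrum.

    ``percent=True`` (the field convention for reflectance files) divides
    the stimulus by 100 before integrating.
    """
    stim = np.asarray(stimulus, dtype=float)
    if stim.shape[-1] != m.wavelengths_nm.size:
        raise ValueError("stimulus not on the model grid")
    if percent:
        stim = stim / 100.0
    Q = m.quantum_catches(stim)
    P = m.R * Q
    return P / (P + 1.0)


@dataclass(frozen=True)
class HexagonLocus:
    """A point in the bee color hexagon with its excitation triplet."""

    E: tuple[float, float, float]
    x: float
    y: float
    label: str = ""
    species: str = ""

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def hexagon_locus(E, label: str = "", species: str = "") -> HexagonLocus:
    """Project an excitation triplet (E_UV, E_B, E_G) into the hexagon."""
    E = tuple(float(e) for e in E)
    if len(E) != 3:
        raise ValueError("excitation triplet must have three components")
    if any(e < 0 or e > 1 for e in E):
        raise ValueError(f"excitations must lie in [0, 1], got {E}")
    e_uv, e_b, e_g = E
    x = (np.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return HexagonLocus(E, float(x), float(y), label, species or label)


def spectra_to_loci(
    spectra: SpectrumSet, m: VisionModel, *, percent: bool = True
) -> list[HexagonLocus]:
    """Convert every spectrum in a set to its hexagon locus."""
    if spectra.wavelengths_nm.shape != m.wavelengths_nm.shape or not np.allclose(
        spectra.wavelengths_nm, m.wavelengths_nm
    ):
        raise ValueError("spectra not on the vision-model grid")
    loci = []
    for refl, lab, sp in zip(spectra.reflectance, spectra.labels, spectra.species):
        E = receptor_excitations(refl, m, percent=percent)
        loci.append(hexagon_locus(E, lab, sp))
    return loci


def color_contrast(
    a: HexagonLocus,
    b: HexagonLocus,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[float, str]:
    """Hexagon-unit distance between two loci and its discrimination class.

    Distances below the lower threshold are ``indistinguishable``, above the
    upper ``discriminable``, and between them ``uncertain`` (behavioural
    thresholds for bees span the 0.062-0.100 range).
    """
    t_lo, t_hi = thresholds
    if not t_lo < t_hi:
        raise ValueError("thresholds must satisfy t_lo < t_hi")
    dist = float(np.hypot(a.x - b.x, a.y - b.y))
    if dist < t_lo:
        cls = "indistinguishable"
    elif dist <= t_hi:
        cls = "uncertain"
    else:
        cls = "discriminable"
    return dist, cls


def achromatic_contrast(a: HexagonLocus, b: HexagonLocus) -> float:
    """Green-receptor contrast |E_G(a) - E_G(b)| (long-wavelength channel)."""
    return abs(a.E[2] - b.E[2])


def species_centroid_distances(loci: list[HexagonLocus]) -> DistanceMatrix:
    """Pairwise Euclidean distances between species centroids in the hexagon.

    The centroid of a species is the coordinate-wise mean of its loci.
    """
    if not loci:
        raise ValueError("no loci given")
    species = sorted({l.species for l in loci})
    cents = []
    for sp in species:
        xy = np.array([l.xy for l in loci if l.species == sp])
        if xy.size == 0:
            raise ValueError(f"species {sp!r} has no loci")
        cents.append(xy.mean(axis=0))
    cents = np.array(cents)
    diff = cents[:, None, :] - cents[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceMatrix(d, species, "euclidean_centroid")
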