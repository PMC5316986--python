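"""Data model and I/O for trait tables, reflectance spectra and distance matrices.

The three containers here feed every downstream analysis:

* :class:`TraitTable` — a samples x variables abundance/concentration matrix
  (floral volatiles as relative fractions, pollen chemicals in mg/g) with
  per-sample metadata (plant species, bee group).
* :class:`SpectrumSet` — flower reflectance spectra in percent on a shared
  wavelength grid (canonically 300–700 nm in 5 nm steps).
* :class:`DistanceMatrix` — a labelled symmetric dissimilarity matrix.

Missing cells are rejected rather than zero-filled: "compound not detected"
must be encoded as an explicit 0, so that parsing errors cannot silently
become absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "SpectrumSet",
    "DistanceMatrix",
    "read_trait_table",
    "write_trait_table",
    "to_relative_abundance",
    "read_square_matrix",
    "write_square_matrix",
    "read_spectra",
    "write_spectra",
]

_ROW_SUM_TOL = 1e-9


@dataclass
class TraitTable:
    """Non-negative samples x variables matrix with sample metadata.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_variables)
        Abundances (relative fractions) or concentrations (mg/g).
    sample_ids, variable_ids : list of str
        Unique row and column labels.
    metadata : DataFrame indexed by sample id
        Must contain a ``species`` column; ``bee_group`` is optional.
    units : {"relative", "concentration"}
        When ``relative``, every row must sum to 1 (tolerance 1e-9).
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    units: str = "concentration"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.variable_ids) != k:
            raise ValueError("label counts do not match value matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.variable_ids)) != k:
            raise ValueError("duplicate variable ids")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_ids[j]!r}; encode non-detection as 0"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, variable {self.variable_ids[j]!r}"
            )
        if self.units not in ("relative", "concentration"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "relative":
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if bad.any():
                i = int(np.argmax(bad))
                raise ValueError(
                    f"relative-abundance row {self.sample_ids[i]!r} sums to "
                    f"{sums[i]}, not 1"
                )
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {"species": ["unknown"] * n}, index=self.sample_ids
            )
        else:
            self.metadata = self.metadata.loc[self.sample_ids]
            if "species" not in self.metadata.columns:
                raise ValueError("metadata must contain a 'species' column")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def groups(self, column: str = "species") -> np.ndarray:
        """Group label per sample, taken from a metadata column."""
        if column not in self.metadata.columns:
            raise KeyError(f"no metadata column {column!r}")
        return self.metadata[column].to_numpy()

    def subset_variables(self, variable_ids: list[str]) -> "TraitTable":
        idx = [self.variable_ids.index(v) for v in variable_ids]
        return TraitTable(
            self.values[:, idx],
            self.sample_ids,
            list(variable_ids),
            self.metadata.copy(),
            units="concentration" if self.units == "relative" else self.units,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_ids
        )


@dataclass
class SpectrumSet:
    """Reflectance spectra (percent) on one strictly increasing grid."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray  # (n_spectra, n_wavelengths), percent
    labels: list[str]
    species: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.atleast_2d(
            np.asarray(self.reflectance, dtype=float)
        )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.reflectance.shape[1] != self.wavelengths_nm.size:
            raise ValueError("reflectance columns do not match grid length")
        if len(self.labels) != self.reflectance.shape[0]:
            raise ValueError("label count does not match spectra count")
        if np.isnan(self.reflectance).any():
            raise ValueError("missing reflectance values")
        if (self.reflectance < 0).any():
            raise ValueError("negative reflectance")
        if (self.reflectance > 100).any():
            warnings.warn(
                "reflectance above 100% present (permitted but unusual)",
                stacklevel=2,
            )
        if self.species is None:
            self.species = list(self.labels)

    @property
    def n_spectra(self) -> int:
        return self.reflectance.shape[0]


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    d: np.ndarray
    labels: list[str]
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix not symmetric within 1e-12")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(
            self.d[np.ix_(idx, idx)], list(labels), self.metric_name
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# readers / writers


def read_trait_table(
    path,
    *,
    delimiter: str = ",",
    orientation: str = "samples_in_rows",
    metadata_columns: tuple[str, ...] = (),
    units: str = "concentration",
) -> TraitTable:
    """Read a labelled CSV/TSV trait table.

    First row holds variable labels and first column sample labels (or the
    transpose under ``orientation="samples_in_columns"``). Columns named in
    ``metadata_columns`` are split out as sample metadata, not data.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "samples_in_columns":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    meta_cols = [c for c in metadata_columns if c in df.columns]
    metadata = df[meta_cols].copy() if meta_cols else None
    data = df.drop(columns=meta_cols)
    arr = data.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # distinguish "non-numeric text" from genuinely empty cells
    if np.isnan(arr).any():
        raw = data.to_numpy()
        i, j = np.argwhere(np.isnan(arr))[0]
        cell = raw[i, j]
        what = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
        raise ValueError(
            f"{what} cell at sample {data.index[i]!r}, "
            f"variable {data.columns[j]!r}"
        )
    if metadata is not None and "species" not in metadata.columns:
        metadata["species"] = "unknown"
    return TraitTable(
        arr, list(data.index), list(data.columns), metadata, units=units
    )


def write_trait_table(
    t: TraitTable, path, *, delimiter: str = ",", percent: bool = False
) -> None:
    """Write a trait table as labelled CSV; metadata columns appended last.

    ``percent=True`` emits relative abundances x100 (display convention);
    the on-disk units tag is the caller's concern.
    """
    df = t.to_dataframe()
    if percent:
        if t.units != "relative":
            raise ValueError("percent output only applies to relative units")
        df = df * 100.0
    out = pd.concat([df, t.metadata], axis=1)
    out.to_csv(path, sep=delimiter, index_label="sample_id")


def to_relative_abundance(t: TraitTable) -> TraitTable:
    """Row-normalise to relative abundances (fractions summing to 1).

    Idempotent; preserves within-row rank order. Raises on all-zero rows,
    naming the offending sample.
    """
    sums = t.values.sum(axis=1)
    if (sums <= 0).any():
        i = int(np.argmax(sums <= 0))
        raise ValueError(
            f"sample {t.sample_ids[i]!r} has zero total abundance; "
            "cannot normalise"
        )
    return TraitTable(
        t.values / sums[:, None],
        t.sample_ids,
        t.variable_ids,
        t.metadata.copy(),
        units="relative",
    )


def write_square_matrix(m: DistanceMatrix, path, *, delimiter: str = ",") -> None:
    """Write a labelled square CSV; read-back reproduces d within 1e-12."""
    m.to_dataframe().to_csv(
        path, sep=delimiter, index_label="label", float_format="%.17g"
    )


def read_square_matrix(
    path, *, delimiter: str = ",", metric_name: str = "unknown"
) -> DistanceMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("row and column labels differ; not a square matrix")
    return DistanceMatrix(
        df.to_numpy(dtype=float), list(df.index.astype(str)), metric_name
    )


def read_spectra(
    path, *, delimiter: str = ",", species_from_label: bool = True
) -> SpectrumSet:
    """Read wide-format spectra: first column ``wavelength_nm``, one column
    per flower. Species inferred as the label part before the last ``_``
    (``Hedera_helix_f01`` -> ``Hedera_helix``) unless disabled."""
    df = pd.read_csv(path, sep=delimiter)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    labels = [str(c) for c in df.columns[1:]]
    refl = df.iloc[:, 1:].to_numpy(dtype=float).T
    if species_from_label:
        species = [lab.rsplit("_", 1)[0] if "_" in lab else lab for lab in labels]
    else:
        species = list(labels)
    return SpectrumSet(wl, refl, labels, species)


def write_spectra(s: SpectrumSet, path, *, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        s.reflectance.T, columns=s.labels
    )
    df.insert(0, "wavelength_nm", s.wavelengths_nm)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")
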