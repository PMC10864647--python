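"""Spectral calibration data containers and CSV I/O.

A calibration data set pairs absorbance spectra (M samples x N wavelengths,
mAU or arbitrary absorbance) with reference concentrations (M x P, g/L or
arbitrary) and carries per-sample group labels identifying the experiment
(chromatography run) each fraction came from.  Group labels drive the
leave-one-group-out cross-validation used throughout the package.

The on-disk dialect is two CSV files:

* spectra file:   ``sample_id,group,<wl_1>,<wl_2>,...`` with numeric
  wavelength headers (strictly increasing);
* concentrations: ``sample_id,<component_1>,<component_2>,...``.

Both are comma-separated, '.'-decimal, UTF-8, header row mandatory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "read_dataset", "write_dataset"]


class DatasetFormatError(ValueError):
    """Raised for malformed spectra/concentration files or inconsistent data."""


@dataclass
class SpectralDataset:
    """Paired spectra and concentrations with wavelength axis and group labels.

    Attributes
    ----------
    X : ndarray, shape (M, N)
        Absorbance spectra, one row per sample.
    Y : ndarray, shape (M, P)
        Reference concentrations, one column per component.
    wavelengths : ndarray, shape (N,)
        Strictly increasing wavelength axis (nm or cm^-1).
    component_names : list of str, length P
    groups : ndarray, shape (M,)
        Experiment/run label per sample (object dtype; any hashable labels).
    sample_ids : ndarray, shape (M,), optional
    """

    X: np.ndarray
    Y: np.ndarray
    wavelengths: np.ndarray
    component_names: list[str]
    groups: np.ndarray
    sample_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise DatasetFormatError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise DatasetFormatError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.X.shape[1] != self.wavelengths.size:
            raise DatasetFormatError(
                f"X has {self.X.shape[1]} columns but wavelength axis "
                f"has {self.wavelengths.size} entries"
            )
        if self.wavelengths.size < 2:
            raise DatasetFormatError("need at least 2 wavelengths")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DatasetFormatError("wavelength axis must be strictly increasing")
        if self.Y.shape[1] < 1:
            raise DatasetFormatError("need at least one component (P >= 1)")
        if len(self.component_names) != self.Y.shape[1]:
            raise DatasetFormatError("component_names length must equal P")
        if self.groups.shape != (self.X.shape[0],):
            raise DatasetFormatError("groups must have one label per sample")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(self.n_samples)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (self.n_samples,):
                raise DatasetFormatError("sample_ids must have one entry per sample")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    @property
    def n_components(self) -> int:
        return self.Y.shape[1]

    def group_labels(self) -> list:
        """Unique group labels in order of first appearance."""
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset by boolean mask or index array."""
        return SpectralDataset(
            X=self.X[mask],
            Y=self.Y[mask],
            wavelengths=self.wavelengths,
            component_names=list(self.component_names),
            groups=self.groups[mask],
            sample_ids=self.sample_ids[mask],
        )


def read_dataset(spectra_path: str | os.PathLike,
                 concentrations_path: str | os.PathLike) -> SpectralDataset:
    """Read a paired spectra/concentration CSV set into a :class:`SpectralDataset`.

    Sample order follows the spectra file; concentration rows are aligned by
    sample ID.  Wavelengths are parsed from the spectra header.
    """
    spec_df = pd.read_csv(spectra_path, header=0, dtype={0: str})
    conc_df = pd.read_csv(concentrations_path, header=0, dtype={0: str})
    if spec_df.shape[1] < 4:
        raise DatasetFormatError(
            f"{spectra_path}: expected sample-ID, group and >=2 wavelength columns"
        )
    if conc_df.shape[1] < 2:
        raise DatasetFormatError(
            f"{concentrations_path}: expected sample-ID and >=1 component column"
        )
    try:
        wavelengths = np.array([float(c) for c in spec_df.columns[2:]])
    except ValueError as exc:
        raise DatasetFormatError(
            f"{spectra_path}: non-numeric wavelength header: {exc}"
        ) from exc
    if not np.all(np.diff(wavelengths) > 0):
        raise DatasetFormatError(
            f"{spectra_path}: wavelength headers must be strictly increasing"
        )

    spec_ids = spec_df.iloc[:, 0].astype(str).to_numpy()
    conc_ids = conc_df.iloc[:, 0].astype(str).to_numpy()
    if sorted(spec_ids) != sorted(conc_ids):
        missing = set(spec_ids) ^ set(conc_ids)
        raise DatasetFormatError(
            "sample IDs differ between spectra and concentration files; "
            f"unmatched: {sorted(missing)[:5]}"
        )
    conc_df = conc_df.set_index(conc_df.columns[0]).loc[spec_ids]

    try:
        X = spec_df.iloc[:, 2:].to_numpy(dtype=float)
        Y = conc_df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DatasetFormatError(f"non-numeric data cell: {exc}") from exc

    return SpectralDataset(
        X=X,
        Y=Y,
        wavelengths=wavelengths,
        component_names=[str(c) for c in conc_df.columns],
        groups=spec_df.iloc[:, 1].to_numpy(),
        sample_ids=spec_ids,
    )


def write_dataset(ds: SpectralDataset, out_dir: str | os.PathLike,
                  prefix: str = "dataset") -> tuple[str, str]:
    """Write the two-CSV dialect accepted by :func:`read_dataset`.

    Returns the (spectra_path, concentrations_path) pair.
    """
    os.makedirs(out_dir, exist_ok=True)
    spectra_path = os.path.join(out_dir, f"{prefix}_spectra.csv")
    conc_path = os.path.join(out_dir, f"{prefix}_concentrations.csv")

    spec_df = pd.DataFrame(ds.X, columns=[repr(float(w))
                                          for w in ds.wavelengths])
    spec_df.insert(0, "group", ds.groups)
    spec_df.insert(0, "sample_id", ds.sample_ids)
    conc_df = pd.DataFrame(ds.Y, columns=ds.component_names)
    conc_df.insert(0, "sample_id", ds.sample_ids)
    try:
        # repr() of float keeps full precision so the round trip is lossless
        spec_df.to_csv(spectra_path, index=False, float_format="%.17g",
                       encoding="utf-8")
        conc_df.to_csv(conc_path, index=False, float_format="%.17g",
                       encoding="utf-8")
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out_dir}: {exc}") from exc
    return spectra_path, conc_path
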