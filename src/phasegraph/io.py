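"""Imaging input/output: ROI extraction from volumes and delimited-text persistence.

Regional BOLD time series are represented as an ``n_regions x n_timepoints``
matrix with an explicit sampling interval (TR).  Regions are identified by the
integer labels of the parcellation atlas they were extracted from, ordered by
ascending label; label 0 is background, negative labels are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PET_TRACERS = ("rCPS", "SUV")


class DimensionError(ValueError):
    """Shapes or grids of two inputs do not match."""


class MissingRegionError(ValueError):
    """A requested atlas label has no voxels."""


@dataclass
class RoiTimeSeries:
    """Region-by-time matrix of spatially averaged BOLD samples.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_timepoints)
        Mean BOLD signal per region per volume, arbitrary units.
    region_ids : sequence of int
        Atlas labels in row order (ascending, unique, positive).
    tr_seconds : float
        Sampling interval between volumes in seconds.
    """

    values: np.ndarray
    region_ids: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.ndim != 2:
            raise DimensionError("values must be 2-D (regions x time)")
        n_regions, n_timepoints = self.values.shape
        if n_regions < 2:
            raise ValueError("need at least 2 regions")
        if n_timepoints < 64:
            raise ValueError("need at least 64 timepoints")
        if len(self.region_ids) != n_regions:
            raise DimensionError("region_ids length must match number of rows")
        if len(np.unique(self.region_ids)) != n_regions:
            raise ValueError("region_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in time series")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_rate(self) -> float:
        """Nominal sampling rate 1/TR in Hz."""
        return 1.0 / self.tr_seconds


@dataclass
class RegionalPetVector:
    """One PET-derived value per region, aligned with a :class:`RoiTimeSeries`.

    ``tracer`` is ``"rCPS"`` (regional cerebral protein synthesis, nmol/g/min)
    or ``"SUV"`` (standardized uptake value, dimensionless).
    """

    values: np.ndarray
    tracer: str
    region_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.tracer not in PET_TRACERS:
            raise ValueError(f"tracer must be one of {PET_TRACERS}")
        if self.region_ids is None:
            self.region_ids = np.arange(1, len(self.values) + 1)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if len(self.region_ids) != len(self.values):
            raise DimensionError("region_ids length must match values")
        if np.any(self.values <= 0):
            logger.warning(
                "%d non-positive regional means in %s vector retained",
                int(np.sum(self.values <= 0)), self.tracer,
            )


def _check_labels(atlas: np.ndarray) -> np.ndarray:
    atlas = np.asarray(atlas)
    if not np.issubdtype(atlas.dtype, np.integer):
        rounded = np.round(atlas)
        if not np.allclose(atlas, rounded):
            raise ValueError("atlas must contain integer labels")
        atlas = rounded.astype(int)
    if atlas.min() < 0:
        raise ValueError("negative atlas labels are not allowed")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    if len(labels) < 2:
        raise ValueError("atlas must contain at least 2 nonzero labels")
    return atlas


def extract_roi_timeseries(
    bold: np.ndarray,
    atlas: np.ndarray,
    tr_seconds: float,
    region_ids: Sequence[int] | None = None,
) -> RoiTimeSeries:
    """Spatially average a 4-D BOLD volume within each atlas region.

    Row ``r`` at time ``t`` is the unweighted arithmetic mean of the voxels of
    ``bold[..., t]`` whose atlas label equals ``region_ids[r]``.  Rows are
    ordered by ascending label; background (label 0) is excluded.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise DimensionError("bold must be 4-D (x, y, z, t)")
    if np.shape(atlas) != bold.shape[:3]:
        raise DimensionError(
            f"atlas grid {np.shape(atlas)} does not match bold grid "
            f"{bold.shape[:3]}"
        )
    atlas = _check_labels(atlas)
    if region_ids is None:
        labels = np.unique(atlas)
        labels = np.sort(labels[labels > 0])
    else:
        labels = np.sort(np.asarray(region_ids, dtype=int))
    flat_atlas = atlas.ravel()
    flat_bold = bold.reshape(-1, bold.shape[3])
    rows = np.empty((len(labels), bold.shape[3]))
    for r, lab in enumerate(labels):
        mask = flat_atlas == lab
        if not mask.any():
            raise MissingRegionError(f"atlas label {lab} has no voxels")
        rows[r] = flat_bold[mask].mean(axis=0)
    return RoiTimeSeries(values=rows, region_ids=labels, tr_seconds=tr_seconds)


def average_pet_by_region(
    pet: np.ndarray,
    atlas: np.ndarray,
    tracer: str,
    region_ids: Sequence[int] | None = None,
) -> RegionalPetVector:
    """Mean PET value per atlas region, same ordering rule as the BOLD extraction."""
    pet = np.asarray(pet, dtype=float)
    if pet.ndim != 3:
        raise DimensionError("pet must be 3-D")
    if np.shape(atlas) != pet.shape:
        raise DimensionError(
            f"atlas grid {np.shape(atlas)} does not match pet grid {pet.shape}"
        )
    atlas = _check_labels(atlas)
    if region_ids is None:
        labels = np.unique(atlas)
        labels = np.sort(labels[labels > 0])
    else:
        labels = np.sort(np.asarray(region_ids, dtype=int))
    out = np.empty(len(labels))
    for r, lab in enumerate(labels):
        mask = atlas == lab
        if not mask.any():
            raise MissingRegionError(f"atlas label {lab} has no voxels")
        out[r] = pet[mask].mean()
    return RegionalPetVector(values=out, tracer=tracer, region_ids=labels)


# ---------------------------------------------------------------------------
# NIfTI and delimited-text persistence


def load_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj)


def nifti_tr(path: str | Path) -> float | None:
    """TR recorded in a NIfTI header (zooms[3]), or None if absent/zero."""
    import nibabel as nib

    zooms = nib.load(str(path)).header.get_zooms()
    if len(zooms) > 3 and zooms[3] > 0:
        return float(zooms[3])
    return None


def write_matrix_tsv(path: str | Path, matrix: np.ndarray,
                     region_ids: Sequence[int]) -> None:
    """Square or rectangular matrix as TSV with a region-label header row."""
    df = pd.DataFrame(np.asarray(matrix), columns=None)
    df.columns = [str(c) for c in range(df.shape[1])] \
        if len(region_ids) != df.shape[1] else [str(r) for r in region_ids]
    df.insert(0, "region", list(region_ids)[: df.shape[0]]
              if len(region_ids) >= df.shape[0] else range(df.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_matrix_tsv`: returns (matrix, region_ids)."""
    df = pd.read_csv(path, sep="\t")
    region_ids = df["region"].to_numpy(dtype=int)
    return df.drop(columns="region").to_numpy(dtype=float), region_ids


def read_timeseries_tsv(path: str | Path, tr_seconds: float) -> RoiTimeSeries:
    values, region_ids = read_matrix_tsv(path)
    return RoiTimeSeries(values=values, region_ids=region_ids,
                         tr_seconds=tr_seconds)


def read_pet_tsv(path: str | Path, tracer: str) -> RegionalPetVector:
    df = pd.read_csv(path, sep="\t")
    return RegionalPetVector(values=df["value"].to_numpy(dtype=float),
                             tracer=tracer,
                             region_ids=df["region"].to_numpy(dtype=int))


def write_pet_tsv(path: str | Path, pet: RegionalPetVector) -> None:
    pd.DataFrame({"region": pet.region_ids, "value": pet.values}).to_csv(
        path, sep="\t", index=False)
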