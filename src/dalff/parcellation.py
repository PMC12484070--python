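"""Labeled brain parcellation with region table and centroids.

Holds an integer label volume (0 = background) plus a per-region table
carrying hemisphere flags, world-mm centroids and unit-sphere coordinates
(the latter drive spin-permutation nulls).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["Parcellation"]

REGION_COLUMNS = ["label", "hemisphere", "cx_mm", "cy_mm", "cz_mm", "sx", "sy", "sz"]


@dataclass
class Parcellation:
    """Integer-labeled volume plus a region table.

    ``regions`` is indexed by label (contiguous 1..n) with columns
    ``hemisphere`` ('L'/'R'), ``cx_mm``/``cy_mm``/``cz_mm`` (world-mm
    centroid) and ``sx``/``sy``/``sz`` (centroid projected on the unit
    sphere, used to build spin nulls).
    """

    labels: np.ndarray
    affine: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        self.affine = np.asarray(self.affine, dtype=float)
        present = np.unique(self.labels)
        present = present[present > 0]
        missing = set(present) - set(self.regions.index)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from region table")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_labels(self) -> np.ndarray:
        return self.regions.index.to_numpy()

    def hemisphere_labels(self, hemisphere: str) -> np.ndarray:
        return self.regions.index[self.regions["hemisphere"] == hemisphere].to_numpy()

    @property
    def centroids_mm(self) -> np.ndarray:
        return self.regions[["cx_mm", "cy_mm", "cz_mm"]].to_numpy()

    @property
    def sphere_coords(self) -> np.ndarray:
        return self.regions[["sx", "sy", "sz"]].to_numpy()

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def save(self, nifti_path: str | Path, table_path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, str(nifti_path))
        out = self.regions.reset_index(names="label")
        out.to_csv(str(table_path), sep="\t", index=False)

    @classmethod
    def load(cls, nifti_path: str | Path, table_path: str | Path) -> "Parcellation":
        img = nib.load(str(nifti_path))
        table = pd.read_csv(str(table_path), sep="\t").set_index("label")
        return cls(
            labels=np.asarray(img.get_fdata(), dtype=int),
            affine=img.affine,
            regions=table,
        )
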