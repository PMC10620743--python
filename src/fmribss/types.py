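"""Shared in-memory containers for multi-subject fMRI datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HC = "HC"
ASD = "ASD"
GROUPS = (HC, ASD)


@dataclass
class SubjectScan:
    """One subject's masked voxel-by-time data matrix plus metadata.

    ``data`` is V x T (in-mask voxels x timepoints). All subjects in a
    dataset share a common mask, hence a common V and voxel ordering
    (row-major over the mask grid).
    """

    subject_id: str
    group: str
    data: np.ndarray  # V x T
    tr_seconds: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be V x T with T >= 2")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in data")


@dataclass
class GroupDataset:
    """A cohort of subjects sharing one mask and acquisition grid."""

    subjects: list  # list[SubjectScan]
    mask: np.ndarray  # 3D boolean grid
    tr_seconds: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        n_voxels = int(self.mask.sum())
        for s in self.subjects:
            if s.data.shape[0] != n_voxels:
                raise ValueError(
                    f"subject {s.subject_id}: {s.data.shape[0]} voxels, "
                    f"mask has {n_voxels}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def grid_shape(self) -> tuple:
        return self.mask.shape

    def by_group(self, group: str) -> list:
        return [s for s in self.subjects if s.group == group]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])
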