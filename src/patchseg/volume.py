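"""Core image containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical sequence names, in storage order.
SEQUENCES = ("t2w", "dwi_b0", "dwi_high_b")

#: Channel order used when patches are assembled (channel 1 = t2w,
#: channel 2 = dwi_high_b, channel 3 = dwi_b0).  Fixed for reproducibility.
CHANNEL_ORDER = ("t2w", "dwi_high_b", "dwi_b0")


@dataclass
class MpVolume:
    """One subject's aligned multiparametric 3D image (three sequences).

    Arrays are indexed ``(x, y, z)`` where the first two axes span the
    axial (in-plane) dimensions and the last axis indexes slices.
    ``spacing`` is the physical voxel size in mm per axis.
    """

    t2w: np.ndarray
    dwi_b0: np.ndarray
    dwi_high_b: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = "subject"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.t2w.shape, self.dwi_b0.shape, self.dwi_high_b.shape}
        if len(shapes) != 1:
            raise ValueError(f"sequence shapes differ: {shapes}")
        if len(self.t2w.shape) != 3:
            raise ValueError("sequences must be 3D arrays")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2w.shape

    def sequences(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in SEQUENCES}

    def channel_stack(self) -> np.ndarray:
        """Stack the sequences into a ``(nx, ny, nz, 3)`` array.

        Channel order follows :data:`CHANNEL_ORDER`.
        """
        return np.stack([getattr(self, n) for n in CHANNEL_ORDER], axis=-1)

    def map_sequences(self, fn) -> "MpVolume":
        """Return a copy with ``fn`` applied to each sequence array."""
        return MpVolume(
            t2w=fn(self.t2w),
            dwi_b0=fn(self.dwi_b0),
            dwi_high_b=fn(self.dwi_high_b),
            spacing=self.spacing,
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )


@dataclass
class LabelMap:
    """Binary tumour label map aligned to an :class:`MpVolume`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        values = np.unique(mask)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("label map must be binary (values in {0, 1})")
        self.mask = mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
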