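"""Voxelwise probability maps and segmentation post-processing.

The probability map assigns to every voxel the tumour-class softmax output
of the classifier applied to the in-plane patch centred on that voxel.
Segmentation keeps the largest connected component of the suprathreshold
set (p >= 0.5 by default), which deliberately reproduces the documented
failure mode: when a hyperintense distractor larger than the tumour
survives the threshold, the tumour is discarded and the Dice score drops
to zero even though the voxelwise ranking (AUC) stays high.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .model.network import ConvNet
from .volume import CHANNEL_ORDER, MpVolume


@dataclass
class ProbabilityMap:
    """Voxelwise tumour probability aligned to the source volume."""

    p: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.p = p

    @property
    def shape(self):
        return self.p.shape


@dataclass
class SegMask:
    """Binary segmentation after thresholding and component selection."""

    mask: np.ndarray
    component_count_before_selection: int
    selected_component_size: int

    @property
    def shape(self):
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def predict_volume(
    model: ConvNet,
    volume: MpVolume,
    M: int | None = None,
    batch: int = 256,
) -> ProbabilityMap:
    """Classify the patch centred on every voxel of a standardized volume.

    Border voxels use the same zero-padding rule as patch sampling.  The
    result is independent of ``batch`` (dropout is off at inference).
    """
    M = model.patch_edge if M is None else int(M)
    if M != model.patch_edge:
        raise ValueError(f"model expects patch edge {model.patch_edge}, got M={M}")
    nx, ny, nz = volume.shape
    r = M // 2
    stack = np.stack(
        [np.asarray(getattr(volume, n), dtype=np.float32) for n in CHANNEL_ORDER], axis=-1
    )
    padded = np.pad(stack, ((r, r), (r, r), (0, 0), (0, 0)))
    out = np.empty((nx, ny, nz), dtype=np.float64)
    for k in range(nz):
        sl = padded[:, :, k, :]  # (nx + 2r, ny + 2r, 3)
        win = sliding_window_view(sl, (M, M), axis=(0, 1))  # (nx, ny, 3, M, M)
        tiles = np.ascontiguousarray(win.transpose(0, 1, 3, 4, 2)).reshape(
            nx * ny, M, M, 3
        )
        probs = model.predict_proba(tiles, batch=batch)
        out[:, :, k] = probs[:, 1].reshape(nx, ny)
    return ProbabilityMap(p=out, spacing=volume.spacing)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def threshold_and_select(
    p: ProbabilityMap | np.ndarray, t: float = 0.5, connectivity: int = 26
) -> SegMask:
    """Threshold at ``t`` (inclusive) and keep the largest connected component.

    Size ties are broken deterministically in favour of the component whose
    minimum voxel index is lexicographically smallest.
    """
    arr = p.p if isinstance(p, ProbabilityMap) else np.asarray(p, dtype=float)
    if not 0 <= t <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    binary = arr >= t
    structure = _connectivity_structure(connectivity)
    labels, n_comp = ndimage.label(binary, structure=structure)
    if n_comp == 0:
        return SegMask(
            mask=np.zeros(arr.shape, dtype=np.uint8),
            component_count_before_selection=0,
            selected_component_size=0,
        )
    sizes = np.bincount(labels.ravel())[1:]
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        winner = min(candidates, key=lambda l: int(np.argmax(flat == l)))
    return SegMask(
        mask=(labels == winner).astype(np.uint8),
        component_count_before_selection=int(n_comp),
        selected_component_size=int(best_size),
    )
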