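"""Region-stratified patch sampling.

Each labelled volume is partitioned into four strata: the tumour T, a
shell B1 within 10 mm (physical distance, anisotropy-aware) of the tumour,
the remaining diffusion-hyperintense voxels B2 (standardized high-b DWI
above 2.0, i.e. mu + 2*sigma), and everything else B3.  Class-balanced
training patches are drawn with per-stratum quotas N/4 : N/2 : N/4 for
B1 : B2 : B3 and N from the tumour.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LabelMap, MpVolume

# stratum codes
T, B1, B2, B3 = 0, 1, 2, 3
STRATUM_NAMES = {T: "T", B1: "B1", B2: "B2", B3: "B3"}

DEFAULT_RADIUS_MM = 10.0
DEFAULT_THRESHOLD = 2.0


def physical_ball(spacing, radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """Structuring element: voxel offsets within ``radius_mm`` physical mm.

    Half-width along axis i is floor(radius / spacing_i), so for spacing
    (2, 2, 5) mm and a 10 mm radius the element spans (5, 5, 2) voxels on
    either side of the centre.
    """
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    offs = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    d2 = (
        offs[0][:, None, None] ** 2
        + offs[1][None, :, None] ** 2
        + offs[2][None, None, :] ** 2
    )
    return d2 <= radius_mm**2 + 1e-9


@dataclass
class RegionDecomposition:
    """Per-voxel stratum labels partitioning a volume into T, B1, B2, B3."""

    stratum: np.ndarray  # uint8 codes
    spacing: tuple[float, float, float]
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {
                code: int((self.stratum == code).sum()) for code in (T, B1, B2, B3)
            }

    def voxels_in(self, code: int) -> np.ndarray:
        """Flat indices (C order) of voxels in the given stratum."""
        return np.flatnonzero(self.stratum.ravel() == code)


def decompose(
    dwi_high_b: np.ndarray,
    mask: LabelMap | np.ndarray,
    spacing,
    radius_mm: float = DEFAULT_RADIUS_MM,
    threshold: float = DEFAULT_THRESHOLD,
) -> RegionDecomposition:
    """Partition a standardized high-b DWI volume into the four strata."""
    mask_arr = mask.mask if isinstance(mask, LabelMap) else np.asarray(mask)
    tumour = mask_arr.astype(bool)
    if not tumour.any():
        raise ValueError("empty tumour mask: nothing to learn from this volume")
    vol = np.asarray(dwi_high_b)
    if vol.shape != tumour.shape:
        raise ValueError("volume and mask shapes differ")

    ball = physical_ball(spacing, radius_mm)
    dilated = ndimage.binary_dilation(tumour, structure=ball)
    b1 = dilated & ~tumour
    b2 = (vol > threshold) & ~dilated
    b3 = ~(tumour | b1 | b2)

    stratum = np.full(vol.shape, B3, dtype=np.uint8)
    stratum[b2] = B2
    stratum[b1] = B1
    stratum[tumour] = T
    return RegionDecomposition(stratum=stratum, spacing=tuple(spacing))


@dataclass
class PatchSet:
    """Labelled M x M x 3 patches with coordinates and stratum provenance."""

    patches: np.ndarray  # (n, M, M, 3) float32
    labels: np.ndarray  # (n,) uint8, 1 = tumour
    coords: np.ndarray  # (n, 3) int
    strata: np.ndarray  # (n,) uint8 stratum codes
    subject_ids: np.ndarray | None = None  # (n,) str

    def __post_init__(self) -> None:
        n = len(self.patches)
        if not (len(self.labels) == len(self.coords) == len(self.strata) == n):
            raise ValueError("inconsistent PatchSet field lengths")
        if self.subject_ids is None:
            self.subject_ids = np.array(["?"] * n)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def M(self) -> int:
        return self.patches.shape[1]

    def subset(self, idx) -> "PatchSet":
        return PatchSet(
            patches=self.patches[idx],
            labels=self.labels[idx],
            coords=self.coords[idx],
            strata=self.strata[idx],
            subject_ids=self.subject_ids[idx],
        )

    @classmethod
    def concatenate(cls, sets: list["PatchSet"]) -> "PatchSet":
        return cls(
            patches=np.concatenate([s.patches for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            coords=np.concatenate([s.coords for s in sets]),
            strata=np.concatenate([s.strata for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
        )

    def save(self, path) -> None:
        """Write the patch array container plus a sidecar table."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), patches=self.patches)
        pd.DataFrame(
            {
                "label": self.labels,
                "i": self.coords[:, 0],
                "j": self.coords[:, 1],
                "k": self.coords[:, 2],
                "stratum": [STRATUM_NAMES[s] for s in self.strata],
                "subject_id": self.subject_ids,
            }
        ).to_csv(path.with_suffix(".csv"), index=False)

    @classmethod
    def load(cls, path) -> "PatchSet":
        path = Path(path)
        patches = np.load(path.with_suffix(".npz"))["patches"]
        table = pd.read_csv(path.with_suffix(".csv"))
        inv = {v: k for k, v in STRATUM_NAMES.items()}
        return cls(
            patches=patches,
            labels=table["label"].to_numpy(np.uint8),
            coords=table[["i", "j", "k"]].to_numpy(int),
            strata=np.array([inv[s] for s in table["stratum"]], dtype=np.uint8),
            subject_ids=table["subject_id"].to_numpy(str),
        )


def _padded_stack(volume: MpVolume, M: int) -> np.ndarray:
    r = M // 2
    stack = volume.channel_stack()
    # zero padding = background mean after standardization
    return np.pad(stack, ((r, r), (r, r), (0, 0), (0, 0)))


def extract_patch(volume: MpVolume, voxel, M: int) -> np.ndarray:
    """Axial in-plane M x M neighbourhood centred on ``voxel``, 3 channels.

    Out-of-bounds positions are zero-padded (zero being the background mean
    on the standardized scale).
    """
    if M % 2 == 0:
        raise ValueError("patch edge M must be odd")
    i, j, k = (int(v) for v in voxel)
    nx, ny, nz = volume.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise ValueError(f"voxel {voxel} outside volume of shape {volume.shape}")
    padded = _padded_stack(volume, M)
    return np.ascontiguousarray(padded[i : i + M, j : j + M, k, :], dtype=np.float32)


def _extract_many(volume: MpVolume, coords: np.ndarray, M: int) -> np.ndarray:
    padded = _padded_stack(volume, M).astype(np.float32)
    out = np.empty((len(coords), M, M, 3), dtype=np.float32)
    for n, (i, j, k) in enumerate(coords):
        out[n] = padded[i : i + M, j : j + M, k, :]
    return out


def _background_quotas(N: int, counts: dict) -> dict:
    """Per-stratum background quotas N/4 : N/2 : N/4, with the quota of any
    empty stratum reallocated proportionally to the non-empty ones."""
    weights = {B1: 1, B2: 2, B3: 1}
    active = [s for s in (B1, B2, B3) if counts[s] > 0]
    if not active:
        raise ValueError("background is empty: cannot sample non-tumour patches")
    wsum = sum(weights[s] for s in active)
    raw = {s: N * weights[s] / wsum for s in active}
    quotas = {s: int(np.floor(raw[s])) for s in active}
    # largest-remainder rounding so quotas sum exactly to N
    remainder = N - sum(quotas.values())
    for s in sorted(active, key=lambda s: raw[s] - quotas[s], reverse=True)[:remainder]:
        quotas[s] += 1
    for s in (B1, B2, B3):
        quotas.setdefault(s, 0)
    return quotas


def sample_patches(
    volume: MpVolume,
    regions: RegionDecomposition,
    N: int = 5000,
    M: int = 21,
    seed: int = 0,
) -> PatchSet:
    """Draw N tumour and N background patches per the stratum quotas.

    Sampling is without replacement when a stratum holds at least its quota
    of voxels, with replacement otherwise.  Deterministic given ``seed``.
    """
    if N % 4 != 0:
        raise ValueError("N must be divisible by 4")
    if M % 2 == 0:
        raise ValueError("patch edge M must be odd")
    if volume.shape != regions.stratum.shape:
        raise ValueError("volume and region decomposition shapes differ")

    rng = np.random.default_rng(seed)
    shape = volume.shape
    quotas = {T: N, **_background_quotas(N, regions.counts)}

    coords_list, strata_list = [], []
    for code in (T, B1, B2, B3):
        quota = quotas[code]
        if quota == 0:
            continue
        pool = regions.voxels_in(code)
        if len(pool) == 0:
            raise ValueError(f"stratum {STRATUM_NAMES[code]} empty with quota {quota}")
        replace = len(pool) < quota
        chosen = rng.choice(pool, size=quota, replace=replace)
        coords_list.append(np.column_stack(np.unravel_index(chosen, shape)))
        strata_list.append(np.full(quota, code, dtype=np.uint8))

    coords = np.concatenate(coords_list)
    strata = np.concatenate(strata_list)
    labels = (strata == T).astype(np.uint8)
    patches = _extract_many(volume, coords, M)
    subject_ids = np.array([volume.subject_id] * len(coords))
    return PatchSet(
        patches=patches, labels=labels, coords=coords, strata=strata, subject_ids=subject_ids
    )
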