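"""Synthetic multiparametric MR phantoms with ground-truth tumour masks.

Volumes are generated directly near the standardized intensity scale:
background voxels are drawn from N(0, noise_sd^2) and lesions are additive
offsets per sequence, so that a tumour offset of ~3 on the high-b diffusion
channel lands well above the mu + 2*sigma hyperintensity cutoff after
standardization.  Tumour and distractor shapes are spheres (optionally
perturbed by seeded smooth radial noise), which keeps an analytic volume
oracle available for testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import LabelMap, MpVolume

ARTEFACT_MODES = ("none", "fat_suppression_band", "ghosting")

#: Per-sequence additive offsets, ordered (t2w, dwi_b0, dwi_high_b).
Offsets = tuple[float, float, float]


@dataclass(frozen=True)
class Distractor:
    """A non-tumour structure that is hyperintense on high-b DWI."""

    centre: tuple[float, float, float]  # mm
    radius: float  # mm
    offsets: Offsets = (-0.8, 0.5, 3.0)


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    tumour_radius: float = 10.0  # mm
    tumour_centre: tuple[float, float, float] | None = None  # mm; None = grid centre
    tumour_offsets: Offsets = (1.2, 0.4, 3.2)
    distractors: tuple[Distractor, ...] = ()
    noise_sd: float = 1.0
    artefact_mode: str = "none"
    misalignment: float = 0.0  # mm, smooth displacement applied to the t2w channel
    radial_noise: float = 0.0  # mm, amplitude of smooth radial shape perturbation
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must have all axes >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.tumour_radius < 0:
            raise ValueError("tumour_radius must be >= 0")
        if self.artefact_mode not in ARTEFACT_MODES:
            raise ValueError(
                f"artefact_mode must be one of {ARTEFACT_MODES}, got {self.artefact_mode!r}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def physical_extent(self) -> tuple[float, float, float]:
        """Physical coordinate of the last voxel centre along each axis (mm)."""
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))

    def resolved_tumour_centre(self) -> tuple[float, float, float]:
        if self.tumour_centre is not None:
            return tuple(float(c) for c in self.tumour_centre)
        return tuple(e / 2.0 for e in self.physical_extent())


def _axis_coords(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def sphere_mask(
    shape,
    spacing,
    centre,
    radius,
    rng: np.random.Generator | None = None,
    radial_noise: float = 0.0,
) -> np.ndarray:
    """Voxels whose centre lies inside the (optionally perturbed) sphere."""
    if radius <= 0:
        return np.zeros(shape, dtype=bool)
    xs, ys, zs = _axis_coords(shape, spacing)
    d2 = (
        (xs - centre[0])[:, None, None] ** 2
        + (ys - centre[1])[None, :, None] ** 2
        + (zs - centre[2])[None, None, :] ** 2
    )
    r = np.full(shape, float(radius))
    if radial_noise > 0:
        if rng is None:
            raise ValueError("radial_noise requires an rng")
        coarse = rng.standard_normal((4, 4, 4))
        factors = [n / 4 for n in shape]
        bump = ndimage.zoom(coarse, factors, order=3, mode="nearest", grid_mode=True)
        peak = np.abs(bump).max()
        if peak > 0:
            r = r + radial_noise * bump / peak
    return d2 <= r**2


def _smooth_displacement(shape, amplitude_mm, spacing, rng) -> np.ndarray:
    """Seeded smooth random displacement field, in voxel units, shape (3, *shape)."""
    field3 = np.empty((3,) + tuple(shape))
    for axis in range(3):
        coarse = rng.standard_normal((3, 3, 3))
        factors = [n / 3 for n in shape]
        f = ndimage.zoom(coarse, factors, order=3, mode="nearest", grid_mode=True)
        peak = np.abs(f).max()
        if peak > 0:
            f = f / peak
        field3[axis] = f * (amplitude_mm / spacing[axis])
    return field3


def _warp(arr: np.ndarray, disp_voxels: np.ndarray) -> np.ndarray:
    idx = np.indices(arr.shape, dtype=float)
    return ndimage.map_coordinates(arr, idx + disp_voxels, order=1, mode="nearest")


def generate_phantom(config: PhantomConfig) -> tuple[MpVolume, LabelMap]:
    """Generate one multiparametric phantom and its ground-truth tumour mask.

    Deterministic: identical ``config`` (including ``seed``) yields
    bit-identical arrays.  ``MpVolume.meta`` records the true distractor
    masks so tests can use them as oracles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = tuple(float(s) for s in config.spacing)

    centre = config.resolved_tumour_centre()
    extent = config.physical_extent()
    if config.tumour_radius > 0:
        for c, e in zip(centre, extent):
            if c - config.tumour_radius < 0 or c + config.tumour_radius > e:
                raise ValueError(
                    f"tumour (centre {centre} mm, radius {config.tumour_radius} mm) "
                    f"extends outside the grid (extent {extent} mm)"
                )

    tumour = sphere_mask(
        shape, spacing, centre, config.tumour_radius, rng=rng, radial_noise=config.radial_noise
    )
    distractor_masks = []
    for d in config.distractors:
        dmask = sphere_mask(
            shape, spacing, d.centre, d.radius, rng=rng, radial_noise=config.radial_noise
        )
        if (dmask & tumour).any():
            raise ValueError(f"distractor at {d.centre} mm overlaps the tumour")
        distractor_masks.append(dmask)

    seqs = {}
    # t2w, dwi_b0, dwi_high_b -- offsets tuples are ordered the same way
    for i, name in enumerate(("t2w", "dwi_b0", "dwi_high_b")):
        arr = rng.standard_normal(shape) * config.noise_sd
        arr[tumour] += config.tumour_offsets[i]
        for d, dmask in zip(config.distractors, distractor_masks):
            arr[dmask] += d.offsets[i]
        seqs[name] = arr

    if config.artefact_mode == "fat_suppression_band":
        # failed fat suppression: bright in-plane band on the diffusion images
        width = max(2, shape[1] // 8)
        y0 = 1 + int(rng.integers(0, max(1, shape[1] // 4)))
        seqs["dwi_high_b"][:, y0 : y0 + width, :] += 3.0
        seqs["dwi_b0"][:, y0 : y0 + width, :] += 1.5
    elif config.artefact_mode == "ghosting":
        shift = shape[1] // 3
        signal = np.zeros(shape)
        signal[tumour] += config.tumour_offsets[2]
        for d, dmask in zip(config.distractors, distractor_masks):
            signal[dmask] += d.offsets[2]
        seqs["dwi_high_b"] += 0.5 * np.roll(signal, shift, axis=1)

    if config.misalignment > 0:
        disp = _smooth_displacement(shape, config.misalignment, spacing, rng)
        seqs["t2w"] = _warp(seqs["t2w"], disp)

    vol = MpVolume(
        t2w=seqs["t2w"],
        dwi_b0=seqs["dwi_b0"],
        dwi_high_b=seqs["dwi_high_b"],
        spacing=spacing,
        subject_id="phantom",
        meta={
            "tumour_mask": tumour,
            "distractor_masks": distractor_masks,
            "tumour_centre_mm": centre,
            "tumour_radius_mm": config.tumour_radius,
        },
    )
    return vol, LabelMap(mask=tumour.astype(np.uint8))


def generate_cohort(
    n_subjects: int, base_config: PhantomConfig, seed: int
) -> list[tuple[MpVolume, LabelMap]]:
    """Generate ``n_subjects`` phantoms with seeded per-subject jitter.

    Tumour size, position and intensity (and likewise for distractors) are
    jittered per subject from a single seeded stream; subject ids are unique
    and carry a numeric index usable by parity split rules.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_config.validate()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        jrng = np.random.default_rng(child)
        centre = np.array(base_config.resolved_tumour_centre())
        centre = centre + jrng.uniform(-4.0, 4.0, size=3)
        radius = base_config.tumour_radius * (1.0 + jrng.uniform(-0.2, 0.2))
        offsets = tuple(
            o * (1.0 + jrng.uniform(-0.1, 0.1)) for o in base_config.tumour_offsets
        )
        distractors = []
        for d in base_config.distractors:
            dc = np.array(d.centre) + jrng.uniform(-4.0, 4.0, size=3)
            dr = d.radius * (1.0 + jrng.uniform(-0.15, 0.15))
            distractors.append(replace(d, centre=tuple(dc), radius=dr))
        cfg = replace(
            base_config,
            tumour_centre=tuple(centre),
            tumour_radius=radius,
            tumour_offsets=offsets,
            distractors=tuple(distractors),
            seed=int(child.generate_state(1)[0]),
        )
        vol, label = generate_phantom(cfg)
        vol.subject_id = f"sub-{i:03d}"
        cohort.append((vol, label))
    return cohort
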