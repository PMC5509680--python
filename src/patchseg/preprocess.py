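"""Intensity standardization and a simplified deformable registration stage.

Standardization rescales each sequence to zero mean and unit standard
deviation (population SD over all voxels), so the hyperintensity cutoff
``mu + 2*sigma`` evaluates to exactly 2.0 on standardized volumes.

Registration aligns a moving sequence to the DWI-b0 reference with a
two-stage scheme: a multi-resolution global translation search followed by
an optional coarse B-spline free-form refinement, both driven by
histogram-based mutual information with a bending-energy penalty on the
displacement field.  The candidate field is kept only if it improves mutual
information over the identity, so registration never degrades alignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volume import MpVolume, SEQUENCES


# ---------------------------------------------------------------------------
# standardization

def standardize(volume: np.ndarray) -> np.ndarray:
    """Affinely rescale to mean 0, SD 1 (population SD over all voxels)."""
    arr = np.asarray(volume, dtype=float)
    sd = arr.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant volume (SD = 0)")
    return (arr - arr.mean()) / sd


@dataclass
class StandardizedVolume(MpVolume):
    """MpVolume whose sequences have been standardized; records the original
    per-sequence mean/SD as provenance."""

    stats: dict = field(default_factory=dict)


def standardize_volume(volume: MpVolume) -> StandardizedVolume:
    """Standardize each sequence independently (per-sequence, per-subject)."""
    stats = {}
    out = {}
    for name in SEQUENCES:
        arr = np.asarray(getattr(volume, name), dtype=float)
        stats[name] = {"mean": float(arr.mean()), "sd": float(arr.std())}
        out[name] = standardize(arr)
    return StandardizedVolume(
        t2w=out["t2w"],
        dwi_b0=out["dwi_b0"],
        dwi_high_b=out["dwi_high_b"],
        spacing=volume.spacing,
        subject_id=volume.subject_id,
        meta=dict(volume.meta),
        stats=stats,
    )


# ---------------------------------------------------------------------------
# registration

@dataclass(frozen=True)
class RegistrationConfig:
    grid_spacing: float = 4.0  # mm, B-spline control grid spacing
    penalty_weight: float = 20.0  # bending-energy : similarity ratio
    metric: str = "mi"
    n_resolutions: int = 2
    max_iterations: int = 20
    seed: int = 0
    bins: int = 32
    max_control_points: int = 4  # per-axis cap keeping the optimisation tractable
    refine: bool = True

    def validate(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Histogram-based mutual information between two images (nats)."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def bending_energy(disp: np.ndarray) -> float:
    """Mean squared second difference of a displacement field (3, nx, ny, nz)."""
    total = 0.0
    for comp in disp:
        for axis in range(3):
            if comp.shape[axis] >= 3:
                d2 = np.diff(comp, n=2, axis=axis)
                total += float((d2**2).sum())
    return total / disp[0].size


def _warp(arr: np.ndarray, disp: np.ndarray) -> np.ndarray:
    idx = np.indices(arr.shape, dtype=float)
    return ndimage.map_coordinates(arr, idx + disp, order=1, mode="nearest")


def _translate(arr: np.ndarray, t: np.ndarray) -> np.ndarray:
    return ndimage.shift(arr, -t, order=1, mode="nearest")


def _upsample_field(ctrl: np.ndarray, shape) -> np.ndarray:
    """Cubic B-spline-like upsampling of a coarse control field to full size."""
    out = np.empty((3,) + tuple(shape))
    for axis in range(3):
        factors = [n / c for n, c in zip(shape, ctrl.shape[1:])]
        out[axis] = ndimage.zoom(
            ctrl[axis], factors, order=3, mode="nearest", grid_mode=True
        )
    return out


def register_to_reference(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Register ``moving`` to ``fixed``; returns (warped, displacement_field).

    The displacement field has shape ``(3, nx, ny, nz)`` in voxel units and
    follows the pull-back convention ``warped(x) = moving(x + d(x))``.
    """
    config = config or RegistrationConfig()
    config.validate()
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: moving {moving.shape} vs fixed {fixed.shape}")

    mi0 = mutual_information(moving, fixed, config.bins)

    # stage 1: multi-resolution global translation (zero bending energy)
    t = np.zeros(3)
    for level in range(config.n_resolutions - 1, -1, -1):
        factor = 2**level
        if factor > 1:
            mov_l = ndimage.zoom(moving, 1.0 / factor, order=1)
            fix_l = ndimage.zoom(fixed, 1.0 / factor, order=1)
        else:
            mov_l, fix_l = moving, fixed

        def neg_mi(params, mov=mov_l, fix=fix_l):
            return -mutual_information(_translate(mov, np.asarray(params)), fix, config.bins)

        res = optimize.minimize(
            neg_mi,
            t / factor,
            method="Powell",
            options={"maxiter": config.max_iterations, "xtol": 0.05, "ftol": 1e-4},
        )
        t = np.asarray(res.x) * factor

    disp = np.broadcast_to(t[:, None, None, None], (3,) + moving.shape).copy()

    # stage 2: coarse B-spline residual refinement
    if config.refine and config.max_iterations > 0:
        extent = [(n - 1) * s for n, s in zip(moving.shape, spacing)]
        n_ctrl = [
            int(np.clip(round(e / config.grid_spacing) + 1, 2, config.max_control_points))
            for e in extent
        ]
        ctrl_shape = (3, *n_ctrl)
        n_params = int(np.prod(ctrl_shape))

        def objective(params):
            ctrl = params.reshape(ctrl_shape)
            field = _upsample_field(ctrl, moving.shape) + t[:, None, None, None]
            sim = -mutual_information(_warp(moving, field), fixed, config.bins)
            return sim + config.penalty_weight * bending_energy(field)

        res = optimize.minimize(
            objective,
            np.zeros(n_params),
            method="Powell",
            options={"maxiter": 2, "maxfev": 20 * n_params, "xtol": 0.05, "ftol": 1e-4},
        )
        ctrl = res.x.reshape(ctrl_shape)
        disp = _upsample_field(ctrl, moving.shape) + t[:, None, None, None]

    warped = _warp(moving, disp)
    if mutual_information(warped, fixed, config.bins) <= mi0 + 1e-9:
        # keep identity rather than degrade the metric
        return moving.copy(), np.zeros((3,) + moving.shape)
    return warped, disp


def register_volume(
    volume: MpVolume, config: RegistrationConfig | None = None
) -> MpVolume:
    """Align t2w (and dwi_high_b) to the dwi_b0 reference channel."""
    config = config or RegistrationConfig()
    out = MpVolume(
        t2w=volume.t2w,
        dwi_b0=volume.dwi_b0,
        dwi_high_b=volume.dwi_high_b,
        spacing=volume.spacing,
        subject_id=volume.subject_id,
        meta=dict(volume.meta),
    )
    warped, disp = register_to_reference(
        volume.t2w, volume.dwi_b0, config, spacing=volume.spacing
    )
    out.t2w = warped
    out.meta["t2w_displacement_max_voxels"] = float(np.abs(disp).max())
    return out
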