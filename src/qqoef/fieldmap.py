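"""Total-field, R2* and mask estimation from multi-echo complex data.

The total field is the per-voxel slope of unwrapped phase versus echo time,
estimated by weighted least squares and converted to ppm of B0. R2* is the
weighted log-linear magnitude decay rate. CSF is identified by thresholding
R2* (default 2.5 1/s) inside the brain mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import AcquisitionParams, MGREVolume

__all__ = [
    "FieldMaps",
    "fit_total_field",
    "unwrap_phase",
    "erode_mask",
    "fit_r2star",
    "make_csf_mask",
    "process_fieldmap",
]


@dataclass
class FieldMaps:
    """Intermediate reconstruction state produced from an MGRE volume."""

    total_field: np.ndarray  # ppm
    r2star: np.ndarray  # 1/s
    brain_mask: np.ndarray
    csf_mask: np.ndarray
    noise_weight: np.ndarray  # inverse-variance weight of the field estimate
    local_field: np.ndarray | None = None  # ppm, filled by the QSM stage
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Phase unwrapping
# ---------------------------------------------------------------------------

def unwrap_phase(
    phase: np.ndarray,
    magnitude: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Temporally unwrap multi-echo phase (last axis = echo).

    Successive echo-to-echo phase increments are forced into (-pi, pi], so
    the output differs from the input by integer multiples of 2 pi at every
    voxel. Fields whose per-echo-spacing phase advance exceeds pi alias and
    are flagged (returned quality flag False) by checking the residual
    spatial roughness of the increment map.
    """
    ph = np.asarray(phase, dtype=float)
    out = np.unwrap(ph, axis=-1)
    # quality heuristic: remaining voxelwise jumps of ~2 pi between
    # spatial neighbours on the first increment map indicate aliasing
    ok = True
    if ph.shape[-1] >= 2:
        inc = out[..., 1] - out[..., 0]
        for ax in range(inc.ndim):
            d = np.abs(np.diff(inc, axis=ax))
            if d.size and np.nanmax(d) > 1.5 * math.pi:
                ok = False
    return out, ok


# ---------------------------------------------------------------------------
# Total field
# ---------------------------------------------------------------------------

def fit_total_field(
    mgre: MGREVolume,
    mask: np.ndarray | None = None,
    include_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Weighted least-squares phase slope -> total field in ppm.

    Phase is temporally unwrapped, then regressed against echo time per
    voxel with a free intercept (phi0) that is discarded. Weights are the
    squared first-echo magnitude (constant across echoes within a voxel, so
    the WLS slope reduces to the OLS slope; the weight enters the returned
    ``noise_weight`` precision map). All-zero-magnitude voxels get field 0,
    weight 0 and a flag.
    """
    acq = mgre.acq
    te = acq.echo_times
    phase, ok = unwrap_phase(mgre.phase)
    mag0 = mgre.magnitude[..., 0]
    dead = mag0 <= 0

    te_c = te - te.mean()
    denom = float((te_c**2).sum())
    if include_intercept:
        slope = np.tensordot(phase, te_c, axes=([-1], [0])) / denom  # rad/s
    else:
        slope = np.tensordot(phase, te, axes=([-1], [0])) / float((te**2).sum())

    field_ppm = slope / (2.0 * math.pi * acq.larmor_hz_per_ppm)
    # slope variance ~ sigma^2 / (w * sum(te_c^2)); report inverse variance
    # up to the common noise scale
    noise_weight = mag0**2 * denom
    field_ppm = np.where(dead, 0.0, field_ppm)
    noise_weight = np.where(dead, 0.0, noise_weight)
    if mask is not None:
        field_ppm = field_ppm * mask
        noise_weight = noise_weight * mask
    flags = {"unwrap_ok": ok, "n_dead_voxels": int(dead.sum())}
    return field_ppm, noise_weight, flags


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def _spherical_structure(radius_mm: float, voxel_size) -> np.ndarray:
    """Ellipsoidal structuring element of a given physical radius."""
    r = [max(int(round(radius_mm / v)), 0) for v in voxel_size]
    if all(x == 0 for x in r):
        return np.ones((1, 1, 1), dtype=bool)
    zz, yy, xx = np.ogrid[
        -r[0]: r[0] + 1, -r[1]: r[1] + 1, -r[2]: r[2] + 1
    ]
    return (
        (zz / max(r[0], 1e-9)) ** 2
        + (yy / max(r[1], 1e-9)) ** 2
        + (xx / max(r[2], 1e-9)) ** 2
    ) <= 1.0 + 1e-9


def erode_mask(mask: np.ndarray, radius_mm: float, voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Morphological erosion by a spherical element of physical radius (mm)."""
    if radius_mm < 0:
        raise ValueError("radius must be nonnegative")
    if radius_mm == 0:
        return mask.copy()
    struct = _spherical_structure(radius_mm, voxel_size)
    out = ndimage.binary_erosion(np.asarray(mask, dtype=bool), structure=struct)
    if mask.any() and not out.any():
        warnings.warn("erosion radius exceeds object size; empty mask returned")
    return out


def fit_r2star(
    magnitude: np.ndarray,
    echo_times: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel weighted log-linear R2* (1/s), clipped at zero below.

    Log-magnitude is regressed on TE with weights equal to the squared
    magnitude (the delta-method variance of log S is sigma^2 / S^2, so
    squared magnitude is the inverse-variance weight). Voxels with any
    nonpositive magnitude are excluded (R2* = 0).
    """
    te = np.asarray(echo_times, dtype=float)
    mag = np.asarray(magnitude, dtype=float)
    valid = np.all(mag > 0, axis=-1)
    safe = np.where(mag > 0, mag, 1.0)
    logm = np.log(safe)
    w = safe**2
    sw = w.sum(axis=-1)
    te_b = te.reshape((1,) * (mag.ndim - 1) + (-1,))
    tbar = (w * te_b).sum(axis=-1) / sw
    ybar = (w * logm).sum(axis=-1) / sw
    cov = (w * (te_b - tbar[..., None]) * (logm - ybar[..., None])).sum(axis=-1)
    var = (w * (te_b - tbar[..., None]) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / var
    r2s = np.clip(-slope, 0.0, None)
    r2s = np.where(valid, r2s, 0.0)
    if mask is not None:
        r2s = r2s * mask
    return r2s


def make_csf_mask(
    r2star: np.ndarray,
    brain_mask: np.ndarray,
    threshold: float = 2.5,
) -> np.ndarray:
    """CSF mask: voxels with R2* below threshold (default 2.5 1/s) in brain."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (r2star < threshold) & np.asarray(brain_mask, dtype=bool)


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def process_fieldmap(
    mgre: MGREVolume,
    brain_mask: np.ndarray,
    erode_radius_mm: float = 3.0,
    r2star_threshold: float = 2.5,
    voxel_size=None,
) -> FieldMaps:
    """Run the full field-mapping stage: mask erosion, field fit, R2*, CSF."""
    vs = voxel_size if voxel_size is not None else mgre.acq.voxel_size
    mask = erode_mask(np.asarray(brain_mask, dtype=bool), erode_radius_mm, vs)
    total_field, noise_weight, flags = fit_total_field(mgre, mask)
    r2s = fit_r2star(mgre.magnitude, mgre.acq.echo_times, mask)
    csf = make_csf_mask(r2s, mask, r2star_threshold)
    return FieldMaps(
        total_field=total_field,
        r2star=r2s,
        brain_mask=mask,
        csf_mask=csf,
        noise_weight=noise_weight,
        flags=flags,
    )
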