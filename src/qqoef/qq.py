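"""Joint QSM+qBOLD (QQ) inversion with CCTV clustering and VSF correction.

The QQ model couples the two-compartment susceptibility model (phase route)
and the static-dephasing qBOLD magnitude model through shared OEF and
venous blood volume parameters. The joint cost per cluster is

    w * sum_vox (chi_obs - chi_model)^2
      + sum_vox sum_echo (m_obs - S0 exp(-R2 TE) exp(-v f_s(dw TE)))^2

with cluster-shared {OEF, v, chi_nb} and voxel-wise {S0, R2}. Clusters
combine k-means on first-echo-normalized decay curves (temporal) with the
tissue class from the label volume (composition); a total-variation
proximal step smooths the OEF map between re-fits (CCTV). Macroscopic
field gradients across a voxel are compensated beforehand by the voxel
spread function (VSF) sinc factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .fieldmap import FieldMaps
from .phantom import (
    LABELS,
    AcquisitionParams,
    PhysioConstants,
    blood_dephasing_rate,
    fs_integral,
)

__all__ = [
    "QQConfig",
    "OEFResult",
    "vsf_correction",
    "cluster_voxels",
    "qq_cost",
    "solve_qq_cctv",
    "lcurve_weight",
    "lcurve_corner",
    "fit_oef",
]

#: tissue-composition classes used for clustering: label codes per class
DEFAULT_TISSUE_CLASSES: dict[str, tuple[int, ...]] = {
    "gm": (
        LABELS["cortical_gm"],
        LABELS["thalamus"],
        LABELS["putamen"],
        LABELS["pallidum"],
    ),
    "wm": (LABELS["wm"],),
    "wmh": (LABELS["wmh"],),
}


@dataclass
class QQConfig:
    """Settings for the QQ-CCTV solver."""

    w: float | str = "lcurve"  # QSM-vs-qBOLD weighting, scalar or "lcurve"
    n_temporal_clusters: int = 8
    tissue_classes: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_CLASSES)
    )
    tv_weight: float | str = "auto"  # "auto": TV term ~10% of data term at init
    max_iters: int = 3  # CCTV rounds (TV prox + voxelwise refit)
    vsf_mode: str = "nearest"  # {"none", "nearest", "order3"}
    vsf_floor: float = 0.1
    cluster_smooth_sigma: float = 1.0  # voxels; spatial smoothing before k-means
    oef_bounds: tuple[float, float] = (0.0, 1.0)
    v_bounds: tuple[float, float] = (0.0, 0.2)
    r2_bounds: tuple[float, float] = (0.0, 100.0)
    chi_nb_bounds: tuple[float, float] = (-0.3, 0.3)
    lcurve_grid: tuple[float, ...] = tuple(np.logspace(3, 9, 7))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_temporal_clusters < 1:
            raise ValueError("n_temporal_clusters must be >= 1")
        if isinstance(self.tv_weight, (int, float)) and self.tv_weight < 0:
            raise ValueError("tv_weight must be nonnegative")
        if self.vsf_mode not in {"none", "nearest", "order3"}:
            raise ValueError("vsf_mode must be none, nearest or order3")


@dataclass
class OEFResult:
    """Estimated parameter maps; OEF reported in percent [0, 100]."""

    oef: np.ndarray  # percent, NaN outside fitted voxels
    v: np.ndarray
    r2: np.ndarray
    s0: np.ndarray
    chi_nb: np.ndarray
    cluster_id: np.ndarray  # -1 outside
    converged: np.ndarray  # bool per voxel (its cluster's fit status)
    excluded_csf: np.ndarray
    w: float = 0.0
    cost_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# VSF correction
# ---------------------------------------------------------------------------

def _field_gradients_rad_s(total_field: np.ndarray, larmor_hz_per_ppm: float, mode: str) -> np.ndarray:
    """Across-voxel angular-frequency differences (rad/s), shape (3, *vol)."""
    omega = 2.0 * math.pi * larmor_hz_per_ppm * np.asarray(total_field, dtype=float)
    grads = np.empty((3,) + omega.shape)
    for ax in range(3):
        g = np.gradient(omega, axis=ax)  # central differences, one-sided at edges
        if mode == "order3":
            # least-squares plane fit over the 3x3x3 neighbourhood equals the
            # central difference averaged over the two transverse axes
            from scipy.ndimage import uniform_filter1d

            for other in range(3):
                if other != ax:
                    g = uniform_filter1d(g, size=3, axis=other, mode="nearest")
        grads[ax] = g
    return grads


def vsf_correction(
    magnitude: np.ndarray,
    total_field: np.ndarray,
    acq: AcquisitionParams,
    mode: str = "nearest",
    floor: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-spread-function compensation of macroscopic field gradients.

    Treats the macroscopic field as linearly varying within each voxel: a
    through-voxel angular frequency difference Delta-omega along each axis
    attenuates the echo magnitude by |sinc(Delta-omega TE / 2)|. The
    per-voxel correction factor F(TE) (product over axes, floored at
    ``floor`` to bound noise amplification) divides the magnitude.
    Returns (corrected magnitude, correction factor map).
    """
    mag = np.asarray(magnitude, dtype=float)
    if mode == "none":
        return mag.copy(), np.ones_like(mag)
    grads = _field_gradients_rad_s(total_field, acq.larmor_hz_per_ppm, mode)
    te = acq.echo_times
    arg = 0.5 * grads[..., None] * te  # (3, *vol, echo)
    f = np.abs(np.sinc(arg / math.pi)).prod(axis=0)  # np.sinc(x) = sin(pi x)/(pi x)
    f = np.clip(f, floor, None)
    return mag / f, f


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_voxels(
    magnitude: np.ndarray,
    labels: np.ndarray,
    cfg: QQConfig,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Temporal x tissue-composition cluster map; -1 outside fitted voxels.

    Decay curves are mildly smoothed in space (``cluster_smooth_sigma``
    voxels; clustering input only -- the fit always uses raw data),
    normalized by the first echo and k-means clustered (seeded); the final
    id crosses the temporal cluster with the tissue class of each voxel.
    Without the smoothing, k-means partitions identical-decay voxels by
    their noise realization and the cluster-mean curves acquire a
    systematic non-exponential bend that biases OEF downward.
    """
    from scipy.ndimage import gaussian_filter
    from sklearn.cluster import KMeans

    lab = np.asarray(labels)
    tissue_idx = np.full(lab.shape, -1, dtype=np.int32)
    for t, (_, codes) in enumerate(cfg.tissue_classes.items()):
        for code in codes:
            tissue_idx[lab == code] = t
    mask = tissue_idx >= 0
    if exclude is not None:
        mask &= ~np.asarray(exclude, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < 1:
        raise ValueError("no voxels available for clustering")

    mag_in = np.asarray(magnitude, dtype=float)
    if cfg.cluster_smooth_sigma > 0:
        mag_in = np.stack(
            [gaussian_filter(mag_in[..., e], cfg.cluster_smooth_sigma)
             for e in range(mag_in.shape[-1])],
            axis=-1,
        )
    curves = mag_in[mask]
    first = curves[:, :1]
    first = np.where(first > 0, first, 1.0)
    curves = curves / first

    k = min(cfg.n_temporal_clusters, n_vox)
    if k < cfg.n_temporal_clusters:
        warnings.warn("fewer voxels than temporal clusters; reducing cluster count")
    if k == 1 or np.allclose(curves, curves[0]):
        temporal = np.zeros(n_vox, dtype=np.int32)
    else:
        km = KMeans(n_clusters=k, random_state=cfg.seed, n_init=4)
        temporal = km.fit_predict(curves)

    n_tissue = len(cfg.tissue_classes)
    combo = temporal * n_tissue + tissue_idx[mask]
    _, compact = np.unique(combo, return_inverse=True)
    out = np.full(lab.shape, -1, dtype=np.int32)
    out[mask] = compact
    return out


# ---------------------------------------------------------------------------
# Cost and per-cluster fitting
# ---------------------------------------------------------------------------

def _magnitude_model(s0, r2, v, oef, te, const, b0):
    """qBOLD magnitude model on flattened voxels, shape (n_vox, n_echo)."""
    dw = blood_dephasing_rate(oef, const, b0)
    x = np.atleast_1d(dw)[..., None] * te
    return s0[:, None] * np.exp(-r2[:, None] * te - np.atleast_1d(v)[..., None] * fs_integral(x))


def qq_cost(
    oef: np.ndarray,
    v: np.ndarray,
    chi_nb: np.ndarray,
    s0: np.ndarray,
    r2: np.ndarray,
    chi_obs: np.ndarray,
    mag_obs: np.ndarray,
    w: float,
    const: PhysioConstants,
    acq: AcquisitionParams,
) -> float:
    """Joint QQ cost over flattened voxels (mag_obs shape (n_vox, n_echo))."""
    from .phantom import chi_model

    chi_pred = chi_model(oef, v, chi_nb, const)
    te = acq.echo_times
    dw = blood_dephasing_rate(oef, const, acq.b0)
    x = np.asarray(dw)[..., None] * te
    m_pred = s0[..., None] * np.exp(-r2[..., None] * te - np.asarray(v)[..., None] * fs_integral(x))
    return float(w * ((chi_obs - chi_pred) ** 2).sum() + ((mag_obs - m_pred) ** 2).sum())


def _profile_s0_r2(mag, te, v, oef, const, b0, r2_hi):
    """Closed-form voxel-wise (S0, R2) given (OEF, v), scalar or per voxel.

    With the blood dephasing term moved to the left, log-magnitude is
    linear in TE; a magnitude^2-weighted regression gives S0 and R2.
    """
    dw = blood_dephasing_rate(oef, const, b0)
    if np.ndim(dw) == 0:
        fsv = fs_integral(dw * te)  # (n_echo,)
        vterm = v * fsv
    else:
        fsv = fs_integral(np.asarray(dw)[:, None] * te)  # (n_vox, n_echo)
        vterm = np.asarray(v)[:, None] * fsv
    safe = np.where(mag > 0, mag, 1e-12)
    z = np.log(safe) + vterm  # log S0 - R2 TE
    wgt = safe**2
    sw = wgt.sum(axis=1)
    tbar = (wgt * te).sum(axis=1) / sw
    zbar = (wgt * z).sum(axis=1) / sw
    var = (wgt * (te - tbar[:, None]) ** 2).sum(axis=1)
    cov = (wgt * (te - tbar[:, None]) * (z - zbar[:, None])).sum(axis=1)
    r2 = np.clip(-cov / var, 0.0, r2_hi)
    s0 = np.exp(zbar + r2 * tbar)
    return s0, r2, fsv


def _fit_cluster(chi_obs, mag_obs, te, w, const, b0, cfg):
    """Bounded NLLS over (OEF, v) with chi_nb, S0, R2 profiled out."""
    chi_mean = float(chi_obs.mean())
    sqrt_w = math.sqrt(max(w, 0.0))

    def chi_nb_of(oef, v):
        blood = const.chi_oxy + oef * const.delta_chi0 * const.hct
        nb = (chi_mean - v * blood) / max(1.0 - v, 1e-6)
        return float(np.clip(nb, *cfg.chi_nb_bounds))

    def residuals(p):
        oef, v = p
        nb = chi_nb_of(oef, v)
        blood = const.chi_oxy + oef * const.delta_chi0 * const.hct
        chi_pred = (1.0 - v) * nb + v * blood
        s0, r2, fsv = _profile_s0_r2(mag_obs, te, v, oef, const, b0, cfg.r2_bounds[1])
        m_pred = s0[:, None] * np.exp(-r2[:, None] * te - v * fsv)
        r_qsm = sqrt_w * (chi_obs - chi_pred)
        r_mag = (mag_obs - m_pred).ravel()
        return np.concatenate([r_qsm, r_mag])

    lo = [cfg.oef_bounds[0], cfg.v_bounds[0]]
    hi = [cfg.oef_bounds[1], cfg.v_bounds[1]]
    try:
        sol = least_squares(
            residuals,
            x0=[0.3, 0.03],
            bounds=(lo, hi),
            x_scale=[0.1, 0.01],
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=200,
        )
        oef, v = sol.x
        ok = bool(sol.success)
    except Exception:
        oef, v, ok = 0.3, 0.03, False
    nb = chi_nb_of(oef, v)
    s0, r2, _ = _profile_s0_r2(mag_obs, te, v, oef, const, b0, cfg.r2_bounds[1])
    return oef, v, nb, s0, r2, ok


def _stage1(chi, mag_flat, cluster_flat, te, w, const, b0, cfg):
    """Cluster-wise fits; returns per-voxel parameter vectors and flags."""
    n = chi.shape[0]
    oef = np.full(n, np.nan)
    v = np.zeros(n)
    nb = np.zeros(n)
    s0 = np.zeros(n)
    r2 = np.zeros(n)
    ok = np.zeros(n, dtype=bool)
    for cid in np.unique(cluster_flat):
        sel = cluster_flat == cid
        o, vv, cnb, cs0, cr2, cok = _fit_cluster(
            chi[sel], mag_flat[sel], te, w, const, b0, cfg
        )
        oef[sel], v[sel], nb[sel] = o, vv, cnb
        s0[sel], r2[sel], ok[sel] = cs0, cr2, cok
    return oef, v, nb, s0, r2, ok


# ---------------------------------------------------------------------------
# L-curve
# ---------------------------------------------------------------------------

def lcurve_corner(rho: np.ndarray, eta: np.ndarray) -> int | None:
    """Index of maximum Menger curvature on the log-log residual curve.

    Returns None when the curve is degenerate (collinear points). Ties
    resolve to the smaller index.
    """
    x = np.log10(np.maximum(np.asarray(rho, dtype=float), 1e-300))
    y = np.log10(np.maximum(np.asarray(eta, dtype=float), 1e-300))
    n = len(x)
    if n < 3:
        return None
    best, best_k = 0.0, None
    for k in range(1, n - 1):
        a = np.array([x[k - 1], y[k - 1]])
        b = np.array([x[k], y[k]])
        c = np.array([x[k + 1], y[k + 1]])
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        la, lb, lc = np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(c - a)
        if la * lb * lc == 0:
            continue
        curv = 2.0 * area2 / (la * lb * lc)
        if curv > best + 1e-12:
            best, best_k = curv, k
    return best_k if best > 1e-9 else None


def lcurve_weight(
    chi: np.ndarray,
    mag_flat: np.ndarray,
    cluster_flat: np.ndarray,
    te: np.ndarray,
    const: PhysioConstants,
    b0: float,
    cfg: QQConfig,
    candidates=None,
) -> float:
    """Pick the QSM-vs-qBOLD weight w by L-curve analysis.

    Runs a stage-1 fit at every candidate w, records the two residual
    terms, and returns the maximum-curvature point of the log-log curve.
    Degenerate curves fall back to the geometric mean of the grid.
    """
    grid = np.sort(np.asarray(candidates if candidates is not None else cfg.lcurve_grid, dtype=float))
    if len(grid) == 1:
        warnings.warn("single-candidate L-curve grid; returning it unchanged")
        return float(grid[0])
    if len(grid) < 3:
        warnings.warn("fewer than 3 candidates; returning geometric mean")
        return float(np.exp(np.mean(np.log(grid))))
    from .phantom import chi_model as _chi_model

    r_qsm, r_mag = [], []
    for w in grid:
        oef, v, nb, s0, r2, _ = _stage1(chi, mag_flat, cluster_flat, te, w, const, b0, cfg)
        chi_pred = _chi_model(np.clip(oef, 0, 1), v, nb, const)
        m_pred = _magnitude_model(s0, r2, v, np.clip(oef, 0, 1), te, const, b0)
        r_qsm.append(float(((chi - chi_pred) ** 2).sum()))
        r_mag.append(float(((mag_flat - m_pred) ** 2).sum()))
    k = lcurve_corner(np.asarray(r_qsm), np.asarray(r_mag))
    if k is None:
        warnings.warn("degenerate L-curve; using geometric-mean weight")
        return float(np.exp(np.mean(np.log(grid))))
    return float(grid[k])


# ---------------------------------------------------------------------------
# CCTV solve
# ---------------------------------------------------------------------------

def solve_qq_cctv(
    chi_map: np.ndarray,
    magnitude: np.ndarray,
    brain_mask: np.ndarray,
    csf_mask: np.ndarray,
    cluster_id: np.ndarray,
    cfg: QQConfig | None = None,
    const: PhysioConstants = PhysioConstants(),
    acq: AcquisitionParams | None = None,
) -> OEFResult:
    """Cluster-wise QQ inversion with TV smoothing of the OEF map.

    Stage 1 fits each cluster by bounded nonlinear least squares with
    cluster-shared {OEF, v, chi_nb} and voxel-wise {S0, R2} (profiled in
    closed form). Stage 2 alternates an isotropic total-variation proximal
    step on the OEF map with voxel-wise re-fits of S0 and R2, for
    ``max_iters`` rounds. CSF voxels are excluded throughout; OEF is
    emitted in percent.
    """
    from skimage.restoration import denoise_tv_chambolle

    cfg = cfg or QQConfig()
    if acq is None:
        acq = AcquisitionParams(matrix_size=tuple(np.asarray(chi_map).shape))
    te = acq.echo_times
    mask = np.asarray(brain_mask, dtype=bool) & (np.asarray(cluster_id) >= 0)
    csf = np.asarray(csf_mask, dtype=bool)
    mask &= ~csf
    if not mask.any():
        raise ValueError("no voxels to fit after CSF exclusion")

    chi_flat = np.asarray(chi_map, dtype=float)[mask]
    mag_flat = np.asarray(magnitude, dtype=float)[mask]
    clus_flat = np.asarray(cluster_id)[mask]

    if cfg.w == "lcurve":
        w = lcurve_weight(chi_flat, mag_flat, clus_flat, te, const, acq.b0, cfg)
    else:
        w = float(cfg.w)

    oef, v, nb, s0, r2, ok = _stage1(chi_flat, mag_flat, clus_flat, te, w, const, acq.b0, cfg)
    cost_history = [qq_cost(oef, v, nb, s0, r2, chi_flat, mag_flat, w, const, acq)]

    # resolve the TV weight: ~10% of the reducible data term per unit TV at
    # init; the QSM term carries an irreducible within-cluster floor (chi_nb
    # is cluster-shared), so only the magnitude misfit enters the rule
    tv_weight = cfg.tv_weight
    if tv_weight == "auto":
        m_pred = _magnitude_model(s0, r2, v, np.clip(oef, 0, 1), te, const, acq.b0)
        mag_term = float(((mag_flat - m_pred) ** 2).sum())
        oef_map0 = np.zeros(mask.shape)
        oef_map0[mask] = oef
        tv0 = sum(
            float(np.abs(np.diff(oef_map0, axis=ax)).sum()) for ax in range(3)
        )
        tv_weight = 0.1 * mag_term / tv0 if tv0 > 0 else 0.0

    fill = float(np.mean(oef)) if len(oef) else 0.0
    oef_map = np.full(mask.shape, fill)
    oef_map[mask] = oef
    for _ in range(cfg.max_iters):
        if tv_weight > 0:
            sm = denoise_tv_chambolle(oef_map, weight=float(tv_weight))
            oef_map = np.where(mask, sm, fill)
            oef = np.clip(oef_map[mask], *cfg.oef_bounds)
        # voxel-wise refit of S0, R2 at the (possibly smoothed) OEF
        s0, r2, _ = _profile_s0_r2(mag_flat, te, v, oef, const, acq.b0, cfg.r2_bounds[1])
        cost_history.append(qq_cost(oef, v, nb, s0, r2, chi_flat, mag_flat, w, const, acq))

    shape = mask.shape
    out_oef = np.full(shape, np.nan)
    out_oef[mask] = 100.0 * np.clip(oef, 0.0, 1.0)  # percent
    out_v = np.zeros(shape)
    out_v[mask] = v
    out_nb = np.zeros(shape)
    out_nb[mask] = nb
    out_s0 = np.zeros(shape)
    out_s0[mask] = s0
    out_r2 = np.zeros(shape)
    out_r2[mask] = r2
    out_ok = np.zeros(shape, dtype=bool)
    out_ok[mask] = ok
    return OEFResult(
        oef=out_oef,
        v=out_v,
        r2=out_r2,
        s0=out_s0,
        chi_nb=out_nb,
        cluster_id=np.asarray(cluster_id).copy(),
        converged=out_ok,
        excluded_csf=csf.copy(),
        w=w,
        cost_history=cost_history,
    )


def fit_oef(
    chi_map: np.ndarray,
    magnitude4d: np.ndarray,
    fm: FieldMaps,
    labels: np.ndarray,
    cfg: QQConfig | None = None,
    const: PhysioConstants = PhysioConstants(),
    acq: AcquisitionParams | None = None,
) -> OEFResult:
    """VSF-correct the magnitude, cluster, and run the CCTV solve."""
    cfg = cfg or QQConfig()
    if acq is None:
        acq = AcquisitionParams(matrix_size=tuple(np.asarray(chi_map).shape))
    mag, _ = vsf_correction(magnitude4d, fm.total_field, acq, cfg.vsf_mode, cfg.vsf_floor)
    cluster_id = cluster_voxels(mag, np.where(fm.brain_mask, labels, 0), cfg, exclude=fm.csf_mask)
    return solve_qq_cctv(
        chi_map, mag, fm.brain_mask, fm.csf_mask, cluster_id, cfg, const, acq
    )
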