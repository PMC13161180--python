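"""Region-of-interest OEF summaries, WMH burden and mask agreement.

ROI means optionally erode deep-gray regions by one voxel to suppress
partial-volume contamination from adjacent CSF or WM. WMH burden is the
volumetric fraction of white-matter-hyperintensity voxels relative to the
whole brain, split into periventricular (PWMH) and deep (DWMH) components
by the "continuity to ventricle" rule on 26-connected components.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .phantom import LABELS

__all__ = ["roi_mean", "wmh_fraction", "split_pwmh_dwmh", "dice", "roi_table"]

#: ROI codes eroded by 1 voxel before averaging (deep gray nuclei)
DGM_CODES = (LABELS["thalamus"], LABELS["putamen"], LABELS["pallidum"])


def roi_mean(
    oef_map: np.ndarray,
    labels: np.ndarray,
    roi_codes: dict[str, int],
    erode_dgm: bool = True,
    exclude: np.ndarray | None = None,
    erosion_connectivity: int = 1,
) -> dict[str, float]:
    """Mean OEF per ROI; NaN-valued and excluded voxels are omitted.

    Deep-gray ROIs are eroded by one voxel (face-connected structuring
    element by default) before averaging when ``erode_dgm`` is set. An ROI
    that is empty after erosion/exclusion yields NaN with a warning.
    """
    lab = np.asarray(labels)
    known = set(LABELS.values()) | set(np.unique(lab).tolist())
    out: dict[str, float] = {}
    vals = np.asarray(oef_map, dtype=float)
    bad = ~np.isfinite(vals)
    if exclude is not None:
        bad = bad | np.asarray(exclude, dtype=bool)
    struct = ndimage.generate_binary_structure(3, erosion_connectivity)
    for name, code in roi_codes.items():
        if code not in known:
            raise ValueError(f"unknown ROI code {code} for {name!r}")
        sel = lab == code
        if erode_dgm and code in DGM_CODES:
            sel = ndimage.binary_erosion(sel, structure=struct)
        sel = sel & ~bad
        if not sel.any():
            warnings.warn(f"ROI {name!r} empty after erosion/exclusion")
            out[name] = float("nan")
        else:
            out[name] = float(vals[sel].mean())
    return out


def wmh_fraction(labels: np.ndarray, wmh_code: int = LABELS["wmh"]) -> float:
    """WMH volume as a percentage of brain volume: 100 * #WMH / #brain."""
    lab = np.asarray(labels)
    brain = lab > 0
    n_brain = int(brain.sum())
    if n_brain == 0:
        raise ValueError("empty brain: no labeled voxels")
    return 100.0 * float((lab == wmh_code).sum()) / n_brain


def split_pwmh_dwmh(
    wmh_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    connectivity: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Split WMH into periventricular and deep masks by ventricle continuity.

    Connected components of the WMH mask (26-connectivity by default,
    ``connectivity`` in {1, 2, 3} as in scipy) containing any voxel
    adjacent to the ventricle surface are periventricular; all others are
    deep. The two outputs partition the input exactly.
    """
    wmh = np.asarray(wmh_mask, dtype=bool)
    vent = np.asarray(ventricle_mask, dtype=bool)
    if (wmh & vent).any():
        raise ValueError("WMH and ventricle masks must be disjoint")
    struct = ndimage.generate_binary_structure(3, connectivity)
    comp, n = ndimage.label(wmh, structure=struct)
    pwmh = np.zeros_like(wmh)
    if n:
        vent_halo = ndimage.binary_dilation(vent, structure=struct)
        touching = np.unique(comp[vent_halo & wmh])
        touching = touching[touching > 0]
        pwmh = np.isin(comp, touching)
    return pwmh, wmh & ~pwmh


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B| / (|A|+|B|); both-empty -> 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1")
        return 1.0
    return 2.0 * float((a & b).sum()) / denom


def roi_table(
    oef_map: np.ndarray,
    labels: np.ndarray,
    exclude: np.ndarray | None = None,
    erode_dgm: bool = True,
) -> dict[str, float]:
    """Subject-level summary: per-ROI OEF means plus WMH burden split.

    The phantom has no isthmus-cingulate / rostral-middle-frontal
    parcellation, so the cortical ribbon stands in for cortical gray.
    """
    codes = {
        "thalamus": LABELS["thalamus"],
        "putamen": LABELS["putamen"],
        "pallidum": LABELS["pallidum"],
        "cortical_gm": LABELS["cortical_gm"],
    }
    means = roi_mean(oef_map, labels, codes, erode_dgm=erode_dgm, exclude=exclude)
    lab = np.asarray(labels)
    brain = lab > 0
    vals = np.asarray(oef_map, dtype=float)
    ok = brain & np.isfinite(vals)
    if exclude is not None:
        ok &= ~np.asarray(exclude, dtype=bool)
    means["whole_brain"] = float(vals[ok].mean()) if ok.any() else float("nan")
    total = wmh_fraction(labels)
    pwmh, dwmh = split_pwmh_dwmh(lab == LABELS["wmh"], lab == LABELS["csf"])
    n_brain = int(brain.sum())
    means["wmh_fraction"] = total
    means["pwmh_fraction"] = 100.0 * float(pwmh.sum()) / n_brain
    means["dwmh_fraction"] = 100.0 * float(dwmh.sum()) / n_brain
    return means
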