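"""End-to-end driver: simulate -> fieldmap -> qsm -> fit-oef -> roi-stats -> cohort-stats.

A single YAML config (or nested dict) plus a seed drives the whole chain on
synthetic data, writing NIfTI intermediates and tidy CSV results.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .cohortstats import analyze_cohort
from .fieldmap import process_fieldmap
from .phantom import (
    AcquisitionParams,
    CohortSpec,
    PhysioConstants,
    make_phantom,
    simulate_cohort,
    simulate_mgre,
)
from .qq import QQConfig, fit_oef
from .qsm import QSMConfig, run_qsm
from .roistats import roi_table

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "phantom": {"matrix": 48, "lesion_load": 0.02, "voxel_size": [2.0, 2.0, 2.0]},
    "acquisition": {"n_echoes": 10, "te_first": 6.68e-3, "delta_te": 4.06e-3, "b0": 3.0},
    "noise_sigma": 0.0,
    "fieldmap": {"erode_radius_mm": 3.0, "r2star_threshold": 2.5},
    "qsm": {},
    "qq": {"w": 1e7, "n_temporal_clusters": 4, "vsf_mode": "nearest"},
    "cohort": {"n_ad": 16, "n_nonad": 15, "predictor": "log_wmh"},
    "analysis": {"predictor": "log_wmh", "covariates": ["age"], "bh": True,
                 "exclude_influential": False},
}


def _merge(base: dict, extra: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(
    config: dict | str | Path | None = None,
    seed: int = 0,
    outdir: str | Path = "qqoef_out",
    save_nifti: bool = True,
) -> dict:
    """Run the full synthetic-data pipeline; returns the key results.

    Returns a dict with the ground truth, field maps, susceptibility map,
    OEF result, the subject's ROI summary row, the simulated cohort table
    and the tidy regression results frame (also written as CSV).
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ph = cfg["phantom"]
    n = int(ph["matrix"])
    vs = tuple(float(v) for v in ph["voxel_size"])
    gt = make_phantom((n, n, n), float(ph["lesion_load"]), seed=seed, voxel_size=vs)
    acq = AcquisitionParams(matrix_size=(n, n, n), voxel_size=vs, **cfg["acquisition"])
    const = PhysioConstants()
    mgre = simulate_mgre(gt, const, acq, noise_sigma=float(cfg["noise_sigma"]), seed=seed + 1)

    fm = process_fieldmap(mgre, gt.brain_mask, voxel_size=vs, **cfg["fieldmap"])
    chi, fm, qsm_info = run_qsm(fm, mgre.magnitude[..., 0], QSMConfig(**cfg["qsm"]), vs)
    qq_cfg = QQConfig(seed=seed, **cfg["qq"])
    oef = fit_oef(chi, mgre.magnitude, fm, gt.labels, qq_cfg, const, acq)

    # WMH burden is a property of the full label volume; OEF means skip
    # voxels outside the fitted (SMV-reduced, CSF-excluded) region via NaNs
    subject_row = roi_table(oef.oef, gt.labels, exclude=oef.excluded_csf)

    cohort = simulate_cohort(CohortSpec(seed=seed + 2, **cfg["cohort"]))
    ana = cfg["analysis"]
    results = analyze_cohort(
        cohort,
        predictor=ana["predictor"],
        covariates=tuple(ana["covariates"]),
        exclude_influential=bool(ana["exclude_influential"]),
        bh=bool(ana["bh"]),
    )

    cohort.to_csv(outdir / "cohort.csv", index=False)
    results.to_csv(outdir / "regression_results.csv", index=False)
    pd.DataFrame([subject_row]).to_csv(outdir / "subject_roi_stats.csv", index=False)
    if save_nifti:
        qio.save_ground_truth(gt, outdir / "truth")
        qio.save_map(chi, outdir / "chi.nii.gz", vs)
        qio.save_map(fm.total_field, outdir / "total_field.nii.gz", vs)
        qio.save_map(oef.oef, outdir / "oef_percent.nii.gz", vs)

    return {
        "ground_truth": gt,
        "mgre": mgre,
        "fieldmaps": fm,
        "chi": chi,
        "qsm_info": qsm_info,
        "oef": oef,
        "subject_row": subject_row,
        "cohort": cohort,
        "results": results,
        "outdir": outdir,
    }
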