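"""NIfTI / CSV / JSON sidecar I/O for pipeline inputs and outputs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import AcquisitionParams, GroundTruth, MGREVolume, LABELS

__all__ = [
    "save_map",
    "load_map",
    "save_mgre",
    "load_mgre",
    "save_ground_truth",
    "save_label_codes",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_map(arr: np.ndarray, path: str | Path, voxel_size=(2.0, 2.0, 2.0)) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), vs


def save_mgre(mgre: MGREVolume, stem: str | Path) -> None:
    """Write magnitude/phase 4-D NIfTI pairs plus a JSON echo-time sidecar."""
    stem = Path(stem)
    vs = mgre.acq.voxel_size
    save_map(mgre.magnitude, stem.with_name(stem.name + "_mag.nii.gz"), vs)
    save_map(mgre.phase, stem.with_name(stem.name + "_phase.nii.gz"), vs)
    sidecar = {
        "echo_times_s": mgre.acq.echo_times.tolist(),
        "b0_tesla": mgre.acq.b0,
        "voxel_size_mm": list(vs),
        "noise_sigma": mgre.noise_sigma,
    }
    stem.with_name(stem.name + ".json").write_text(json.dumps(sidecar, indent=2))


def load_mgre(stem: str | Path) -> MGREVolume:
    stem = Path(stem)
    mag, vs = load_map(stem.with_name(stem.name + "_mag.nii.gz"))
    phase, _ = load_map(stem.with_name(stem.name + "_phase.nii.gz"))
    meta = json.loads(stem.with_name(stem.name + ".json").read_text())
    te = np.asarray(meta["echo_times_s"], dtype=float)
    acq = AcquisitionParams(
        n_echoes=len(te),
        te_first=float(te[0]),
        delta_te=float(te[1] - te[0]),
        b0=float(meta["b0_tesla"]),
        voxel_size=tuple(meta["voxel_size_mm"]),
        matrix_size=tuple(mag.shape[:3]),
    )
    return MGREVolume(signal=mag * np.exp(1j * phase), acq=acq,
                      noise_sigma=float(meta.get("noise_sigma", 0.0)))


def save_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = gt.voxel_size
    for name in ("oef", "v", "r2", "s0", "chi_nb"):
        save_map(getattr(gt, name), outdir / f"truth_{name}.nii.gz", vs)
    img = nib.Nifti1Image(gt.labels.astype(np.int16), _affine(vs))
    nib.save(img, str(outdir / "labels.nii.gz"))
    save_label_codes(outdir / "labels.json")


def save_label_codes(path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(LABELS), indent=2))
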