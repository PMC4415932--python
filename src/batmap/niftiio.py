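"""NIfTI and CSV input/output.

Volumes are written with a diagonal affine built from the voxel size,
axes ordered x = right-left, y = anterior-posterior (posterior = +y),
z = feet-head.  Multi-echo complex data is stored as a real/imaginary
pair of 4D NIfTIs plus a JSON sidecar holding the acquisition protocol
and the fat spectrum, so a data set is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import MultiEchoImage, TruthMaps
from .protocol import AcquisitionProtocol, FatSpectrum
from .recon import QuantitativeMaps

POSTERIOR_AXIS = 1  # +y is posterior


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def save_volume(
    data: np.ndarray, voxel_size, path, dtype=None, description: str = ""
) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size) + (1.0,) * (arr.ndim - 3))
    if description:
        img.header["descrip"] = description.encode()[:79]
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel


def save_mask(mask: np.ndarray, voxel_size, path, description: str = "") -> Path:
    return save_volume(
        np.asarray(mask).astype(np.uint8), voxel_size, path, description=description
    )


def load_mask(path) -> np.ndarray:
    data, _ = load_volume(path)
    return data.astype(bool)


def save_multiecho(
    image: MultiEchoImage, prefix, spectrum: Optional[FatSpectrum] = None,
    description: str = "",
) -> dict:
    """Write a multi-echo image as <prefix>_real/_imag NIfTIs + sidecar."""
    prefix = Path(prefix)
    vs = image.protocol.voxel_size
    real = save_volume(image.signal.real, vs, prefix.with_name(prefix.name + "_real.nii.gz"),
                       dtype=np.float32, description=description)
    imag = save_volume(image.signal.imag, vs, prefix.with_name(prefix.name + "_imag.nii.gz"),
                       dtype=np.float32, description=description)
    sidecar = prefix.with_name(prefix.name + ".json")
    payload = {"protocol": image.protocol.to_dict()}
    if spectrum is not None:
        payload["fat_spectrum"] = spectrum.to_dict()
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"real": real, "imag": imag, "sidecar": sidecar}


def load_multiecho(prefix) -> Tuple[MultiEchoImage, Optional[FatSpectrum]]:
    prefix = Path(prefix)
    real, _ = load_volume(prefix.with_name(prefix.name + "_real.nii.gz"))
    imag, _ = load_volume(prefix.with_name(prefix.name + "_imag.nii.gz"))
    payload = json.loads(prefix.with_name(prefix.name + ".json").read_text())
    protocol = AcquisitionProtocol.from_dict(payload["protocol"])
    spectrum = (
        FatSpectrum.from_dict(payload["fat_spectrum"])
        if "fat_spectrum" in payload
        else None
    )
    signal = np.asarray(real, dtype=np.float64) + 1j * np.asarray(imag, dtype=np.float64)
    return MultiEchoImage(signal=signal, protocol=protocol), spectrum


MAP_NAMES = ("water", "fat", "ff", "r2s", "fieldmap", "residual")


def save_maps(maps: QuantitativeMaps, outdir, stem: str = "maps", description: str = "") -> dict:
    outdir = Path(outdir)
    out = {}
    for name in MAP_NAMES:
        out[name] = save_volume(
            getattr(maps, name), maps.voxel_size,
            outdir / f"{stem}_{name}.nii.gz", dtype=np.float32,
            description=description,
        )
    out["degenerate"] = save_mask(
        maps.degenerate, maps.voxel_size, outdir / f"{stem}_degenerate.nii.gz",
        description=description,
    )
    return out


def load_maps(outdir, stem: str = "maps") -> QuantitativeMaps:
    outdir = Path(outdir)
    vols = {}
    voxel = (1.0, 1.0, 1.0)
    for name in MAP_NAMES:
        data, voxel = load_volume(outdir / f"{stem}_{name}.nii.gz")
        vols[name] = np.asarray(data, dtype=np.float64)
    degen_path = outdir / f"{stem}_degenerate.nii.gz"
    degenerate = load_mask(degen_path) if degen_path.exists() else None
    return QuantitativeMaps(voxel_size=voxel, degenerate=degenerate, **vols)


def save_truth(truth: TruthMaps, outdir, stem: str = "truth") -> dict:
    outdir = Path(outdir)
    out = {}
    for name in ("water", "fat", "r2s", "fieldmap"):
        out[name] = save_volume(
            getattr(truth, name), truth.voxel_size, outdir / f"{stem}_{name}.nii.gz",
            dtype=np.float32,
        )
    out["label"] = save_volume(
        truth.label, truth.voxel_size, outdir / f"{stem}_label.nii.gz", dtype=np.int16
    )
    return out


SUMMARY_COLUMNS = (
    "subject", "state", "voi", "mean_ff_pct", "sd_ff_pct",
    "mean_r2s", "sd_r2s", "n_voxels", "volume_ml",
)


def save_measurements(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path)
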