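"""Readers and writers for the pipeline's on-disk formats.

Force maps travel as UTF-8 TSV, one file per map: ``#key=value`` header
lines carry the calibration and acquisition metadata, followed by the
columns ``pixel_i  pixel_j  height_m  deflection_V``.  Elasticity maps are
a TSV grid plus a JSON provenance sidecar.  Images are multi-page TIFF with
pixel-size metadata; masks are 8-bit TIFF (0/255); ground truth is a JSON
sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .calibration import AcquisitionSettings, CantileverCalibration
from .curves import ElasticityMap, ForceDistanceCurve, ForceMap
from .imaging import FluorImage

REQUIRED_MAP_KEYS = ("sensitivity_nm_per_V", "spring_constant_pN_per_nm",
                     "alpha_deg", "nu", "setpoint_N", "sample_rate_Hz")


class FormatError(ValueError):
    """A file failed validation against the documented format."""


# ---------------------------------------------------------------------------
# force maps
# ---------------------------------------------------------------------------

def save_force_map(fmap: ForceMap, path) -> None:
    path = Path(path)
    header = {}
    header.update(fmap.calibration.to_header())
    header.update(fmap.acquisition.to_header())
    header["rows"] = fmap.shape[0]
    header["cols"] = fmap.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in header.items():
            fh.write(f"#{k}={v}\n")
        fh.write("pixel_i\tpixel_j\theight_m\tdeflection_V\n")
        for idx, curve in enumerate(fmap.curves):
            i, j = divmod(idx, fmap.shape[1])
            for z, v in zip(curve.height_m, curve.deflection_V):
                fh.write(f"{i}\t{j}\t{z:.9e}\t{v:.9e}\n")


def load_force_map(path) -> ForceMap:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    header = {}
    with open(path, encoding="utf-8") as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            header[k] = v
            pos += 1
    for key in REQUIRED_MAP_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing required header key '{key}'")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse table ({exc})") from exc
    needed = ["pixel_i", "pixel_j", "height_m", "deflection_V"]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    if df[needed].isna().any().any():
        raise FormatError(f"{path}: ragged or non-numeric rows detected")
    if len(df) == 0:
        raise FormatError(f"{path}: file contains no curve samples")

    calib = CantileverCalibration(
        sensitivity_nm_per_V=float(header["sensitivity_nm_per_V"]),
        spring_constant_pN_per_nm=float(header["spring_constant_pN_per_nm"]),
        alpha_deg=float(header["alpha_deg"]), nu=float(header["nu"]))
    acq = AcquisitionSettings(
        setpoint_force=float(header["setpoint_N"]),
        z_length=float(header.get("z_length_m", 15e-6)),
        z_speed=float(header.get("z_speed_m_per_s", 30e-6)),
        sample_rate=float(header["sample_rate_Hz"]),
        grid_points=int(header.get("grid_points", 64)),
        scan_size=float(header.get("scan_size_m", 100e-6)))
    rows = int(header.get("rows", acq.grid_points))
    cols = int(header.get("cols", acq.grid_points))

    curves = [None] * (rows * cols)
    for (i, j), sub in df.groupby(["pixel_i", "pixel_j"], sort=True):
        i, j = int(i), int(j)
        if not (0 <= i < rows and 0 <= j < cols):
            raise FormatError(f"{path}: pixel ({i},{j}) outside {rows}x{cols}")
        z = sub["height_m"].to_numpy()
        dz = np.diff(z)
        if z.size >= 2 and not (np.all(dz < 0) or np.all(dz > 0)):
            raise FormatError(
                f"{path}: non-monotone height series at pixel ({i},{j})")
        try:
            curves[i * cols + j] = ForceDistanceCurve(
                height_m=z, deflection_V=sub["deflection_V"].to_numpy(),
                calibration=calib, pixel=(i, j))
        except ValueError as exc:
            raise FormatError(f"{path}: pixel ({i},{j}): {exc}") from exc
    missing = [k for k, c in enumerate(curves) if c is None]
    if missing:
        raise FormatError(f"{path}: {len(missing)} pixels have no curve data")
    return ForceMap(curves=curves, shape=(rows, cols), acquisition=acq,
                    calibration=calib)


# ---------------------------------------------------------------------------
# elasticity maps
# ---------------------------------------------------------------------------

def save_elasticity_map(emap: ElasticityMap, path) -> None:
    """TSV grid (NaN for invalid pixels) + JSON provenance sidecar."""
    path = Path(path)
    np.savetxt(path, emap.modulus_Pa, delimiter="\t", fmt="%.9e")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"provenance": emap.provenance,
                   "valid": emap.valid.astype(int).tolist()}, fh, indent=1)


def load_elasticity_map(path) -> ElasticityMap:
    path = Path(path)
    grid = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
        valid = np.asarray(meta["valid"], dtype=bool)
        prov = meta.get("provenance", {})
    else:
        valid = np.isfinite(grid)
        prov = {}
    return ElasticityMap(modulus_Pa=grid, valid=valid, provenance=prov)


# ---------------------------------------------------------------------------
# images and masks
# ---------------------------------------------------------------------------

def save_image(img: FluorImage, path) -> None:
    """Multi-page TIFF with pixel-size metadata (ImageJ-style resolution)."""
    path = Path(path)
    names = list(img.channels.keys())
    stack = np.stack([img.channels[n].astype(np.float32) for n in names])
    res = 1.0 / img.pixel_size_um
    tifffile.imwrite(path, stack, imagej=True, resolution=(res, res),
                     metadata={"unit": "um", "Labels": names,
                               "axes": "CYX"})


def load_image(path, pixel_size_um: Optional[float] = None,
               channel_names: Optional[list] = None) -> FluorImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        ps = None
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is not None:
            num, den = xres.value
            # (1, 1) is the writer default for uncalibrated rasters
            if num and (num, den) != (1, 1):
                ps = den / num
        labels = None
        if tif.imagej_metadata:
            labels = tif.imagej_metadata.get("Labels")
    if pixel_size_um is None:
        if ps is None:
            raise FormatError(
                f"{path}: no pixel-size metadata in TIFF; pass pixel size "
                "explicitly (--pixel-size)")
        pixel_size_um = ps
    if arr.ndim == 2:
        arr = arr[None]
    names = channel_names or labels or [f"ch{i}" for i in range(arr.shape[0])]
    channels = {str(n): arr[i].astype(float)
                for i, n in enumerate(names[:arr.shape[0]])}
    return FluorImage(channels=channels, pixel_size_um=float(pixel_size_um))


def save_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def save_ground_truth(truth, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh)
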