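"""File interfaces: NIfTI/MetaImage volumes, float TIFF images with JSON
sidecars, TOML configuration and CSV shift lists."""

from __future__ import annotations

import csv
import json
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .fluence import FluenceMap
from .geometry import AcquisitionGeometry, CouchShift, VolumeImage
from .preprocess import EPIDImage, ProjectionImage


def save_volume(volume: VolumeImage, path):
    """Write a VolumeImage as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    The affine/offset places voxel (0,0,0)'s center at origin + voxel/2."""
    path = Path(path)
    center0 = np.asarray(volume.origin) + np.asarray(volume.voxel_size) / 2.0
    if path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            volume.values.transpose(2, 1, 0)))
        img.SetSpacing(tuple(volume.voxel_size))
        img.SetOrigin(tuple(center0))
        sitk.WriteImage(img, str(path))
    else:
        affine = np.diag(list(volume.voxel_size) + [1.0])
        affine[:3, 3] = center0
        nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), path)
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"modality": volume.modality,
                   "voxel_size": list(volume.voxel_size),
                   "origin": list(volume.origin)}, fh)


def load_volume(path, modality: str | None = None) -> VolumeImage:
    path = Path(path)
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    if path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        vs = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin()) - vs / 2.0
    else:
        img = nib.load(path)
        values = np.asarray(img.dataobj, dtype=np.float64)
        aff = img.affine
        vs = np.diag(aff)[:3]
        origin = aff[:3, 3] - vs / 2.0
    return VolumeImage(values, tuple(vs), tuple(origin),
                       modality or meta.get("modality", "attenuation"))


def _save_image(values, path, meta):
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)


def _load_meta(path):
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def save_epid(image: EPIDImage, path):
    _save_image(image.values, path, {"pixel_pitch": image.pixel_pitch,
                                     "gantry_angle": image.gantry_angle})


def load_epid(path) -> EPIDImage:
    meta = _load_meta(path)
    return EPIDImage(tifffile.imread(path).astype(np.float64),
                     meta.get("pixel_pitch", 1.0), meta.get("gantry_angle", 0.0))


def save_projection(proj: ProjectionImage, path):
    _save_image(proj.values, path,
                {"pixel_pitch": proj.pixel_pitch, "gantry_angle": proj.gantry_angle,
                 "center_uv": list(proj.center_uv),
                 "crop_offset": list(proj.crop_offset)})


def load_projection(path) -> ProjectionImage:
    meta = _load_meta(path)
    return ProjectionImage(tifffile.imread(path).astype(np.float64),
                           meta.get("pixel_pitch", 1.0),
                           meta.get("gantry_angle", 0.0),
                           tuple(meta.get("center_uv", (0.0, 0.0))),
                           tuple(meta.get("crop_offset", (0, 0))))


def save_fluence(fl: FluenceMap, path):
    _save_image(fl.values, path, {"pixel_pitch": fl.pixel_pitch,
                                  "distance": fl.distance})


def load_fluence(path) -> FluenceMap:
    meta = _load_meta(path)
    return FluenceMap(tifffile.imread(path).astype(np.float64),
                      meta.get("pixel_pitch", 1.0), meta.get("distance", 1000.0))


def load_geometry(path) -> AcquisitionGeometry:
    """Acquisition geometry from a TOML table (keys mirror the dataclass)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "gantry_angles" in data:
        data["gantry_angles"] = tuple(float(a) for a in data["gantry_angles"])
    if "field_size" in data:
        data["field_size"] = tuple(float(v) for v in data["field_size"])
    return AcquisitionGeometry(**data)


def load_shift_list(path):
    """Couch shifts from CSV with columns sx_mm, sy_mm, sz_mm."""
    shifts = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            shifts.append(CouchShift(float(row["sx_mm"]), float(row["sy_mm"]),
                                     float(row.get("sz_mm", 0.0))))
    return shifts


def save_shift_list(shifts, path):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sx_mm", "sy_mm", "sz_mm"])
        for s in shifts:
            writer.writerow([s.sx, s.sy, s.sz])


def save_shift_report_csv(report: dict, path):
    """Shift-experiment rows as CSV mirroring the validation table layout."""
    cols = ["group", "matched_center_x", "matched_center_y",
            "derived_tx_mm", "derived_ty_mm", "gold_tx_mm", "gold_ty_mm",
            "error_tx_mm", "error_ty_mm", "mi_value", "failure"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in report["rows"]:
            if "failure" in row:
                writer.writerow([row["group"], "", "", "", "",
                                 row["gold_shift_mm"][0], row["gold_shift_mm"][1],
                                 "", "", "", row["failure"]])
            else:
                writer.writerow([
                    row["group"],
                    row["matched_center"][0], row["matched_center"][1],
                    row["derived_shift_mm"][0], row["derived_shift_mm"][1],
                    row["gold_shift_mm"][0], row["gold_shift_mm"][1],
                    row["error_mm"][0], row["error_mm"][1],
                    row["mi_value"], ""])
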