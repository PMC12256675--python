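"""NIfTI readers/writers, common-grid resampling and course manifests.

Volumes, masks and doses are 3D NIfTI images; displacement fields are 4D
NIfTI with a trailing component axis of size 3 (x, y, z displacement in mm,
fixed-grid frame).  Voxel spacing is carried in the header zooms and the
affine is the plain diagonal ``diag(spacing, 1)`` — axis order is (x, y, z)
with world coordinates ``index * spacing`` (no direction cosines in v1).
A course manifest is a JSON file listing each frame's files, role,
fractionation and mask paths, with exactly one frame flagged fixed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .grids import Course, DisplacementField, DoseGrid, Frame, Mask3D, Volume3D


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: Volume3D | Mask3D | DoseGrid, path) -> None:
    data = vol.data.astype(np.uint8) if isinstance(vol, Mask3D) else vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_field(field: DisplacementField, path) -> None:
    img = nib.Nifti1Image(field.u.astype(np.float32), _affine(field.spacing))
    img.header.set_zooms((*field.spacing, 1.0))
    nib.save(img, str(path))


def read_volume(path) -> Volume3D | DisplacementField:
    """Read a NIfTI file: 3D -> Volume3D, 4D with 3 components -> field."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    if data.ndim == 3:
        return Volume3D(data, tuple(float(z) for z in zooms[:3]))
    if data.ndim == 4 and data.shape[-1] == 3:
        return DisplacementField(data, tuple(float(z) for z in zooms[:3]))
    raise ValueError(
        f"{path}: expected a 3D volume or a 4D 3-component field, got shape {data.shape}"
    )


def read_mask(path, organ: str = "organ") -> Mask3D:
    vol = read_volume(path)
    if not isinstance(vol, Volume3D):
        raise ValueError(f"{path}: masks must be 3D")
    return Mask3D(vol.data > 0.5, vol.spacing, organ=organ)


def read_dose(path, kind: str = "physical_per_fraction", n_fractions: int = 1) -> DoseGrid:
    vol = read_volume(path)
    if not isinstance(vol, Volume3D):
        raise ValueError(f"{path}: doses must be 3D")
    return DoseGrid(np.maximum(vol.data, 0.0), vol.spacing, kind=kind, n_fractions=n_fractions)


def resample_to(vol: Volume3D | Mask3D | DoseGrid, shape, spacing, mode: str = "linear"):
    """Resample onto a target grid (same world origin); identity when the
    target grid equals the source grid."""
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    if any(n < 1 for n in shape) or any(s <= 0 for s in spacing):
        raise ValueError("invalid target grid")
    src_extent = [(n - 1) * s for n, s in zip(vol.data.shape, vol.spacing)]
    tgt_start = [0.0, 0.0, 0.0]
    if any(t > e + 1e-9 for t, e in zip(tgt_start, src_extent)):
        raise ValueError("target grid does not overlap the source grid")
    if shape == vol.data.shape and spacing == tuple(vol.spacing):
        out = vol.data.copy()
    else:
        axes = [np.arange(n) * s / vs for n, s, vs in zip(shape, spacing, vol.spacing)]
        coords = np.stack(np.meshgrid(*axes, indexing="ij"))
        order = 1 if mode == "linear" else 0
        out = map_coordinates(
            vol.data.astype(np.float64), coords, order=order, mode="nearest"
        )
    if isinstance(vol, Mask3D):
        return Mask3D(out > 0.5, spacing, organ=vol.organ)
    if isinstance(vol, DoseGrid):
        return DoseGrid(np.maximum(out, 0.0), spacing, kind=vol.kind, n_fractions=vol.n_fractions)
    return Volume3D(out, spacing, role=vol.role)


def write_course(course: Course, out_dir) -> Path:
    """Write every frame's files plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"frames": []}
    for i, frame in enumerate(course.frames):
        tag = f"frame{i:02d}_{frame.role}"
        entry = {
            "role": frame.role,
            "is_fixed": frame.is_fixed,
            "n_fractions": frame.n_fractions,
            "image": f"{tag}_image.nii.gz",
            "masks": {},
        }
        write_volume(frame.image, out_dir / entry["image"])
        for organ, mask in frame.masks.items():
            fname = f"{tag}_mask_{organ}.nii.gz"
            write_volume(mask, out_dir / fname)
            entry["masks"][organ] = fname
        if frame.dose is not None:
            fname = f"{tag}_dose.nii.gz"
            write_volume(frame.dose, out_dir / fname)
            entry["dose"] = fname
            entry["dose_kind"] = frame.dose.kind
        if frame.deformation is not None:
            fname = f"{tag}_truth_field.nii.gz"
            write_field(frame.deformation, out_dir / fname)
            entry["truth_field"] = fname
        manifest["frames"].append(entry)
    path = out_dir / "course.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_course(manifest_path) -> Course:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    frames = []
    for entry in manifest["frames"]:
        image_path = root / entry["image"]
        if not image_path.exists():
            raise FileNotFoundError(f"manifest references missing image {image_path}")
        image = read_volume(image_path)
        if not isinstance(image, Volume3D):
            raise ValueError(f"{image_path}: frame image must be 3D")
        masks = {}
        for organ, fname in entry.get("masks", {}).items():
            mpath = root / fname
            if not mpath.exists():
                raise FileNotFoundError(
                    f"frame {entry['role']!r}: missing mask file {mpath}"
                )
            masks[organ] = read_mask(mpath, organ=organ)
        dose = None
        if "dose" in entry:
            dose = read_dose(
                root / entry["dose"],
                kind=entry.get("dose_kind", "physical_per_fraction"),
                n_fractions=int(entry.get("n_fractions", 1)),
            )
        deformation = None
        if "truth_field" in entry:
            f = read_volume(root / entry["truth_field"])
            if isinstance(f, DisplacementField):
                deformation = f
        frames.append(
            Frame(
                role=entry["role"],
                image=image,
                masks=masks,
                dose=dose,
                n_fractions=int(entry.get("n_fractions", 1)),
                is_fixed=bool(entry.get("is_fixed", False)),
                deformation=deformation,
            )
        )
    return Course(frames)
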