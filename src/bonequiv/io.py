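"""File I/O: segmentation masks (NIfTI/MetaImage), meshes (PLY/STL).

Masks are binary 0/1 volumes whose header carries voxel spacing and origin
in mm; the in-memory array follows the package convention of axis order
``(x, y, z)``.  NIfTI files store exactly that order; MetaImage files are
transposed on the way in/out because SimpleITK's array view is ``(z, y, x)``.

PLY output is binary little-endian with an optional per-vertex float
``signed_distance`` channel and uchar ``red/green/blue``; trimesh's PLY
writer does not round-trip a custom float scalar channel, so a small
dedicated writer/reader lives here (round-trip tested).
"""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import trimesh

from .surface import VoxelGrid

__all__ = ["read_mask", "write_mask", "write_ply", "read_ply", "write_stl"]


def write_mask(grid: VoxelGrid, path) -> None:
    """Write a binary mask as .nii/.nii.gz or .mha, per the file suffix."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([*grid.spacing, 1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(grid.data.astype(np.uint8), affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(np.transpose(grid.data, (2, 1, 0)).astype(np.uint8))
        img.SetSpacing(tuple(grid.spacing))
        img.SetOrigin(tuple(grid.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def read_mask(path) -> VoxelGrid:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    return VoxelGrid((np.asarray(data) > 0.5).astype(np.uint8), spacing=spacing, origin=origin)


def write_stl(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


def write_ply(
    mesh: trimesh.Trimesh,
    path,
    scalar: np.ndarray | None = None,
    colors: np.ndarray | None = None,
    scalar_name: str = "signed_distance",
) -> None:
    """Binary little-endian PLY with optional per-vertex scalar and RGB."""
    v = np.asarray(mesh.vertices, dtype="<f4")
    f = np.asarray(mesh.faces, dtype="<i4")
    n = len(v)
    if scalar is not None:
        scalar = np.asarray(scalar, dtype="<f4")
        if scalar.shape != (n,):
            raise ValueError("scalar must have one value per vertex")
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8)
        if colors.shape != (n, 3):
            raise ValueError("colors must be (n_vertices, 3) uint8")

    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n}"]
    header += [f"property float {ax}" for ax in "xyz"]
    if scalar is not None:
        header.append(f"property float {scalar_name}")
    if colors is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header += [f"element face {len(f)}", "property list uchar int vertex_indices", "end_header"]

    fields = [("xyz", "<f4", (3,))]
    if scalar is not None:
        fields.append(("scalar", "<f4", ()))
    if colors is not None:
        fields.append(("rgb", "u1", (3,)))
    vdata = np.empty(n, dtype=np.dtype(fields))
    vdata["xyz"] = v
    if scalar is not None:
        vdata["scalar"] = scalar
    if colors is not None:
        vdata["rgb"] = colors

    fdata = np.empty(len(f), dtype=np.dtype([("count", "u1"), ("idx", "<i4", (3,))]))
    fdata["count"] = 3
    fdata["idx"] = f

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(vdata.tobytes())
        fh.write(fdata.tobytes())


def read_ply(path) -> tuple[trimesh.Trimesh, np.ndarray | None, np.ndarray | None]:
    """Read a PLY written by :func:`write_ply`.

    Returns ``(mesh, scalar, colors)`` with ``None`` for absent channels.
    """
    with open(path, "rb") as fh:
        props: list[tuple[str, str]] = []
        n_vert = n_face = 0
        element = ""
        while True:
            line = fh.readline().decode("ascii").strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
                element = "vertex"
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
                element = "face"
            elif line.startswith("property") and element == "vertex":
                _, typ, name = line.split()
                props.append((name, typ))
            elif line == "end_header":
                break
        typemap = {"float": "<f4", "uchar": "u1"}
        vdtype = np.dtype([(name, typemap[typ]) for name, typ in props])
        vdata = np.frombuffer(fh.read(n_vert * vdtype.itemsize), dtype=vdtype)
        fdtype = np.dtype([("count", "u1"), ("idx", "<i4", (3,))])
        fdata = np.frombuffer(fh.read(n_face * fdtype.itemsize), dtype=fdtype)

    verts = np.column_stack([vdata[ax].astype(float) for ax in "xyz"])
    mesh = trimesh.Trimesh(vertices=verts, faces=fdata["idx"].astype(int), process=False)
    names = [name for name, _ in props]
    scalar = None
    extra = [nm for nm in names if nm not in ("x", "y", "z", "red", "green", "blue")]
    if extra:
        scalar = vdata[extra[0]].astype(float)
    colors = None
    if "red" in names:
        colors = np.column_stack([vdata[c] for c in ("red", "green", "blue")])
    return mesh, scalar, colors
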