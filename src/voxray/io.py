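"""Volume and image readers/writers.

Volumes: NIfTI (``.nii`` / ``.nii.gz``, via nibabel), NRRD (``.nrrd``,
a self-contained reader/writer for attached raw- or ASCII-encoded
data), and a raw-grid JSON dialect (``.json``) convenient for small
text fixtures.  Grid spacing and origin map to the world bounding box;
the scalar range comes from the file when available, else from the
data min/max.

Images: 8-bit straight-alpha RGBA PNG, rounding half up.  Depth images
(camera-space distances, 0 = no geometry) load from ``.npy`` or
whitespace-separated text.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .rays import RenderedImage
from .volume import ScalarVolume

__all__ = [
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "write_image",
    "write_frames",
    "read_depth_image",
]


class VolumeIOError(ValueError):
    """A volume file could not be read or written."""


_NRRD_TYPES = {
    "float": "<f4", "double": "<f8",
    "short": "<i2", "signed short": "<i2", "unsigned short": "<u2",
    "int": "<i4", "signed int": "<i4", "unsigned int": "<u4",
    "uchar": "u1", "unsigned char": "u1", "char": "i1", "signed char": "i1",
}


def _bbox_from_spacing(origin: np.ndarray, spacing: np.ndarray,
                       dims) -> tuple[np.ndarray, np.ndarray]:
    extent = spacing * (np.asarray(dims, dtype=np.float64) - 1.0)
    return origin, origin + extent


def _check_3d(data: np.ndarray, path) -> None:
    if data.ndim != 3:
        raise VolumeIOError(
            f"{path}: expected a 3-D volume, got {data.ndim} dimensions "
            f"with shape {tuple(data.shape)}"
        )


def _read_nifti(path: Path) -> ScalarVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    data = np.squeeze(data)
    _check_3d(data, path)
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    spacing[spacing == 0] = 1.0
    origin = affine[:3, 3].astype(np.float64)
    return _build(data, origin, spacing, path)


def _build(data: np.ndarray, origin, spacing, path) -> ScalarVolume:
    lo, hi = float(data.min()), float(data.max())
    if not lo < hi:
        raise VolumeIOError(
            f"{path}: degenerate scalar range (all values equal {lo})"
        )
    bbox = _bbox_from_spacing(np.asarray(origin, dtype=np.float64),
                              np.asarray(spacing, dtype=np.float64), data.shape)
    return ScalarVolume(data, scalar_range=(lo, hi), bbox=bbox)


def _parse_nrrd_header(fh) -> dict:
    magic = fh.readline().decode("ascii", "replace").strip()
    if not magic.startswith("NRRD"):
        raise VolumeIOError(f"not an NRRD file (magic line {magic!r})")
    fields: dict[str, str] = {}
    while True:
        line = fh.readline()
        if line in (b"", b"\n", b"\r\n"):
            break
        text = line.decode("ascii", "replace").rstrip("\r\n")
        if text.startswith("#"):
            continue
        if ":" not in text:
            raise VolumeIOError(f"malformed NRRD header line {text!r}")
        key, _, val = text.partition(":")
        fields[key.strip().lower()] = val.lstrip("= ").strip()
    return fields


def _read_nrrd(path: Path) -> ScalarVolume:
    with open(path, "rb") as fh:
        fields = _parse_nrrd_header(fh)
        payload = fh.read()
    if int(fields.get("dimension", 0)) != 3:
        raise VolumeIOError(
            f"{path}: expected a 3-D volume, got dimension "
            f"{fields.get('dimension')}"
        )
    sizes = [int(s) for s in fields["sizes"].split()]
    tname = fields.get("type", "float")
    if tname not in _NRRD_TYPES:
        raise VolumeIOError(f"{path}: unsupported NRRD sample type '{tname}'")
    dtype = np.dtype(_NRRD_TYPES[tname])
    if fields.get("endian", "little") == "big" and dtype.itemsize > 1:
        dtype = dtype.newbyteorder(">")
    if "data file" in fields or "datafile" in fields:
        raise VolumeIOError(f"{path}: detached NRRD data files are not supported")
    encoding = fields.get("encoding", "raw")
    count = int(np.prod(sizes))
    if encoding == "raw":
        data = np.frombuffer(payload, dtype=dtype, count=count)
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(payload.split(), dtype=np.float64)
    else:
        raise VolumeIOError(f"{path}: unsupported NRRD encoding '{encoding}'")
    if data.size != count:
        raise VolumeIOError(
            f"{path}: expected {count} samples, found {data.size}"
        )
    # NRRD stores the first axis fastest
    data = data.astype(np.float64).reshape(sizes, order="F")

    spacing = np.ones(3)
    if "space directions" in fields:
        rows = [v for v in fields["space directions"].split(") ")
                if v.strip() not in ("none", "")]
        vecs = []
        for row in rows:
            vecs.append([float(x) for x in row.strip("() ").split(",")])
        mat = np.asarray(vecs, dtype=np.float64)
        spacing = np.linalg.norm(mat, axis=1)
    elif "spacings" in fields:
        spacing = np.array([float(s) if s != "nan" else 1.0
                            for s in fields["spacings"].split()])
    origin = np.zeros(3)
    if "space origin" in fields:
        origin = np.array([float(x) for x in
                           fields["space origin"].strip("() ").split(",")])
    return _build(data, origin, spacing, path)


def _write_nrrd(vol: ScalarVolume, path: Path) -> None:
    bmin, bmax = vol.bbox
    spacing = (bmax - bmin) / (np.asarray(vol.dims, dtype=np.float64) - 1.0)
    header = [
        "NRRD0004",
        "type: double",
        "dimension: 3",
        "sizes: {} {} {}".format(*vol.dims),
        "endian: little",
        "encoding: raw",
        "spacings: {} {} {}".format(*spacing),
        "space origin: ({},{},{})".format(*bmin),
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(vol.values.astype("<f8").tobytes(order="F"))


def _read_raw_json(path: Path) -> ScalarVolume:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        dims = tuple(doc["dims"])
        values = np.asarray(doc["values"], dtype=np.float64).reshape(dims)
    except (KeyError, ValueError) as e:
        raise VolumeIOError(f"{path}: malformed raw-grid volume: {e}") from e
    if len(dims) != 3:
        raise VolumeIOError(
            f"{path}: expected a 3-D volume, got {len(dims)} dimensions"
        )
    rng = doc.get("scalar_range")
    if rng is not None and not rng[0] < rng[1]:
        raise VolumeIOError(f"{path}: degenerate scalar range {rng}")
    bbox = doc.get("bbox")
    if bbox is not None:
        bbox = (np.asarray(bbox["min"], dtype=np.float64),
                np.asarray(bbox["max"], dtype=np.float64))
    if rng is None:
        lo, hi = float(values.min()), float(values.max())
        if not lo < hi:
            raise VolumeIOError(
                f"{path}: degenerate scalar range (all values equal {lo})"
            )
        rng = (lo, hi)
    return ScalarVolume(values, scalar_range=tuple(rng), bbox=bbox)


def read_volume(path) -> ScalarVolume:
    """Load a volume; the format is chosen by file extension."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"{path}: no such file")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    if name.endswith(".json"):
        return _read_raw_json(path)
    raise VolumeIOError(
        f"{path}: unsupported volume format '{path.suffix}' "
        "(expected .nii, .nii.gz, .nrrd or .json)"
    )


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a volume; the format is chosen by file extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        bmin, bmax = vol.bbox
        spacing = (bmax - bmin) / (np.asarray(vol.dims, dtype=np.float64) - 1.0)
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = bmin
        nib.save(nib.Nifti1Image(vol.values, affine), str(path))
    elif name.endswith(".nrrd"):
        _write_nrrd(vol, path)
    elif name.endswith(".json"):
        bmin, bmax = vol.bbox
        doc = {
            "dims": list(vol.dims),
            "scalar_range": list(vol.scalar_range),
            "bbox": {"min": bmin.tolist(), "max": bmax.tolist()},
            "values": vol.values.reshape(-1).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise VolumeIOError(
            f"{path}: unsupported volume format '{path.suffix}' "
            "(expected .nii, .nii.gz, .nrrd or .json)"
        )


def write_image(image: RenderedImage, path) -> None:
    """Write an RGBA PNG (8-bit, straight alpha, rounding half up)."""
    from PIL import Image

    arr = image.to_uint8()
    Image.fromarray(arr, mode="RGBA").save(str(path), format="PNG")


def write_frames(images, pattern) -> list[str]:
    """Write an animation as zero-padded PNG frames.

    ``pattern`` must contain a ``{frame}`` placeholder (or one is
    appended before the extension).  Returns the written paths.
    """
    pattern = str(pattern)
    if "{frame" not in pattern:
        root, ext = os.path.splitext(pattern)
        pattern = f"{root}_{{frame:04d}}{ext or '.png'}"
    paths = []
    for i, img in enumerate(images):
        p = pattern.format(frame=i)
        write_image(img, p)
        paths.append(p)
    return paths


def read_depth_image(path) -> np.ndarray:
    """Load a single-channel depth image (.npy or whitespace text)."""
    path = Path(path)
    if path.suffix == ".npy":
        depth = np.load(path)
    else:
        depth = np.loadtxt(path)
    depth = np.asarray(depth, dtype=np.float64)
    if depth.ndim != 2:
        raise VolumeIOError(f"{path}: depth image must be 2-D, got {depth.ndim}-D")
    return depth
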