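"""CT volume and landmark I/O with a single internal coordinate convention.

The package works in world millimetres throughout.  Axis semantics are fixed
at load time: ``x`` is the transverse (left-right) dimension, ``y`` the
anterior-posterior dimension and ``z`` the vertical (top-bottom) dimension.
Voxel indices are 0-based and ordered ``(x, y, z)``; ``world = origin +
index * spacing`` per axis.  Hounsfield values are clamped to
``[-1024, 4000]`` on load (air through dense enamel).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HU_MIN = -1024.0
HU_MAX = 4000.0

#: the craniofacial landmark vocabulary (16 clinical names, 5 bilateral)
#: plus the synthetic-phantom names.
KNOWN_LANDMARKS = frozenset(
    {
        "bregma",
        "nasion",
        "sella",
        "ans",
        "pogonion",
        "cfm",
        "r_iof",
        "l_iof",
        "r_porion",
        "l_porion",
        "r_mf",
        "l_mf",
        "r_orbitale",
        "l_orbitale",
        "r_f",
        "l_f",
        "proto_ans",
        "proto_sella",
        "proto_foramen",
    }
)


class VolumeLoadError(RuntimeError):
    """Raised when a CT volume cannot be read or violates preconditions."""


class LandmarkParseError(ValueError):
    """Raised for malformed landmark files; carries offending line numbers."""


@dataclass
class Volume:
    """A 3D scalar grid of HU values with world-space geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values indexed ``[ix, iy, iz]``.
    spacing : ndarray, shape (3,)
        Millimetres per voxel along (x, y, z); all components positive.
    origin : ndarray, shape (3,)
        World-mm position of voxel (0, 0, 0).
    mask : ndarray of bool or None
        Optional render mask; ``False`` voxels are treated as fully
        transparent (used by cutaway views).  HU values are untouched.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("all spacing components must be > 0")
        if self.mask is not None and self.mask.shape != self.voxels.shape:
            raise ValueError("mask shape must match voxel grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def world_min(self) -> np.ndarray:
        return self.origin.copy()

    @property
    def world_max(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) * self.spacing

    @property
    def world_center(self) -> np.ndarray:
        return 0.5 * (self.world_min + self.world_max)

    def contains(self, p) -> bool:
        """True if world-mm point ``p`` lies inside the voxel bounding box."""
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.world_min - 1e-9) and np.all(p <= self.world_max + 1e-9))


def world_to_voxel(v: Volume, p) -> np.ndarray:
    """Continuous voxel index of world-mm point ``p`` (no rounding)."""
    return (np.asarray(p, dtype=float) - v.origin) / v.spacing


def voxel_to_world(v: Volume, idx) -> np.ndarray:
    """World-mm position of (possibly fractional) voxel index ``idx``."""
    return v.origin + np.asarray(idx, dtype=float) * v.spacing


def load_volume(path, format: str | None = None) -> Volume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    The voxel grid is reordered to the internal (x, y, z) convention and HU
    values are clamped to ``[-1024, 4000]``.  DICOM rescale slope/intercept
    are applied so voxels are true HU.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such path: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error wrapping
        raise VolumeLoadError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise VolumeLoadError(f"expected 3D NIfTI, got shape {data.shape}")
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin = affine[:3, 3].astype(float)
    data = np.clip(data, HU_MIN, HU_MAX)
    return Volume(voxels=data, spacing=spacing, origin=origin)


def save_volume(v: Volume, path) -> None:
    """Write a Volume as NIfTI with a diagonal affine (spacing + origin)."""
    import nibabel as nib

    affine = np.diag([*v.spacing, 1.0])
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(v.voxels.astype(np.float32), affine), str(path))


def _load_dicom_series(path: Path) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ""} and p.is_file())
    if not files:
        raise VolumeLoadError(f"no DICOM files in {path}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise VolumeLoadError(f"cannot read DICOM slice {f}: {exc}") from exc
    orientations = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 6)) for s in slices}
    if len(orientations) != 1:
        raise VolumeLoadError("DICOM slices do not share one orientation")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    gaps = np.diff(zs)
    if len(gaps) == 0:
        raise VolumeLoadError("DICOM series needs at least two slices")
    if np.ptp(gaps) > 1e-3 * abs(gaps.mean()) + 1e-6:
        bad = int(np.argmax(np.abs(gaps - gaps.mean())))
        raise VolumeLoadError(
            f"non-uniform slice spacing: gap between slices {bad} and {bad + 1} "
            f"is {gaps[bad]:.4f} mm (expected {gaps.mean():.4f} mm)"
        )
    ps = np.asarray(slices[0].PixelSpacing, dtype=float)  # (row, col) mm
    arrs = []
    for s in slices:
        a = s.pixel_array.astype(np.float32)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        arrs.append(a * slope + intercept)
    # DICOM pixel_array is (row, col) = (y, x); stack along z then put (x,y,z)
    stack = np.stack(arrs, axis=-1)  # (row=y, col=x, z)
    data = np.transpose(stack, (1, 0, 2))
    data = np.clip(data, HU_MIN, HU_MAX)
    ipp = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    spacing = np.array([ps[1], ps[0], float(gaps.mean())])
    return Volume(voxels=data, spacing=spacing, origin=ipp)


@dataclass
class LandmarkSet:
    """Named world-mm landmark points with an optional Bookstein-type tag."""

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    types: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.entries.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return list(self.entries)

    def validate_against(self, volume: Volume) -> None:
        """Raise if any landmark lies outside the volume's bounding box."""
        for name, p in self.entries.items():
            if not volume.contains(p):
                raise ValueError(f"landmark {name!r} at {p} outside volume bounds")


def _warn_unknown(names) -> None:
    unknown = [n for n in names if n not in KNOWN_LANDMARKS]
    if unknown:
        warnings.warn(f"unknown landmark names accepted: {unknown}", stacklevel=3)


def load_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV (``name,x,y,z``) or JSON (``{name: [x,y,z]}``)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
        entries = {str(k): np.asarray(v, dtype=float) for k, v in raw.items()}
        bad = [k for k, v in entries.items() if v.shape != (3,)]
        if bad:
            raise LandmarkParseError(f"JSON entries without 3 coordinates: {bad}")
    else:
        entries = {}
        bad_lines = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts[:1] == ["name"]:
                continue  # header
            if len(parts) != 4:
                bad_lines.append(lineno)
                continue
            try:
                entries[parts[0]] = np.array([float(x) for x in parts[1:]])
            except ValueError:
                bad_lines.append(lineno)
        if bad_lines:
            raise LandmarkParseError(f"malformed landmark rows at lines {bad_lines}")
    _warn_unknown(entries)
    return LandmarkSet(entries=entries)


def save_landmarks(lm: LandmarkSet, path) -> None:
    """Write landmarks as CSV or JSON depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({k: [float(x) for x in v] for k, v in lm.entries.items()}, indent=1)
        )
    else:
        lines = ["name,x,y,z"]
        for k, v in lm.entries.items():
            lines.append(f"{k},{float(v[0])!r},{float(v[1])!r},{float(v[2])!r}")
        path.write_text("\n".join(lines) + "\n")
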