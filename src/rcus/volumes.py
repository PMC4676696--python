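"""Lattice containers and file I/O shared by every stage of the pipeline.

Conventions used throughout the package:

* Voxels are addressed 0-based as ``(ix, iy, iz)``; the physical position of
  a voxel center is ``origin + index * spacing`` (voxel-center convention).
* ``z`` is depth, increasing away from the transducer face at ``z = 0``.
* Intensity volumes carry a ``domain_tag``: ``"linear"`` for envelope/
  reflectivity amplitudes, ``"log"`` for log-compressed images (which may be
  negative).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger("rcus")

DOMAIN_TAGS = ("linear", "log")

#: Sentinel for voxels with no reading.  Never silently zero-filled: a zero
#: would be interpreted as a genuine black reading by the data term.
MISSING = np.nan


class VolumeIOError(IOError):
    """Raised on unreadable, unwritable, or inconsistent volume files."""


@dataclass(frozen=True)
class LatticeSpec:
    """Regular 3-D lattice: voxel counts, physical spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"lattice shape must be three counts >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"lattice spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_position(self, index) -> np.ndarray:
        """Map fractional voxel indices to physical positions (mm)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def position_to_index(self, position) -> np.ndarray:
        """Map physical positions (mm) to fractional voxel indices."""
        pos = np.asarray(position, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing), "origin": list(self.origin)}

    @classmethod
    def from_dict(cls, d: dict) -> "LatticeSpec":
        return cls(tuple(d["shape"]), tuple(d["spacing"]), tuple(d["origin"]))


@dataclass
class Volume3D:
    """Real-valued intensity field on a :class:`LatticeSpec`.

    ``values`` has shape ``lattice.shape`` indexed ``(ix, iy, iz)``.  NaN
    entries mark missing readings (see :data:`MISSING`); ``allow_missing``
    controls whether they are tolerated by validation.
    """

    lattice: LatticeSpec
    values: np.ndarray
    domain_tag: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.lattice.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != lattice shape {self.lattice.shape}"
            )
        if self.domain_tag not in DOMAIN_TAGS:
            raise ValueError(f"domain_tag must be one of {DOMAIN_TAGS}, got {self.domain_tag!r}")
        if np.any(np.isinf(self.values)):
            raise ValueError("volume contains non-finite (inf) values")

    def copy(self, values: np.ndarray | None = None, domain_tag: str | None = None) -> "Volume3D":
        return Volume3D(
            self.lattice,
            self.values.copy() if values is None else values,
            self.domain_tag if domain_tag is None else domain_tag,
        )

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SampleMask:
    """Boolean observation mask: True where a reading is available."""

    lattice: LatticeSpec
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != self.lattice.shape:
            raise ValueError(
                f"mask shape {self.observed.shape} != lattice shape {self.lattice.shape}"
            )
        if not self.observed.any():
            raise ValueError("sample mask has no observed voxels")

    @property
    def coverage(self) -> float:
        return float(self.observed.mean())


@dataclass
class ScattererField:
    """Point scatterers: positions in mm and dimensionless reflectivities."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=np.float64))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.float64))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=np.float64))
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=np.float64))
        n = len(self.x)
        if n == 0:
            raise ValueError("scatterer field is empty")
        if not (len(self.y) == len(self.z) == len(self.amplitude) == n):
            raise ValueError("scatterer coordinate arrays have mismatched lengths")
        for name in ("x", "y", "z", "amplitude"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in scatterer column {name!r}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) positions in mm."""
        return np.column_stack([self.x, self.y, self.z])


# ---------------------------------------------------------------------------
# Volume I/O.  NRRD and MetaImage go through SimpleITK; TIFF stacks through
# tifffile.  A JSON sidecar (path + ".json") carries domain_tag (and, for
# TIFF, spacing/origin, which the container cannot hold in mm).
# ---------------------------------------------------------------------------

_SITK_SUFFIXES = (".nrrd", ".nhdr", ".mhd", ".mha")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(vol: Volume3D, path, dtype: str = "float32") -> Path:
    """Write a volume to NRRD/MetaImage/TIFF with a JSON sidecar.

    Payload is little-endian float32 by default (lossless round-trip for
    float32 data), float64 on request.  Deterministic: the same volume
    serializes to identical bytes.
    """
    import SimpleITK as sitk

    path = Path(path)
    if path.suffix.lower() not in _SITK_SUFFIXES + _TIFF_SUFFIXES:
        raise VolumeIOError(f"unsupported volume format: {path.suffix!r}")
    if not path.parent.is_dir():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    if dtype not in ("float32", "float64"):
        raise ValueError("dtype must be 'float32' or 'float64'")
    payload = np.ascontiguousarray(vol.values.astype(dtype))

    sidecar = {"domain_tag": vol.domain_tag, "dtype": dtype}
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        # tifffile writes pages as the leading axis; store as (z, y, x)
        tifffile.imwrite(path, payload.transpose(2, 1, 0), photometric="minisblack")
        sidecar.update(vol.lattice.to_dict())
    else:
        img = sitk.GetImageFromArray(payload.transpose(2, 1, 0))  # sitk wants (z, y, x)
        img.SetSpacing(tuple(vol.lattice.spacing))
        img.SetOrigin(tuple(vol.lattice.origin))
        sitk.WriteImage(img, str(path), useCompression=False)
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    log.debug("wrote volume %s shape=%s dtype=%s", path, vol.values.shape, dtype)
    return path


def read_volume(path) -> Volume3D:
    """Read a volume written by :func:`write_volume`."""
    import SimpleITK as sitk

    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    domain_tag = sidecar.get("domain_tag", "linear")

    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        if "shape" not in sidecar:
            raise VolumeIOError(f"TIFF volume requires a JSON sidecar with lattice metadata: {path}")
        lattice = LatticeSpec.from_dict(sidecar)
        values = np.asarray(tifffile.imread(path))
        if values.ndim == 2:
            values = values[None]
        values = values.transpose(2, 1, 0)
    elif path.suffix.lower() in _SITK_SUFFIXES:
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        lattice = LatticeSpec(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    else:
        raise VolumeIOError(f"unsupported volume format: {path.suffix!r}")

    if tuple(values.shape) != tuple(lattice.shape):
        raise VolumeIOError(f"payload shape {values.shape} does not match metadata {lattice.shape}")
    return Volume3D(lattice, values.astype(np.float64), domain_tag)


def write_mask(mask: SampleMask, path) -> Path:
    """Store a sample mask as a 0/1 volume."""
    vol = Volume3D(mask.lattice, mask.observed.astype(np.float64), "linear")
    return write_volume(vol, path)


def read_mask(path) -> SampleMask:
    vol = read_volume(path)
    return SampleMask(vol.lattice, vol.values > 0.5)


# ---------------------------------------------------------------------------
# Scatterer CSV I/O
# ---------------------------------------------------------------------------

SCATTERER_COLUMNS = ("x_mm", "y_mm", "z_mm", "amplitude")


def write_scatterers(field: ScattererField, path) -> Path:
    path = Path(path)
    data = np.column_stack([field.x, field.y, field.z, field.amplitude])
    # %.17g preserves float64 exactly; round-trip is lossless
    np.savetxt(path, data, delimiter=",", header=",".join(SCATTERER_COLUMNS),
               comments="", fmt="%.17g")
    return path


def read_scatterers(path) -> ScattererField:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        raise VolumeIOError(f"empty scatterer file: {path}")
    names = [c.strip() for c in header.split(",")]
    missing = [c for c in SCATTERER_COLUMNS if c not in names]
    if missing:
        raise VolumeIOError(f"scatterer CSV missing columns {missing}: {path}")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise VolumeIOError(f"malformed scatterer CSV {path}: {exc}") from exc
    if data.size == 0:
        raise VolumeIOError(f"scatterer file has no records: {path}")
    cols = {name: data[:, i] for i, name in enumerate(names)}
    return ScattererField(cols["x_mm"], cols["y_mm"], cols["z_mm"], cols["amplitude"])


# ---------------------------------------------------------------------------
# Config helpers
# ---------------------------------------------------------------------------

def dataclass_to_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(obj), indent=1, sort_keys=True))
    return path


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
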