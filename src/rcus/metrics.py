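"""Image-quality metrics: MSE, PSNR, CoC, ENL and SNR.

PSNR = 10 log10(MAX(f_p)^2 / MSE) against the ideal image f_p; CoC is the
Pearson correlation of the images' discrete Laplacians (an edge-preservation
score: 1 for identical images, ~0 for uncorrelated ones); ENL = mu^2/sigma^2
of a homogeneous region (speckle smoothness; 1 for fully developed speckle
intensity); the ground-truth-free SNR is mu/sigma^2 over the whole image.

Conventions: population (1/n) variance for ENL and SNR; metrics against a
ground truth are computed on linear-domain images after both are normalized
to [0, 1] by the ideal image's peak.  Perfect matches and zero-variance
regions yield infinities, serialized as the string "inf" in reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import LatticeSpec, Volume3D


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, Volume3D) else np.asarray(v, dtype=float)


@dataclass
class RegionSpec:
    """Named region of interest: an index set, a box, or a sphere (mm)."""

    label: str
    kind: str = "box"                      # 'box' | 'sphere' | 'indices'
    box: tuple | None = None               # ((x0,x1),(y0,y1),(z0,z1)) mm
    center: tuple | None = None            # mm, for spheres
    radius: float | None = None            # mm
    indices: list | None = None            # [(ix,iy,iz), ...]

    def to_mask(self, lattice: LatticeSpec) -> np.ndarray:
        xs, ys, zs = (lattice.axis_coords(a) for a in range(3))
        if self.kind == "box":
            (x0, x1), (y0, y1), (z0, z1) = self.box
            m = ((xs >= x0) & (xs <= x1))[:, None, None] \
                & ((ys >= y0) & (ys <= y1))[None, :, None] \
                & ((zs >= z0) & (zs <= z1))[None, None, :]
        elif self.kind == "sphere":
            X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
            c = self.center
            m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= self.radius ** 2
        elif self.kind == "indices":
            m = np.zeros(lattice.shape, dtype=bool)
            idx = np.asarray(self.indices, dtype=int)
            m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not m.any():
            raise ValueError(f"region {self.label!r} is empty on this lattice")
        return m


def mse(f_p, f_r) -> float:
    """Mean squared error over all voxels."""
    a, b = _values(f_p), _values(f_r)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(f_p, f_r) -> float:
    """Peak signal-to-noise ratio (dB); MAX is the peak of the ideal image.

    Identical images give the perfect-match sentinel ``inf``.
    """
    m = mse(f_p, f_r)
    peak = float(_values(f_p).max())
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(peak ** 2 / m)


def _laplacian(a: np.ndarray) -> np.ndarray:
    # second-difference stencil (4-neighbor in 2-D, 6-neighbor in 3-D),
    # replicate padding; singleton axes contribute zero
    return ndimage.laplace(a, mode="nearest")


def coc(f_p, f_r) -> float:
    """Coefficient of correlation of the discrete Laplacians (edge preservation)."""
    a, b = _values(f_p), _values(f_r)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    la, lb = _laplacian(a).ravel(), _laplacian(b).ravel()
    la = la - la.mean()
    lb = lb - lb.mean()
    denom = math.sqrt(float(np.sum(la ** 2)) * float(np.sum(lb ** 2)))
    if denom == 0.0:
        raise ValueError("zero-variance Laplacian: CoC undefined")
    return float(np.sum(la * lb) / denom)


def enl(vol, region: RegionSpec | np.ndarray | None = None) -> float:
    """Effective number of looks mu^2 / sigma^2 of a region (population variance)."""
    a = _values(vol)
    if region is None:
        vals = a.ravel()
    elif isinstance(region, RegionSpec):
        vals = a[region.to_mask(vol.lattice)]
    else:
        vals = a[np.asarray(region, dtype=bool)]
    if vals.size < 2:
        raise ValueError("region needs at least 2 voxels")
    var = float(np.var(vals))
    if var == 0.0:
        return math.inf
    return float(np.mean(vals)) ** 2 / var


def snr_global(vol) -> float:
    """Ground-truth-free SNR: mean over population variance of all voxels.

    As defined (mu / sigma^2) this is neither shift- nor scale-invariant;
    report it on a fixed intensity scale.
    """
    a = _values(vol).ravel()
    if a.size < 2:
        raise ValueError("need at least 2 voxels")
    var = float(np.var(a))
    if var == 0.0:
        return math.inf
    return float(np.mean(a)) / var


@dataclass
class MetricsReport:
    """All applicable metrics for one reconstruction, JSON round-trippable."""

    psnr: float | None = None
    mse: float | None = None
    coc: float | None = None
    snr: float | None = None
    enl: dict[str, float] = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    @staticmethod
    def _encode(x):
        if x is None or isinstance(x, (str, dict)):
            return x
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        if math.isnan(x):
            return "nan"
        return x

    @staticmethod
    def _decode(x):
        if x in ("inf", "-inf", "nan"):
            return float(x)
        return x

    def to_dict(self) -> dict:
        return {
            "psnr": self._encode(self.psnr),
            "mse": self._encode(self.mse),
            "coc": self._encode(self.coc),
            "snr": self._encode(self.snr),
            "enl": {k: self._encode(v) for k, v in self.enl.items()},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            psnr=cls._decode(d.get("psnr")),
            mse=cls._decode(d.get("mse")),
            coc=cls._decode(d.get("coc")),
            snr=cls._decode(d.get("snr")),
            enl={k: cls._decode(v) for k, v in d.get("enl", {}).items()},
            provenance=d.get("provenance", {}),
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def read(cls, path) -> "MetricsReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate(f_p: Volume3D | None, f_r: Volume3D,
             regions: list[RegionSpec] | None = None,
             provenance: dict | None = None) -> MetricsReport:
    """Assemble all applicable metrics into one report.

    With a ground truth ``f_p``: PSNR, MSE, CoC (both images normalized to
    [0, 1] by the ideal image's peak) plus SNR/ENL of the normalized
    reconstruction.  Without ground truth (real-data mode): SNR and ENL of
    the raw reconstruction only.
    """
    report = MetricsReport(provenance=provenance or {})
    if f_p is not None:
        peak = float(_values(f_p).max())
        if peak <= 0:
            raise ValueError("ideal image peak must be positive")
        fp_n = _values(f_p) / peak
        fr_n = _values(f_r) / peak
        report.mse = mse(fp_n, fr_n)
        report.psnr = psnr(fp_n, fr_n)
        report.coc = coc(fp_n, fr_n)
        scored = Volume3D(f_r.lattice, fr_n, f_r.domain_tag)
    else:
        scored = f_r
    report.snr = snr_global(scored)
    for region in regions or []:
        report.enl[region.label] = enl(scored, region)
    return report
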