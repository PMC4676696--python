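"""Point-spread-function simulation for row-column apertures.

A row-column (RC) array wires an N x N 2-D transducer as N column electrodes
plus N row electrodes.  Columns transmit with electronic focusing in azimuth
(x); rows receive with focusing in elevation (y); the orthogonal dimension of
each aperture relies on natural (near-field) focusing only.  The result is a
two-way beam whose width grows with depth.

The acoustic model is the classical spatial impulse response of a rigid
baffled aperture: the field at point r1 due to an impulsive surface velocity
on the aperture S is

    h(r1, t) = \int_S delta(t - |r1 - r2| / c) / (2 pi |r1 - r2|) dS .

Each element is subdivided into sub-apertures small relative to the
wavelength; their arrival-time contributions are accumulated into a sampled
trace with linear two-bin interpolation of the Dirac delta.  Transmit and
receive responses, convolved with a Gaussian-modulated excitation pulse and
envelope-detected, give the two-way radiation pattern (the lateral PSF).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

from .volumes import LatticeSpec

log = logging.getLogger("rcus")

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class ApertureSpec:
    """Geometry and electrical parameters of one RC sub-aperture (rows or columns)."""

    n_elements: int = 32
    pitch: float = 0.15625           # mm, element-to-element
    element_width: float = 0.15625   # mm, across the element
    aperture_size: float = 5.0       # mm, element length (full array side)
    center_frequency: float = 5.9e6  # Hz
    fractional_bandwidth: float = 0.6
    sound_speed: float = 1540.0      # m/s
    sampling_rate: float = 100e6     # Hz
    orientation: str = "columns"     # columns: elements indexed along x; rows: along y
    focus_depth: float | None = None  # mm, None = unfocused

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if not (self.pitch >= self.element_width > 0):
            raise ValueError("need pitch >= element_width > 0")
        if self.sampling_rate < 4 * self.center_frequency:
            raise ValueError("sampling_rate must be >= 4 x center_frequency")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.orientation not in ("rows", "columns"):
            raise ValueError("orientation must be 'rows' or 'columns'")

    @property
    def wavelength(self) -> float:
        """Wavelength at the center frequency, in mm."""
        return self.sound_speed / self.center_frequency / MM

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def element_centers(self) -> np.ndarray:
        """(n, 3) element-center positions in mm, aperture centered at the origin."""
        u = (np.arange(self.n_elements) - (self.n_elements - 1) / 2.0) * self.pitch
        xyz = np.zeros((self.n_elements, 3))
        xyz[:, 0 if self.orientation == "columns" else 1] = u
        return xyz

    def focus_delays(self, focus_depth: float | None = None, focus_lateral: float = 0.0) -> np.ndarray:
        """Per-element transmit/receive delays (s) focusing at the given depth.

        Elements farther from the focal point fire earlier so that all
        arrivals align; delays are shifted to be non-negative.
        """
        zf = self.focus_depth if focus_depth is None else focus_depth
        if zf is None:
            return np.zeros(self.n_elements)
        centers = self.element_centers()
        ax = 0 if self.orientation == "columns" else 1
        focus = np.zeros(3)
        focus[ax] = focus_lateral
        focus[2] = zf
        dist = np.linalg.norm(centers - focus, axis=1)  # mm
        return (dist.max() - dist) * MM / self.sound_speed


@dataclass(frozen=True)
class FieldPoint:
    """Point in front of the aperture plane (z > 0), in mm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("field point must lie in front of the aperture (z > 0)")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class ImpulseTrace:
    """Sampled impulse response: samples[k] at time start_time + k * dt."""

    start_time: float
    dt: float
    samples: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(len(self.samples))

    @property
    def area(self) -> float:
        """Time integral of the trace."""
        return float(np.sum(self.samples) * self.dt)


@dataclass
class RadiationPattern:
    """Normalized two-way envelope-peak amplitude on a lateral grid at one depth."""

    depth: float            # mm
    xs: np.ndarray          # mm
    ys: np.ndarray          # mm
    amplitude: np.ndarray   # (len(xs), len(ys)), peak = 1

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        peak = self.amplitude.max()
        if peak <= 0:
            raise ValueError("radiation pattern has no positive amplitude")
        self.amplitude = self.amplitude / peak


@dataclass
class PSFKernel:
    """Discrete PSF kernel on the reconstruction lattice spacing, unit sum.

    2-D kernels are (x, z) for slice-wise processing; 3-D kernels (x, y, z).
    The last axis is always depth.
    """

    values: np.ndarray
    depth_band: tuple[float, float]   # (z_min, z_max) mm
    spacing: tuple[float, ...]        # mm per kernel axis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        s = self.values.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("kernel must have positive finite mass")
        self.values = self.values / s

    @property
    def center_depth(self) -> float:
        return 0.5 * (self.depth_band[0] + self.depth_band[1])

    @property
    def ndim(self) -> int:
        return self.values.ndim


@dataclass
class PSFBank:
    """Depth-banded PSF kernels tiling a contiguous imaging range."""

    kernels: list[PSFKernel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("PSF bank needs at least one kernel")
        self.kernels = sorted(self.kernels, key=lambda k: k.center_depth)
        for a, b in zip(self.kernels, self.kernels[1:]):
            if not np.isclose(a.depth_band[1], b.depth_band[0]):
                raise ValueError("depth bands must tile the range with no gaps")

    @property
    def z_range(self) -> tuple[float, float]:
        return (self.kernels[0].depth_band[0], self.kernels[-1].depth_band[1])

    @property
    def band_centers(self) -> np.ndarray:
        return np.array([k.center_depth for k in self.kernels])

    def kernel_for_depth(self, z: float) -> PSFKernel:
        for k in self.kernels:
            if k.depth_band[0] <= z <= k.depth_band[1]:
                return k
        return self.kernels[0] if z < self.z_range[0] else self.kernels[-1]

    def band_weights(self, zs: np.ndarray) -> np.ndarray:
        """(n_bands, len(zs)) linear blending weights.

        Hat functions centered on band centers; constant beyond the outermost
        centers.  Rows sum to 1 at every depth (partition of unity), which
        makes the blended system operator exactly linear with a clean adjoint.
        """
        zs = np.asarray(zs, dtype=float)
        centers = self.band_centers
        n = len(centers)
        w = np.zeros((n, len(zs)))
        if n == 1:
            w[0] = 1.0
            return w
        idx = np.clip(np.searchsorted(centers, zs) - 1, 0, n - 2)
        z0, z1 = centers[idx], centers[idx + 1]
        t = np.clip((zs - z0) / (z1 - z0), 0.0, 1.0)
        cols = np.arange(len(zs))
        w[idx, cols] = 1.0 - t
        w[idx + 1, cols] += t
        return w


# ---------------------------------------------------------------------------
# Spatial impulse response
# ---------------------------------------------------------------------------

def _subapertures(aperture: ApertureSpec, active: np.ndarray | None, sub_size: float | None):
    """Sub-aperture centers (mm), areas (mm^2) and owning-element index.

    Each rectangular element is split into sub-rectangles no larger than
    ``sub_size`` (default: half a wavelength) on a side.
    """
    if sub_size is None:
        sub_size = aperture.wavelength / 2.0
    centers = aperture.element_centers()
    if active is None:
        active = np.arange(aperture.n_elements)
    active = np.asarray(active, dtype=int)

    w, length = aperture.element_width, aperture.aperture_size
    nw = max(1, int(np.ceil(w / sub_size)))
    nl = max(1, int(np.ceil(length / sub_size)))
    du = (np.arange(nw) + 0.5) / nw * w - w / 2.0       # across the element
    dv = (np.arange(nl) + 0.5) / nl * length - length / 2.0  # along the element
    area = (w / nw) * (length / nl)

    across = 0 if aperture.orientation == "columns" else 1
    along = 1 - across
    uu, vv = np.meshgrid(du, dv, indexing="ij")
    offs = np.zeros((nw * nl, 3))
    offs[:, across] = uu.ravel()
    offs[:, along] = vv.ravel()

    pos = (centers[active][:, None, :] + offs[None, :, :]).reshape(-1, 3)
    elem = np.repeat(active, nw * nl)
    return pos, area, elem


def spatial_impulse_response(
    aperture: ApertureSpec,
    point: FieldPoint,
    active_elements: np.ndarray | None = None,
    delays: np.ndarray | None = None,
    sub_size: float | None = None,
    start_time: float | None = None,
    n_samples: int | None = None,
) -> ImpulseTrace:
    """Discrete spatial impulse response of the aperture at one field point.

    Arrival times of sub-aperture contributions (with per-element focusing
    delays applied) are accumulated into bins of width ``1/sampling_rate``
    using linear two-bin interpolation; amplitudes follow 1/(2 pi R)
    spreading, weighted by sub-aperture area.  Pass ``start_time`` and
    ``n_samples`` to force a common time base across calls.
    """
    pos, area, elem = _subapertures(aperture, active_elements, sub_size)
    if delays is None:
        delays = np.zeros(aperture.n_elements)
    delays = np.asarray(delays, dtype=float)
    if not np.all(np.isfinite(delays)):
        raise ValueError("delays must be finite")

    r = np.linalg.norm(pos - point.xyz[None, :], axis=1)  # mm
    if np.any(r < 1e-9):
        raise ValueError("field point coincides with a sub-aperture (singular 1/R)")
    t = r * MM / aperture.sound_speed + delays[elem]
    amp = area / (2.0 * np.pi * r)

    dt = aperture.dt
    if start_time is None:
        start_time = np.floor(t.min() / dt) * dt - 2 * dt
    if n_samples is None:
        n_samples = int(np.ceil((t.max() - start_time) / dt)) + 3

    u = (t - start_time) / dt
    k = np.floor(u).astype(int)
    frac = u - k
    ok = (k >= 0) & (k + 1 < n_samples)
    samples = np.bincount(k[ok], weights=amp[ok] * (1 - frac[ok]), minlength=n_samples)
    samples += np.bincount(k[ok] + 1, weights=amp[ok] * frac[ok], minlength=n_samples)
    return ImpulseTrace(start_time, dt, samples / dt)


def excitation_pulse(aperture: ApertureSpec, analytic: bool = True) -> ImpulseTrace:
    """Gaussian-modulated sinusoid at the center frequency.

    With ``analytic=True`` the in-phase and quadrature components are packed
    into a complex trace, so that envelope detection downstream is a plain
    magnitude (the convolution of an analytic pulse with real impulse
    responses stays analytic).
    """
    fc, bw, dt = aperture.center_frequency, aperture.fractional_bandwidth, aperture.dt
    tc = signal.gausspulse("cutoff", fc=fc, bw=bw, tpr=-60)
    t = np.arange(-tc, tc + dt / 2, dt)
    i, q = signal.gausspulse(t, fc=fc, bw=bw, retquad=True)
    samples = i + 1j * q if analytic else i
    return ImpulseTrace(-tc, dt, samples)


def convolve_traces(a: ImpulseTrace, b: ImpulseTrace) -> ImpulseTrace:
    if not np.isclose(a.dt, b.dt):
        raise ValueError("traces must share a sampling interval")
    samples = np.convolve(a.samples, b.samples) * a.dt
    return ImpulseTrace(a.start_time + b.start_time, a.dt, samples)


def pulse_echo_trace(
    tx: ApertureSpec,
    rx: ApertureSpec,
    point: FieldPoint,
    tx_delays: np.ndarray | None = None,
    rx_delays: np.ndarray | None = None,
    sub_size: float | None = None,
    pulse: ImpulseTrace | None = None,
) -> ImpulseTrace:
    """Two-way (transmit * excitation * receive) analytic trace at one point."""
    h_tx = spatial_impulse_response(tx, point, delays=tx_delays, sub_size=sub_size)
    h_rx = spatial_impulse_response(rx, point, delays=rx_delays, sub_size=sub_size)
    if pulse is None:
        pulse = excitation_pulse(tx)
    return convolve_traces(convolve_traces(h_tx, pulse), h_rx)


# ---------------------------------------------------------------------------
# Two-way radiation pattern
# ---------------------------------------------------------------------------

def two_way_pattern(
    tx: ApertureSpec,
    rx: ApertureSpec,
    depth: float,
    half_extent: float = 3.0,
    step: float | None = None,
    sub_size: float | None = None,
    use_symmetry: bool = True,
) -> RadiationPattern:
    """Two-way radiation pattern at one depth.

    The transmit (column) aperture is focused in azimuth and the receive
    (row) aperture in elevation, both at ``depth`` unless the spec carries
    its own ``focus_depth``.  For each lateral grid point, the transmit
    impulse response excited by a Gaussian pulse is convolved with the
    receive impulse response; the envelope peak over time is the pattern
    value.  Normalized to peak 1.

    ``use_symmetry`` computes one quadrant and mirrors it — exact for the
    centered, symmetric element layouts produced by :class:`ApertureSpec`.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    lam = tx.wavelength
    if step is None:
        step = lam / 4.0
    if step > lam / 4.0 + 1e-12:
        log.warning("pattern grid step %.3g mm coarser than lambda/4 = %.3g mm", step, lam / 4)

    tx_delays = tx.focus_delays(depth if tx.focus_depth is None else None)
    rx_delays = rx.focus_delays(depth if rx.focus_depth is None else None)
    pulse = excitation_pulse(tx)

    n = int(np.ceil(half_extent / step))
    half = step * np.arange(n + 1)
    xs = np.concatenate([-half[:0:-1], half])
    ys = xs.copy()

    sub_tx = _subapertures(tx, None, sub_size)
    sub_rx = _subapertures(rx, None, sub_size)

    def point_amp(x: float, y: float) -> float:
        tr = _fast_two_way(sub_tx, sub_rx, tx, rx, tx_delays, rx_delays, pulse, x, y, depth)
        return float(np.abs(tr).max())

    if use_symmetry:
        quad = np.empty((n + 1, n + 1))
        for i, x in enumerate(half):
            for j, y in enumerate(half):
                quad[i, j] = point_amp(x, y)
        amp = np.empty((2 * n + 1, 2 * n + 1))
        amp[n:, n:] = quad
        amp[:n, n:] = quad[:0:-1, :]
        amp[:, :n] = amp[:, :n:-1]
    else:
        amp = np.empty((len(xs), len(ys)))
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                amp[i, j] = point_amp(x, y)
    return RadiationPattern(depth, xs, ys, amp)


def _fast_two_way(sub_tx, sub_rx, tx, rx, tx_delays, rx_delays, pulse, x, y, z):
    """Complex two-way trace at one point, reusing precomputed sub-apertures."""
    p = np.array([x, y, z])
    out = None
    for (pos, area, elem), ap, delays in ((sub_tx, tx, tx_delays), (sub_rx, rx, rx_delays)):
        r = np.linalg.norm(pos - p[None, :], axis=1)
        t = r * MM / ap.sound_speed + delays[elem]
        amp = area / (2.0 * np.pi * r)
        dt = ap.dt
        t0 = np.floor(t.min() / dt) * dt - 2 * dt
        nsamp = int(np.ceil((t.max() - t0) / dt)) + 3
        u = (t - t0) / dt
        k = np.floor(u).astype(int)
        frac = u - k
        h = np.bincount(k, weights=amp * (1 - frac), minlength=nsamp)
        h += np.bincount(k + 1, weights=amp * frac, minlength=nsamp)
        out = h if out is None else np.convolve(out, h)
    return np.convolve(out, pulse.samples)


# ---------------------------------------------------------------------------
# Pattern characterization
# ---------------------------------------------------------------------------

def _axis_width(coords: np.ndarray, profile: np.ndarray, level_db: float) -> float:
    """Full width of the connected region around the profile peak above level_db."""
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.maximum(profile, 0) / profile.max())
    ipk = int(np.argmax(profile))
    if db[ipk] < level_db:
        raise ValueError("peak below requested level")
    # walk left
    i = ipk
    while i > 0 and db[i - 1] >= level_db:
        i -= 1
    if i == 0 and db[0] >= level_db:
        raise ValueError(f"{level_db} dB level never crossed inside the grid (left)")
    lo = np.interp(level_db, [db[i - 1], db[i]], [coords[i - 1], coords[i]])
    j = ipk
    while j < len(db) - 1 and db[j + 1] >= level_db:
        j += 1
    if j == len(db) - 1 and db[-1] >= level_db:
        raise ValueError(f"{level_db} dB level never crossed inside the grid (right)")
    hi = np.interp(level_db, [db[j + 1], db[j]], [coords[j + 1], coords[j]])
    return float(hi - lo)


def resolution_at_level(pattern: RadiationPattern, level_db: float = -6.0) -> float:
    """Lateral width (mm) of the main lobe at ``level_db`` below the peak.

    Measured along both grid axes through the peak; the wider of the two is
    returned (the wider-principal-axis convention).  Sub-grid resolution via
    linear interpolation of the dB profile crossing.
    """
    if level_db > 0:
        raise ValueError("level_db must be <= 0")
    if level_db == 0:
        return 0.0
    amp = pattern.amplitude
    ix, iy = np.unravel_index(np.argmax(amp), amp.shape)
    widths = []
    if amp.shape[0] > 1:
        widths.append(_axis_width(pattern.xs, amp[:, iy], level_db))
    if amp.shape[1] > 1:
        widths.append(_axis_width(pattern.ys, amp[ix, :], level_db))
    if not widths:
        raise ValueError("pattern grid is degenerate")
    return max(widths)


def peak_sidelobe_level(pattern: RadiationPattern, mainlobe_db: float = -6.0) -> float:
    """Highest local maximum (dB re. peak) outside the main lobe.

    The main lobe is the connected region above ``mainlobe_db`` containing
    the peak; the -6 dB (resolution) core is used so that broadband
    patterns whose filled nulls bridge the first side lobe to the skirt do
    not hide it.  Returns ``-inf`` when no local maximum exists outside.
    """
    amp = pattern.amplitude
    labels, _ = ndimage.label(amp >= 10 ** (mainlobe_db / 20.0))
    peak_idx = np.unravel_index(np.argmax(amp), amp.shape)
    main = labels == labels[peak_idx]
    # local maxima: strict plateau maxima of the amplitude field
    footprint = np.ones((3,) * amp.ndim, dtype=bool)
    local_max = (ndimage.maximum_filter(amp, footprint=footprint, mode="nearest") == amp)
    cand = local_max & ~main & (amp > 0)
    if not cand.any():
        return -np.inf
    return float(20.0 * np.log10(amp[cand].max()))


# ---------------------------------------------------------------------------
# Kernel packaging
# ---------------------------------------------------------------------------

def axial_envelope(
    tx: ApertureSpec,
    rx: ApertureSpec,
    depth: float,
    dz: float,
    sub_size: float | None = None,
    truncate_db: float = -40.0,
) -> np.ndarray:
    """Axial (depth) envelope of the on-axis two-way pulse, sampled at dz (mm).

    Time maps to depth as z = c t / 2 (pulse-echo).  Truncated at
    ``truncate_db`` re. the envelope peak.
    """
    tx_delays = tx.focus_delays(depth if tx.focus_depth is None else None)
    rx_delays = rx.focus_delays(depth if rx.focus_depth is None else None)
    tr = pulse_echo_trace(tx, rx, FieldPoint(0.0, 0.0, depth),
                          tx_delays, rx_delays, sub_size=sub_size)
    env = np.abs(tr.samples)
    z = (tr.times - tr.times[np.argmax(env)]) * tx.sound_speed / 2.0 / MM  # mm
    zq = np.arange(z.min(), z.max() + dz / 2, dz)
    prof = np.interp(zq, z, env)
    keep = prof >= prof.max() * 10 ** (truncate_db / 20.0)
    i0, i1 = np.argmax(keep), len(keep) - np.argmax(keep[::-1])
    return prof[i0:i1]


def psf_kernel_at_depth(
    tx: ApertureSpec,
    rx: ApertureSpec,
    depth: float,
    lattice: LatticeSpec,
    depth_band: tuple[float, float] | None = None,
    ndim: int = 2,
    pattern: RadiationPattern | None = None,
    truncate_db: float = -40.0,
    **pattern_kw,
) -> PSFKernel:
    """Discrete PSF kernel at one depth, on the reconstruction lattice spacing.

    The lateral two-way pattern is resampled to the lattice spacing and
    combined (outer product) with the axial envelope of the two-way pulse,
    truncated at ``truncate_db`` support and normalized to unit sum.  2-D
    kernels are (x, z) cuts through the pattern peak for slice-wise use.
    """
    dx, dy, dz = lattice.spacing
    if pattern is None:
        pattern = two_way_pattern(tx, rx, depth, **pattern_kw)
    width6 = resolution_at_level(pattern, -6.0)
    if dx > width6:
        raise ValueError(
            f"lattice spacing {dx} mm is coarser than the -6 dB width {width6:.3g} mm"
        )
    floor = 10 ** (truncate_db / 20.0)

    def lateral_profile(coords, prof, step):
        q = np.arange(0.0, coords.max() + step / 2, step)
        q = np.concatenate([-q[:0:-1], q])
        p = np.interp(q, coords, prof)
        keep = p >= p.max() * floor
        i0, i1 = np.argmax(keep), len(keep) - np.argmax(keep[::-1])
        return p[i0:i1]

    amp = pattern.amplitude
    ix, iy = np.unravel_index(np.argmax(amp), amp.shape)
    ax = axial_envelope(tx, rx, depth, dz, truncate_db=truncate_db)
    if depth_band is None:
        depth_band = (depth, depth)
    if ndim == 2:
        lat = lateral_profile(pattern.xs, amp[:, iy], dx)
        values = np.outer(lat, ax)
        spacing = (dx, dz)
    elif ndim == 3:
        latx = lateral_profile(pattern.xs, amp[:, iy], dx)
        laty = lateral_profile(pattern.ys, amp[ix, :], dy)
        values = latx[:, None, None] * laty[None, :, None] * ax[None, None, :]
        spacing = (dx, dy, dz)
    else:
        raise ValueError("ndim must be 2 or 3")
    values = np.where(values >= values.max() * floor, values, 0.0)
    return PSFKernel(values, depth_band, spacing)


def build_psf_bank(
    tx: ApertureSpec,
    rx: ApertureSpec,
    z_range: tuple[float, float],
    n_bands: int,
    lattice: LatticeSpec,
    **kernel_kw,
) -> PSFBank:
    """PSF bank with ``n_bands`` uniform depth bands over ``z_range``.

    Kernels are computed at each band's center depth.
    """
    z0, z1 = z_range
    if not (z1 > z0):
        raise ValueError("empty depth range")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    edges = np.linspace(z0, z1, n_bands + 1)
    kernels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        center = 0.5 * (lo + hi)
        kernels.append(
            psf_kernel_at_depth(tx, rx, center, lattice, depth_band=(lo, hi), **kernel_kw)
        )
    return PSFBank(kernels)


def gaussian_psf_bank(
    z_range: tuple[float, float],
    n_bands: int,
    lateral_fwhm: float | list[float],
    axial_fwhm: float,
    lattice: LatticeSpec,
    ndim: int = 2,
    truncate_db: float = -40.0,
) -> PSFBank:
    """Analytic separable-Gaussian PSF bank.

    A controlled stand-in for the simulated bank: lateral full-width at half
    maximum per band (scalar or one value per band, mm) and a common axial
    FWHM.  Used where tests need an exactly known, cheap, depth-varying
    system operator.
    """
    z0, z1 = z_range
    if not (z1 > z0 and n_bands >= 1):
        raise ValueError("invalid range/band count")
    fwhms = np.broadcast_to(np.atleast_1d(lateral_fwhm).astype(float), (n_bands,))
    edges = np.linspace(z0, z1, n_bands + 1)
    dx, dy, dz = lattice.spacing
    floor = 10 ** (truncate_db / 20.0)

    def prof(fwhm, step):
        sig = fwhm / (2 * np.sqrt(2 * np.log(2)))
        half = sig * np.sqrt(-2 * np.log(floor))
        u = np.arange(0, half + step, step)
        u = np.concatenate([-u[:0:-1], u])
        return np.exp(-(u ** 2) / (2 * sig ** 2))

    kernels = []
    for (lo, hi), fw in zip(zip(edges[:-1], edges[1:]), fwhms):
        ax = prof(axial_fwhm, dz)
        if ndim == 2:
            values = np.outer(prof(fw, dx), ax)
            spacing = (dx, dz)
        else:
            values = prof(fw, dx)[:, None, None] * prof(fw, dy)[None, :, None] * ax[None, None, :]
            spacing = (dx, dy, dz)
        kernels.append(PSFKernel(values, (lo, hi), spacing))
    return PSFBank(kernels)


# ---------------------------------------------------------------------------
# Bank serialization: one NRRD per band + JSON index
# ---------------------------------------------------------------------------

def write_psf_bank(bank: PSFBank, directory) -> Path:
    from .volumes import Volume3D, write_volume

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {"bands": []}
    for i, k in enumerate(bank.kernels):
        vals = k.values if k.ndim == 3 else k.values[:, None, :]
        spacing = k.spacing if k.ndim == 3 else (k.spacing[0], 1.0, k.spacing[1])
        name = f"band_{i:03d}.nrrd"
        write_volume(Volume3D(LatticeSpec(vals.shape, spacing), vals, "linear"),
                     directory / name, dtype="float64")
        index["bands"].append(
            {"file": name, "depth_band": list(k.depth_band), "ndim": k.ndim,
             "spacing": list(k.spacing)}
        )
    (directory / "index.json").write_text(json.dumps(index, indent=1))
    return directory


def read_psf_bank(directory) -> PSFBank:
    from .volumes import read_volume

    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    kernels = []
    for b in index["bands"]:
        vol = read_volume(directory / b["file"])
        vals = vol.values if b["ndim"] == 3 else vol.values[:, 0, :]
        kernels.append(PSFKernel(vals, tuple(b["depth_band"]), tuple(b["spacing"])))
    return PSFBank(kernels)


def rc_aperture_pair(
    n_elements: int = 32,
    aperture_size: float = 5.0,
    center_frequency: float = 5.9e6,
    **kw,
) -> tuple[ApertureSpec, ApertureSpec]:
    """Transmit-column / receive-row aperture pair for a square RC array.

    Two presets matter in practice: the simulated 5 mm x 5 mm, 32 x 32 array
    (the default) and the physical 4.8 mm, 150 um-pitch probe
    (``aperture_size=4.8``); neither is privileged.
    """
    pitch = aperture_size / n_elements
    common = dict(
        n_elements=n_elements, pitch=pitch, element_width=pitch,
        aperture_size=aperture_size, center_frequency=center_frequency, **kw,
    )
    return (
        ApertureSpec(orientation="columns", **common),
        ApertureSpec(orientation="rows", **common),
    )
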