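"""Synthetic acquisition: phantoms, the degradation model, and RF beamforming.

The forward model observed by a row-column scanner is

    g(x,y,z) = M(x,y,z) [ f(x,y,z) * h(x,y,z) u_m(x,y,z) + u_a(x,y,z) ]

where f is the tissue reflectivity, h the depth-dependent PSF (realized here
as a bank of depth-banded kernels blended linearly across band boundaries),
u_m multiplicative speckle following a generalized-gamma amplitude law
(Rayleigh by default), u_a additive sensor noise (negligible, default 0),
and M the sparse fan-beam sampling function.  Unobserved voxels carry NaN,
never zero: absence of a reading is not a black reading.

An optional RF-level path (``simulate_rf`` + ``das_beamform``) produces
delay-and-sum beamformed envelope lines from per-element traces, used to
cross-validate the convolution path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import griddata
from scipy.special import gamma as gamma_fn

from .psf import MM, ApertureSpec, PSFBank, excitation_pulse, spatial_impulse_response
from .volumes import MISSING, LatticeSpec, SampleMask, ScattererField, Volume3D

log = logging.getLogger("rcus")


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CystSpec:
    center: tuple[float, float, float]   # mm
    diameter: float                      # mm
    amplitude_ratio: float = 10.0        # scatterer amplitude x ratio inside


@dataclass(frozen=True)
class WireSpec:
    axis: str                            # 'x', 'y' or 'z': cylinder direction
    center: tuple[float, float, float]   # mm, a point on the wire axis
    diameter_um: float                   # micrometers
    amplitude_ratio: float = 10.0


@dataclass
class PhantomSpec:
    """Scatterer phantom: bounds box (mm), cysts/wires, density, amplitudes."""

    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    cysts: list[CystSpec] = field(default_factory=list)
    wires: list[WireSpec] = field(default_factory=list)
    scatterer_density: float = 5.0       # per mm^3
    background_amplitude_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scatterer_density <= 0:
            raise ValueError("scatterer_density must be positive")
        for c in self.cysts:
            if c.diameter <= 0:
                raise ValueError("cyst diameter must be positive")
        for w in self.wires:
            if w.diameter_um <= 0:
                raise ValueError("wire diameter must be positive")

    @property
    def volume(self) -> float:
        return math.prod(hi - lo for lo, hi in self.bounds)


def _inside_cyst(pos: np.ndarray, cyst: CystSpec) -> np.ndarray:
    d = pos - np.asarray(cyst.center)
    return np.einsum("ij,ij->i", d, d) <= (cyst.diameter / 2.0) ** 2


def _inside_wire(pos: np.ndarray, wire: WireSpec) -> np.ndarray:
    ax = "xyz".index(wire.axis)
    keep = [i for i in range(3) if i != ax]
    d = pos[:, keep] - np.asarray(wire.center)[keep]
    return np.einsum("ij,ij->i", d, d) <= (wire.diameter_um / 2000.0) ** 2


def generate_scatterers(spec: PhantomSpec) -> ScattererField:
    """Uniform random scatterers with Gaussian amplitudes.

    Amplitudes inside a cyst (or wire) are multiplied by its amplitude
    ratio (default 10).  Wires are additionally densified (10x the base
    density inside the cylinder) so that sub-resolution cylinders remain
    visible.  Deterministic under the spec's seed.
    """
    if spec.volume <= 0:
        raise ValueError("phantom bounds enclose zero volume")
    rng = np.random.default_rng(spec.seed)
    log.debug("generate_scatterers seed=%d", spec.seed)
    n = rng.poisson(spec.scatterer_density * spec.volume)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    pos = rng.uniform(lo, hi, size=(n, 3))
    amp = rng.normal(0.0, spec.background_amplitude_sd, size=n)

    for cyst in spec.cysts:
        amp[_inside_cyst(pos, cyst)] *= cyst.amplitude_ratio
    for wire in spec.wires:
        amp[_inside_wire(pos, wire)] *= wire.amplitude_ratio
        # densify: thin cylinders hold few background scatterers
        ax = "xyz".index(wire.axis)
        radius = wire.diameter_um / 2000.0
        length = spec.bounds[ax][1] - spec.bounds[ax][0]
        n_extra = rng.poisson(9.0 * spec.scatterer_density * math.pi * radius ** 2 * length)
        if n_extra:
            r = radius * np.sqrt(rng.uniform(0, 1, n_extra))
            phi = rng.uniform(0, 2 * math.pi, n_extra)
            extra = np.tile(np.asarray(wire.center), (n_extra, 1))
            keep = [i for i in range(3) if i != ax]
            extra[:, keep[0]] += r * np.cos(phi)
            extra[:, keep[1]] += r * np.sin(phi)
            extra[:, ax] = rng.uniform(*spec.bounds[ax], n_extra)
            pos = np.vstack([pos, extra])
            amp = np.concatenate(
                [amp, wire.amplitude_ratio *
                 rng.normal(0.0, spec.background_amplitude_sd, n_extra)]
            )
    return ScattererField(pos[:, 0], pos[:, 1], pos[:, 2], amp)


def echogenicity_map(spec: PhantomSpec, lattice: LatticeSpec) -> Volume3D:
    """Deterministic piecewise-constant reflectivity map (the ideal image).

    Background 1; each cyst/wire region set to its amplitude ratio.  This is
    the ground-truth reference that reconstructions are scored against.
    """
    xs = lattice.axis_coords(0)
    ys = lattice.axis_coords(1)
    zs = lattice.axis_coords(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vals = np.ones(len(pos))
    for cyst in spec.cysts:
        vals[_inside_cyst(pos, cyst)] = cyst.amplitude_ratio
    for wire in spec.wires:
        vals[_inside_wire(pos, wire)] = wire.amplitude_ratio
    return Volume3D(lattice, vals.reshape(lattice.shape), "linear")


def rasterize_reflectivity(
    field: ScattererField, lattice: LatticeSpec, out_of_bounds: str = "error"
) -> Volume3D:
    """Trilinear (splatting) deposition of scatterer amplitudes onto voxels.

    Total deposited mass equals the sum of amplitudes of in-lattice
    scatterers.  ``out_of_bounds``: 'error' or 'drop'.
    """
    idx = lattice.position_to_index(field.positions)
    shape = np.array(lattice.shape)
    # splat support must stay inside the lattice (voxel-center convention)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    if not inside.all():
        if out_of_bounds == "error":
            raise ValueError(f"{int((~inside).sum())} scatterers outside the lattice")
        idx, amp = idx[inside], field.amplitude[inside]
    else:
        amp = field.amplitude

    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    out = np.zeros(lattice.shape)
    for corner in range(8):
        off = np.array([(corner >> b) & 1 for b in range(3)])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        tgt = np.clip(i0 + off, 0, shape - 1)
        np.add.at(out, (tgt[:, 0], tgt[:, 1], tgt[:, 2]), amp * w)
    return Volume3D(lattice, out, "linear")


# ---------------------------------------------------------------------------
# System operator H: depth-banded convolution with linear band blending
# ---------------------------------------------------------------------------

def _odd_pad(kernel: np.ndarray) -> np.ndarray:
    """Zero-pad a kernel to odd side lengths (keeps convolve/correlate adjoint exact)."""
    pads = [(0, 1 - n % 2) for n in kernel.shape]
    return np.pad(kernel, pads) if any(p[1] for p in pads) else kernel


class SystemOperator:
    """Linear operator H: per-band convolution blended across depth bands.

    ``H f = sum_b conv(lambda_b(z) . f, K_b)`` with hat-function band weights
    forming a partition of unity over depth; convolution is zero-padded.
    The adjoint is ``H^T g = sum_b lambda_b(z) . corr(g, K_b)``.  With
    ``bank=None`` the operator is the identity.

    Arrays are (nx, nz) slices or (nx, ny, nz) volumes; the last axis is
    depth.
    """

    def __init__(self, bank: PSFBank | None, lattice: LatticeSpec):
        self.bank = bank
        self.lattice = lattice
        if bank is not None:
            zs = lattice.axis_coords(2)
            self._weights = bank.band_weights(zs)  # (n_bands, nz)
            self._kernels = [_odd_pad(k.values) for k in bank.kernels]
            for k, orig in zip(self._kernels, bank.kernels):
                for ks, sp, ax in zip(orig.values.shape, orig.spacing,
                                      (0, 2) if orig.ndim == 2 else (0, 1, 2)):
                    if not np.isclose(sp, lattice.spacing[ax]):
                        raise ValueError(
                            f"kernel spacing {orig.spacing} does not match lattice "
                            f"spacing {lattice.spacing}"
                        )

    def _conv(self, arr: np.ndarray, kern: np.ndarray, adjoint: bool) -> np.ndarray:
        if arr.ndim == 3 and kern.ndim == 2:
            kern = kern[:, None, :]
        elif arr.ndim == 2 and kern.ndim == 3:
            raise ValueError("3-D kernel applied to a 2-D slice")
        op = ndimage.correlate if adjoint else ndimage.convolve
        return op(arr, kern, mode="constant", cval=0.0)

    def _bandweight(self, arr_ndim: int, b: int) -> np.ndarray:
        w = self._weights[b]
        return w[None, :] if arr_ndim == 2 else w[None, None, :]

    def apply(self, arr: np.ndarray) -> np.ndarray:
        if self.bank is None:
            return arr.copy()
        out = np.zeros_like(arr, dtype=float)
        for b, kern in enumerate(self._kernels):
            out += self._conv(arr * self._bandweight(arr.ndim, b), kern, adjoint=False)
        return out

    def adjoint(self, arr: np.ndarray) -> np.ndarray:
        if self.bank is None:
            return arr.copy()
        out = np.zeros_like(arr, dtype=float)
        for b, kern in enumerate(self._kernels):
            out += self._bandweight(arr.ndim, b) * self._conv(arr, kern, adjoint=True)
        return out


def apply_system_operator(f: Volume3D, bank: PSFBank | None) -> Volume3D:
    """Blur a linear-domain reflectivity volume with the depth-banded PSF."""
    if f.domain_tag != "linear":
        raise ValueError("system operator acts on linear-domain volumes")
    op = SystemOperator(bank, f.lattice)
    return f.copy(values=op.apply(f.values))


# ---------------------------------------------------------------------------
# Speckle
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Multiplicative generalized-gamma speckle + optional additive noise.

    The amplitude law is GG(shape=nu, scale=a, power=p) with density
    proportional to ``x^(p nu - 1) exp(-(x/a)^p)``.  The defaults
    (nu=1, p=2) give Rayleigh speckle; ``scale=None`` picks the scale so the
    mean is exactly 1 (mean-preserving noise).  The log-compressed amplitude
    then follows the Fisher-Tippett law with scale ``ft_sigma``.
    """

    shape: float = 1.0
    scale: float | None = None
    power: float = 2.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.power <= 0:
            raise ValueError("generalized-gamma shape and power must be positive")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")

    @property
    def effective_scale(self) -> float:
        if self.scale is not None:
            return self.scale
        # GG mean = a Gamma(nu + 1/p) / Gamma(nu); choose a for mean 1
        return gamma_fn(self.shape) / gamma_fn(self.shape + 1.0 / self.power)

    @property
    def ft_sigma(self) -> float:
        """Fisher-Tippett scale of the log-compressed draw (Rayleigh case)."""
        if not (np.isclose(self.shape, 1.0) and np.isclose(self.power, 2.0)):
            raise ValueError("ft_sigma is defined for the Rayleigh case (shape=1, power=2)")
        return self.effective_scale / math.sqrt(2.0)

    def draw(self, shape: tuple[int, ...], rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
            log.debug("speckle draw seed=%d", self.seed)
        y = rng.gamma(self.shape, 1.0, size=shape)
        return self.effective_scale * y ** (1.0 / self.power)


def multiplicative_speckle(v: Volume3D, noise: NoiseSpec,
                           rng: np.random.Generator | None = None) -> Volume3D:
    """Multiply each voxel by an i.i.d. generalized-gamma speckle draw."""
    if v.domain_tag != "linear":
        raise ValueError("speckle multiplies linear-domain volumes")
    if np.nanmin(v.values) < 0:
        raise ValueError("linear-domain input must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
        log.debug("multiplicative_speckle seed=%d", noise.seed)
    out = v.values * noise.draw(v.values.shape, rng)
    if noise.additive_sd > 0:
        out = out + rng.normal(0.0, noise.additive_sd, v.values.shape)
    return v.copy(values=out)


def log_compress(v: Volume3D, floor_eps: float = 1e-6) -> Volume3D:
    """Natural-log compression with a floor: value <- ln(max(value, eps)).

    NaN (missing) entries propagate unchanged.
    """
    if v.domain_tag != "linear":
        raise ValueError("log_compress expects a linear-domain volume")
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    return v.copy(values=np.log(np.maximum(v.values, floor_eps)), domain_tag="log")


# ---------------------------------------------------------------------------
# Fan-beam sampling and scan conversion
# ---------------------------------------------------------------------------

@dataclass
class BeamGeometry:
    """Transmit-event beam directions: paired polar/azimuth angle sets.

    Angles follow the spherical convention x = r sin(theta) cos(phi),
    y = r sin(theta) sin(phi), z = r cos(theta): theta is measured from the
    depth axis.  The beam origin is the transducer center at z = 0.
    """

    theta: np.ndarray            # rad, one per transmit event
    phi: np.ndarray              # rad, paired with theta
    radial_step: float = 0.1     # mm

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.theta.size == 0:
            raise ValueError("angle set is empty")
        if self.phi.shape != self.theta.shape:
            raise ValueError("theta and phi must pair one-to-one")
        if self.radial_step <= 0:
            raise ValueError("radial_step must be positive")

    @property
    def n_transmit_events(self) -> int:
        return len(self.theta)


def fan_geometry(n_events: int = 32, span_deg: float = 20.0,
                 radial_step: float = 0.1, phi: float = 0.0) -> BeamGeometry:
    """Fan of ``n_events`` beams spanning +-span_deg in the phi-plane.

    The default (32 events over +-20 degrees) matches one transmit event per
    column of a 32-column array.
    """
    theta = np.linspace(-np.deg2rad(span_deg), np.deg2rad(span_deg), n_events)
    return BeamGeometry(theta, np.full(n_events, phi), radial_step)


def spherical_to_cartesian(r, theta, phi) -> np.ndarray:
    """(n, 3) Cartesian positions from spherical beam coordinates."""
    r, theta, phi = np.broadcast_arrays(
        np.atleast_1d(r), np.atleast_1d(theta), np.atleast_1d(phi))
    return np.column_stack([
        r * np.sin(theta) * np.cos(phi),
        r * np.sin(theta) * np.sin(phi),
        r * np.cos(theta),
    ])


def _beam_origin(lattice: LatticeSpec) -> np.ndarray:
    """Transducer center: lateral center of the lattice at z = 0."""
    xs = lattice.axis_coords(0)
    ys = lattice.axis_coords(1)
    return np.array([0.5 * (xs[0] + xs[-1]), 0.5 * (ys[0] + ys[-1]), 0.0])


def fan_beam_mask(geometry: BeamGeometry, lattice: LatticeSpec) -> SampleMask:
    """Voxels traversed by any transmit-event ray, nearest-voxel stamped."""
    origin = _beam_origin(lattice)
    corners = lattice.index_to_position(
        np.array([[i, j, k] for i in (0, lattice.shape[0] - 1)
                  for j in (0, lattice.shape[1] - 1)
                  for k in (0, lattice.shape[2] - 1)]))
    r_max = float(np.linalg.norm(corners - origin, axis=1).max())
    rs = np.arange(0.0, r_max + geometry.radial_step, geometry.radial_step)
    observed = np.zeros(lattice.shape, dtype=bool)
    shape = np.array(lattice.shape)
    for th, ph in zip(geometry.theta, geometry.phi):
        pts = origin + spherical_to_cartesian(rs, th, ph)
        idx = np.rint(lattice.position_to_index(pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        observed[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not observed.any():
        raise ValueError("no ray intersects the lattice")
    return SampleMask(lattice, observed)


@dataclass
class Observation:
    """Sparse measurement bundle: values, mask, geometry and PSF reference."""

    g: Volume3D
    mask: SampleMask
    geometry: BeamGeometry | None = None
    psf_bank: PSFBank | None = None

    def __post_init__(self) -> None:
        if self.g.lattice != self.mask.lattice:
            raise ValueError("observation and mask must share one lattice")
        unobserved = ~self.mask.observed
        if np.any(np.isfinite(self.g.values[unobserved])):
            vals = self.g.values.copy()
            vals[unobserved] = MISSING
            self.g = self.g.copy(values=vals)

    def to_log(self, floor_eps: float | None = None) -> "Observation":
        """Log-compress the observed readings (floor: 1e-6 of the max)."""
        if self.g.domain_tag == "log":
            return self
        if floor_eps is None:
            floor_eps = 1e-6 * float(np.nanmax(self.g.values))
        return Observation(log_compress(self.g, floor_eps), self.mask,
                           self.geometry, self.psf_bank)


def scan_convert(r, theta, phi, values, lattice: LatticeSpec,
                 geometry: BeamGeometry | None = None) -> Observation:
    """Map beam-space samples (r, theta, phi, value) onto the regular lattice.

    Samples are placed at their Cartesian positions (relative to the beam
    origin) and linearly interpolated onto voxel centers; the mask marks the
    voxels inside the interpolation support.  Degenerate sample sets
    (collinear rays) fall back to nearest-voxel stamping.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty sample set")
    if not np.all(np.isfinite(values)):
        raise ValueError("ray samples must be finite")
    pts = _beam_origin(lattice) + spherical_to_cartesian(r, theta, phi)

    xs, ys, zs = (lattice.axis_coords(a) for a in range(3))
    flat2d = lattice.shape[1] == 1
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    targets = np.column_stack([X.ravel(), Z.ravel()] if flat2d
                              else [X.ravel(), Y.ravel(), Z.ravel()])
    sample_pts = pts[:, [0, 2]] if flat2d else pts
    try:
        if len(values) < (3 if flat2d else 4):
            raise ValueError("too few samples for linear interpolation")
        grid = griddata(sample_pts, values, targets, method="linear")
    except Exception:
        grid = np.full(len(targets), np.nan)
        idx = np.rint(lattice.position_to_index(pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(lattice.shape)), axis=1)
        flat = np.ravel_multi_index((idx[ok, 0], idx[ok, 1], idx[ok, 2]), lattice.shape)
        grid[flat] = values[ok]
    grid = grid.reshape(lattice.shape)
    observed = np.isfinite(grid)
    if not observed.any():
        raise ValueError("no sample maps into the lattice")
    vol = Volume3D(lattice, np.where(observed, grid, MISSING), "linear")
    return Observation(vol, SampleMask(lattice, observed), geometry)


def observe(f: Volume3D, bank: PSFBank | None, noise: NoiseSpec | None,
            geometry: BeamGeometry) -> Observation:
    """Full synthetic forward model: blur, speckle, then fan-beam restriction."""
    blurred = apply_system_operator(f, bank)
    speckled = multiplicative_speckle(blurred, noise) if noise is not None else blurred
    mask = fan_beam_mask(geometry, f.lattice)
    vals = np.where(mask.observed, speckled.values, MISSING)
    return Observation(Volume3D(f.lattice, vals, "linear"), mask, geometry, bank)


# ---------------------------------------------------------------------------
# RF path: linear scattering + delay-and-sum
# ---------------------------------------------------------------------------

def simulate_rf(
    field: ScattererField,
    tx: ApertureSpec,
    rx: ApertureSpec,
    tx_focus_depth: float | None = None,
    tx_focus_lateral: float = 0.0,
    sub_size: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Per-row-element RF traces for one transmit event.

    Linear scattering: each receive-element trace is the superposition over
    scatterers of conv(transmit impulse response with focusing delays,
    excitation, single-element receive impulse response), weighted by the
    scatterer amplitude.  The impulse responses carry the geometric
    spreading.  Returns ``(t0, dt, traces)`` with traces of shape
    ``(n_rx_elements, n_samples)``.
    """
    if len(field) == 0:
        raise ValueError("empty scatterer field")
    tx_delays = tx.focus_delays(tx_focus_depth, tx_focus_lateral)
    pulse = excitation_pulse(tx, analytic=False)
    dt = tx.dt

    pieces: list[tuple[int, float, np.ndarray]] = []  # (rx_elem, start, samples)
    for s in range(len(field)):
        pt = _as_field_point(field, s)
        h_tx = spatial_impulse_response(tx, pt, delays=tx_delays, sub_size=sub_size)
        txp = np.convolve(h_tx.samples, pulse.samples) * dt
        txp_start = h_tx.start_time + pulse.start_time
        for j in range(rx.n_elements):
            h_rx = spatial_impulse_response(rx, pt, active_elements=[j], sub_size=sub_size)
            tr = np.convolve(txp, h_rx.samples) * dt * field.amplitude[s]
            pieces.append((j, txp_start + h_rx.start_time, tr))

    t0 = min(p[1] for p in pieces)
    t_end = max(p[1] + len(p[2]) * dt for p in pieces)
    n = int(np.ceil((t_end - t0) / dt)) + 1
    traces = np.zeros((rx.n_elements, n))
    for j, start, tr in pieces:
        k = int(round((start - t0) / dt))
        traces[j, k:k + len(tr)] += tr
    return t0, dt, traces


def _as_field_point(field: ScattererField, i: int):
    from .psf import FieldPoint

    return FieldPoint(float(field.x[i]), float(field.y[i]), float(field.z[i]))


def das_beamform(
    t0: float,
    dt: float,
    traces: np.ndarray,
    rx: ApertureSpec,
    depths: np.ndarray,
    lateral: tuple[float, float] = (0.0, 0.0),
    t_offset: float = 0.0,
    elements: np.ndarray | None = None,
) -> np.ndarray:
    """Delay-and-sum one image line, envelope-detected.

    For each depth sample the per-element receive focusing delay is applied
    (transmit travel approximated as ``t_offset + depth/c``), traces are
    summed coherently, and the envelope of the summed line is taken as the
    analytic-signal magnitude (Hilbert transform along depth).
    """
    depths = np.asarray(depths, dtype=float)
    centers = rx.element_centers()
    if elements is None:
        elements = np.arange(rx.n_elements)
    pts = np.column_stack([np.full(len(depths), lateral[0]),
                           np.full(len(depths), lateral[1]), depths])
    t_end = t0 + (traces.shape[1] - 1) * dt
    line = np.zeros(len(depths))
    any_inside = False
    for j in elements:
        dist = np.linalg.norm(pts - centers[j][None, :], axis=1)  # mm
        t = t_offset + depths * MM / rx.sound_speed + dist * MM / rx.sound_speed
        any_inside |= bool(np.any((t >= t0) & (t <= t_end)))
        # times outside the recording read as silence
        line += np.interp(t, t0 + dt * np.arange(traces.shape[1]), traces[j],
                          left=0.0, right=0.0)
    if not any_inside:
        raise ValueError("requested depths lie entirely outside the recorded time window")
    return np.abs(signal.hilbert(line))


# ---------------------------------------------------------------------------
# Phantom presets (cyst and wire recipes)
# ---------------------------------------------------------------------------

def preset_phantom(name: str, seed: int = 0) -> PhantomSpec:
    """Named phantom recipes.

    ``cysts-equal``: four 6 mm cysts, 10 mm apart in depth.
    ``cysts-shrinking``: four cysts 10 mm apart with gradually reduced
    diameters.  ``wires-644um``: four 644 um wires arranged for a
    cross-section scan.
    """
    if name == "cysts-equal":
        cysts = [CystSpec((0.0, 0.0, 15.0 + 10.0 * i), 6.0) for i in range(4)]
        return PhantomSpec(((-10, 10), (-10, 10), (5, 55)), cysts=cysts, seed=seed)
    if name == "cysts-shrinking":
        diameters = [6.0, 4.5, 3.0, 1.5]
        cysts = [CystSpec((0.0, 0.0, 15.0 + 10.0 * i), d) for i, d in enumerate(diameters)]
        return PhantomSpec(((-10, 10), (-10, 10), (5, 55)), cysts=cysts, seed=seed)
    if name == "wires-644um":
        wires = [WireSpec("y", (-4.5 + 3.0 * i, 0.0, 8.0 + 4.0 * i), 644.0)
                 for i in range(4)]
        return PhantomSpec(((-8, 8), (-2, 2), (2, 26)), wires=wires, seed=seed)
    raise ValueError(f"unknown phantom preset {name!r}")
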