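"""Multilayered conditional random field MAP reconstruction.

The reconstruction estimates the log-domain reflectivity field F from a
sparse, speckled, blurred observation G by minimizing

    E(F, G, Cr) = alpha * sum_i psi_u(f_i)  +  beta * sum_{i,j} psi_p(f_i, f_j)

* The **unary** term is the Fisher-Tippett negative log-likelihood of the
  log-domain residual d = log G - log H(exp F): log-compressed Rayleigh-type
  speckle follows p(I) = 2 exp[(2I - ln 2 sigma^2) - exp(2I - ln 2 sigma^2)].
  It acts only where a reading exists; the **uncertainty layer** Cr (1 at
  missing observations, 0 at available ones) zeroes it elsewhere, so missing
  data exerts no data force and is inpainted by the pairwise term.
* The **pairwise** term sums |f_i - f_j| * w(g_i, g_j) over all pairs
  (center, other) inside a sliding clique window, with the penalty weight
  w = w_sp * w_fov combining spatial proximity (Gaussian in Euclidean voxel
  distance, scale sigma_sp) and first-order variation of the observed
  intensities (Gaussian in |g_i - g_j|, scale sigma_fov) — large observed
  contrast suppresses smoothing, preserving edges.
* Inference is gradient descent with backtracking line search on the step,
  one 2-D slice at a time; the PSF bank is still indexed by each voxel's
  true depth, so the depth-varying beam profile is respected.

H is the depth-banded convolution operator of
:class:`rcus.acquisition.SystemOperator` (identity when no bank is given).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from .acquisition import Observation, SystemOperator
from .volumes import LatticeSpec, SampleMask, Volume3D

log = logging.getLogger("rcus")


class DivergenceError(RuntimeError):
    """Raised when the energy becomes non-finite; carries the trace."""

    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Fisher-Tippett density
# ---------------------------------------------------------------------------

def fisher_tippett_pdf(I, sigma: float):
    """Density of log-compressed Rayleigh speckle: 2 exp[u - exp(u)], u = 2I - ln 2 sigma^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = 2.0 * np.asarray(I, dtype=float) - math.log(2.0 * sigma ** 2)
    return 2.0 * np.exp(u - np.exp(u))


def fisher_tippett_cdf(I, sigma: float):
    """P(log-amplitude <= I) for Rayleigh amplitude of scale sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = 2.0 * np.asarray(I, dtype=float) - math.log(2.0 * sigma ** 2)
    return 1.0 - np.exp(-np.exp(u))


def fisher_tippett_mode(sigma: float) -> float:
    """Location of the density peak: I = ln(2 sigma^2) / 2."""
    return 0.5 * math.log(2.0 * sigma ** 2)


def estimate_sigma(residuals) -> float:
    """Maximum-likelihood Fisher-Tippett scale from log-domain residuals.

    Stationarity of the negative log-likelihood gives the closed form
    ``sigma = sqrt(mean(exp(2 I)) / 2)`` (the root-mean-square amplitude over
    sqrt(2)).  Invariant under relabeling; shifts of I rescale sigma by the
    corresponding linear-domain factor.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    r = r[np.isfinite(r)]
    if r.size < 30:
        raise ValueError(f"need at least 30 residuals, got {r.size}")
    if np.ptp(r) < 1e-12:
        raise ValueError("degenerate (constant) residual sample")
    return float(np.sqrt(np.mean(np.exp(2.0 * r)) / 2.0))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CliqueStructure:
    """Sliding clique window; pairs are (center, every other in-window voxel)."""

    window_size: int = 11
    boundary_policy: str = "clip"  # pairs with both endpoints inside the slice

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("clique window must be odd-sided")
        if self.boundary_policy != "clip":
            raise ValueError("only the 'clip' boundary policy is implemented")

    def offsets(self) -> list[tuple[int, int]]:
        hw = self.window_size // 2
        return [(di, dj) for di in range(-hw, hw + 1) for dj in range(-hw, hw + 1)
                if (di, dj) != (0, 0)]


@dataclass
class MCRFConfig:
    """Model and solver parameters.

    alpha/beta weight the unary (data) and pairwise (smoothness) energies;
    sigma is the Fisher-Tippett scale (None: estimated from the residuals at
    initialization); sigma_sp is in voxel units, sigma_fov in normalized
    log-intensity units (the observed log image is min-max scaled to [0, 1]
    for the FOV penalty when fov_normalize is set).
    """

    alpha: float = 0.3
    beta: float = 1.0
    sigma: float | None = None
    sigma_sp: float = 5.0
    sigma_fov: float = 0.03
    clique: CliqueStructure = field(default_factory=CliqueStructure)
    step_size: float = 0.1
    backtrack: float = 0.5
    max_iters: int = 500
    energy_tol: float = 1e-6
    log_floor_eps: float | None = None   # None: 1e-6 of the volume max
    seed: int = 0
    slice_axis: int = 1
    fov_normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.sigma_sp <= 0 or self.sigma_fov <= 0:
            raise ValueError("sigma_sp and sigma_fov must be positive")
        if self.step_size <= 0 or not (0 < self.backtrack < 1):
            raise ValueError("invalid step control")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "MCRFConfig":
        """Parameter presets: 'simulated' (alpha=0.3, beta=1.0), 'real' (0.7, 0.3)."""
        presets = {"simulated": dict(alpha=0.3, beta=1.0), "real": dict(alpha=0.7, beta=0.3)}
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}")
        return cls(**{**presets[name], **overrides})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clique"] = {"window_size": self.clique.window_size,
                       "boundary_policy": self.clique.boundary_policy}
        return d


@dataclass
class UncertaintyLayer:
    """0/1 layer: 1 at missing observations, 0 where readings exist."""

    cr: np.ndarray

    def __post_init__(self) -> None:
        self.cr = np.asarray(self.cr)
        if not np.isin(self.cr, (0, 1)).all():
            raise ValueError("uncertainty layer must be 0/1")
        self.cr = self.cr.astype(np.uint8)


def make_uncertainty_layer(mask: SampleMask) -> UncertaintyLayer:
    """Cr = 1 - observed."""
    return UncertaintyLayer((~mask.observed).astype(np.uint8))


@dataclass
class EnergyBreakdown:
    unary: float      # unweighted sum of unary potentials
    pairwise: float   # unweighted sum of pairwise potentials
    alpha: float
    beta: float

    @property
    def total(self) -> float:
        return self.alpha * self.unary + self.beta * self.pairwise


@dataclass
class ReconResult:
    """Reconstruction output: log and linear renderings plus solver telemetry."""

    f_log: Volume3D
    f_linear: Volume3D
    energy_trace: np.ndarray
    iterations: int
    converged: bool
    sigma: float
    config: MCRFConfig
    flux_gain: float = 1.0
    slice_traces: list[np.ndarray] | None = None

    @property
    def final_energy(self) -> float:
        return float(self.energy_trace[-1])


# ---------------------------------------------------------------------------
# Penalty functions (scalar forms)
# ---------------------------------------------------------------------------

def penalty_sp(i, j, sigma_sp: float) -> float:
    """Spatial proximity weight exp(-d_E(i,j)^2 / sigma_sp^2), d_E in voxels."""
    if sigma_sp <= 0:
        raise ValueError("sigma_sp must be positive")
    d2 = float(np.sum((np.asarray(i, dtype=float) - np.asarray(j, dtype=float)) ** 2))
    return math.exp(-d2 / sigma_sp ** 2)


def penalty_fov(g_i: float, g_j: float, sigma_fov: float) -> float:
    """First-order-variation weight exp(-|g_i - g_j|^2 / sigma_fov^2)."""
    if sigma_fov <= 0:
        raise ValueError("sigma_fov must be positive")
    return math.exp(-abs(g_i - g_j) ** 2 / sigma_fov ** 2)


def combined_penalty(i, j, g_i, g_j, config: MCRFConfig,
                     observed_i: bool = True, observed_j: bool = True) -> float:
    """Product penalty w_sp * w_fov; w_fov falls back to 1 at unobserved endpoints."""
    w = penalty_sp(i, j, config.sigma_sp)
    if observed_i and observed_j:
        w *= penalty_fov(g_i, g_j, config.sigma_fov)
    return w


# ---------------------------------------------------------------------------
# Slice problem: energies and gradients on one 2-D slice
# ---------------------------------------------------------------------------

class SliceProblem:
    """Energy, gradient and bookkeeping for one (x, z) slice.

    Parameters
    ----------
    g : 2-D log-domain observation (NaN at unobserved voxels)
    observed : boolean mask, same shape
    operator : SystemOperator (identity when built with bank=None)
    config, sigma : model parameters; sigma is the Fisher-Tippett scale
    """

    def __init__(self, g: np.ndarray, observed: np.ndarray,
                 operator: SystemOperator, config: MCRFConfig, sigma: float):
        g = np.asarray(g, dtype=float)
        observed = np.asarray(observed, dtype=bool)
        if g.shape != observed.shape or g.ndim != 2:
            raise ValueError("g and observed must be matching 2-D arrays")
        if not np.all(np.isfinite(g[observed])):
            bad = np.argwhere(observed & ~np.isfinite(g))[0]
            raise ValueError(f"non-finite observation at observed voxel {tuple(int(v) for v in bad)}")
        self.g = g
        self.observed = observed
        self.cr = ~observed
        self.op = operator
        self.config = config
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        self._ln2s2 = math.log(2.0 * sigma ** 2)
        self._g_safe = np.where(observed, g, 0.0)
        self._pairs = self._build_pairs()

    # -- pairwise machinery --------------------------------------------------

    def _build_pairs(self):
        cfg = self.config
        gn = self._g_safe
        if cfg.fov_normalize:
            vals = self.g[self.observed]
            rng = np.ptp(vals) if vals.size else 0.0
            if rng > 0:
                gn = np.where(self.observed, (self.g - vals.min()) / rng, 0.0)
        pairs = []
        nx, nz = self.g.shape
        for di, dj in cfg.clique.offsets():
            sa = (slice(max(0, -di), nx - max(0, di)), slice(max(0, -dj), nz - max(0, dj)))
            sb = (slice(max(0, di), nx - max(0, -di)), slice(max(0, dj), nz - max(0, -dj)))
            if sa[0].start >= sa[0].stop or sa[1].start >= sa[1].stop:
                continue
            w_sp = math.exp(-(di * di + dj * dj) / cfg.sigma_sp ** 2)
            both = self.observed[sa] & self.observed[sb]
            w_fov = np.where(both, np.exp(-((gn[sa] - gn[sb]) ** 2) / cfg.sigma_fov ** 2), 1.0)
            pairs.append((sa, sb, w_sp * w_fov))
        return pairs

    def pairwise_map(self, f: np.ndarray) -> np.ndarray:
        """Per-center pairwise energy: sum over in-window pairs of |f_i - f_j| w."""
        out = np.zeros_like(f)
        for sa, sb, w in self._pairs:
            out[sa] += np.abs(f[sa] - f[sb]) * w
        return out

    def pairwise_total(self, f: np.ndarray) -> float:
        total = 0.0
        for sa, sb, w in self._pairs:
            total += float(np.sum(np.abs(f[sa] - f[sb]) * w))
        return total

    def pairwise_gradient(self, f: np.ndarray) -> np.ndarray:
        """Signed subgradient of the pairwise energy (sign(0) = 0)."""
        grad = np.zeros_like(f)
        for sa, sb, w in self._pairs:
            s = np.sign(f[sa] - f[sb]) * w
            grad[sa] += s
            grad[sb] -= s
        return grad

    # -- unary machinery -----------------------------------------------------

    def _forward(self, f: np.ndarray) -> np.ndarray:
        return self.op.apply(np.exp(f))

    def unary_map(self, f: np.ndarray) -> np.ndarray:
        """Per-voxel Fisher-Tippett NLL of the residual; exactly 0 where Cr = 1."""
        a = self._forward(f)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = self._g_safe - np.log(a)
        u = 2.0 * d - self._ln2s2
        vals = np.exp(u) - u
        if not np.all(np.isfinite(vals[self.observed])):
            bad = np.argwhere(self.observed & ~np.isfinite(vals))[0]
            raise ValueError(f"non-finite unary residual at voxel {tuple(int(v) for v in bad)}")
        return np.where(self.observed, vals, 0.0)

    def unary_total(self, f: np.ndarray) -> float:
        return float(self.unary_map(f).sum())

    def unary_gradient(self, f: np.ndarray) -> np.ndarray:
        ef = np.exp(f)
        a = self.op.apply(ef)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = self._g_safe - np.log(a)
        u = 2.0 * d - self._ln2s2
        psi_prime = np.where(self.observed, 2.0 * (np.exp(u) - 1.0), 0.0)
        with np.errstate(invalid="ignore"):
            back = np.where(self.observed, psi_prime / a, 0.0)
        return -ef * self.op.adjoint(back)

    # -- assembly ------------------------------------------------------------

    def energy(self, f: np.ndarray) -> EnergyBreakdown:
        return EnergyBreakdown(self.unary_total(f), self.pairwise_total(f),
                               self.config.alpha, self.config.beta)

    def gradient(self, f: np.ndarray) -> np.ndarray:
        cfg = self.config
        grad = np.zeros_like(f)
        if cfg.alpha > 0:
            grad += cfg.alpha * self.unary_gradient(f)
        if cfg.beta > 0:
            grad += cfg.beta * self.pairwise_gradient(f)
        return grad


# Spec-level wrappers on raw slice arrays -----------------------------------

def unary_energy(f, g, cr, operator: SystemOperator, sigma: float):
    """Per-voxel unary energies and their (unweighted) total."""
    problem = SliceProblem(np.where(np.asarray(cr, bool), np.nan, g),
                           ~np.asarray(cr, bool), operator, MCRFConfig(), sigma)
    m = problem.unary_map(np.asarray(f, dtype=float))
    return m, float(m.sum())


def pairwise_energy(f, g, config: MCRFConfig, observed=None, operator=None):
    """Per-clique (per-center) pairwise energies and their (unweighted) total."""
    g = np.asarray(g, dtype=float)
    if observed is None:
        observed = np.isfinite(g)
    op = operator if operator is not None else SystemOperator(None, _dummy_lattice(g.shape))
    problem = SliceProblem(g, observed, op, config, sigma=1.0)
    m = problem.pairwise_map(np.asarray(f, dtype=float))
    return m, problem.pairwise_total(np.asarray(f, dtype=float))


def total_energy(f, g, cr, operator: SystemOperator, config: MCRFConfig,
                 sigma: float = 1.0) -> EnergyBreakdown:
    """E = alpha * unary_total + beta * pairwise_total on one slice."""
    cr = np.asarray(cr, bool)
    problem = SliceProblem(np.where(cr, np.nan, g), ~cr, operator, config, sigma)
    return problem.energy(np.asarray(f, dtype=float))


def energy_gradient(f, g, cr, operator: SystemOperator, config: MCRFConfig,
                    sigma: float = 1.0) -> np.ndarray:
    """Analytic gradient of the total energy with respect to F."""
    cr = np.asarray(cr, bool)
    problem = SliceProblem(np.where(cr, np.nan, g), ~cr, operator, config, sigma)
    return problem.gradient(np.asarray(f, dtype=float))


def _dummy_lattice(shape2d) -> LatticeSpec:
    return LatticeSpec((shape2d[0], 1, shape2d[1]))


# ---------------------------------------------------------------------------
# Baseline comparator: interpolation-only reconstruction
# ---------------------------------------------------------------------------

def _fill_slice(values2d: np.ndarray, observed2d: np.ndarray) -> np.ndarray:
    """Bilinear fill of unobserved voxels from observed neighbors.

    Linear interpolation inside the convex hull of the observed voxels,
    nearest-neighbor extrapolation outside it; observed voxels unchanged.
    """
    if observed2d.all():
        return values2d.copy()
    pts = np.argwhere(observed2d).astype(float)
    vals = values2d[observed2d]
    tgt = np.argwhere(~observed2d).astype(float)
    out = values2d.copy()
    filled = None
    if len(pts) >= 3:
        try:
            filled = griddata(pts, vals, tgt, method="linear")
        except Exception:
            filled = None
    if filled is None:
        filled = np.full(len(tgt), np.nan)
    hole = ~np.isfinite(filled)
    if hole.any():
        filled[hole] = griddata(pts, vals, tgt[hole], method="nearest")
    out[~observed2d] = filled
    return out


def baseline_interpolation(obs: Observation) -> Volume3D:
    """Interpolation-only reconstruction: the uncompensated RC comparator.

    Fills unobserved voxels slice by slice by bilinear interpolation from
    observed neighbors; observed readings pass through unchanged.
    """
    vals = obs.g.values
    observed = obs.mask.observed
    out = np.empty_like(vals)
    for iy in range(vals.shape[1]):
        if not observed[:, iy, :].any():
            raise ValueError(f"slice {iy} has no observed voxels")
        out[:, iy, :] = _fill_slice(vals[:, iy, :], observed[:, iy, :])
    return Volume3D(obs.g.lattice, out, obs.g.domain_tag)


# ---------------------------------------------------------------------------
# Gradient-descent inference
# ---------------------------------------------------------------------------

_MAX_BACKTRACKS = 40


def _descend(problem: SliceProblem, f0: np.ndarray, config: MCRFConfig):
    f = f0.astype(float).copy()
    e = problem.energy(f).total
    if not np.isfinite(e):
        raise DivergenceError("initial energy is not finite", np.array([e]))
    trace = [e]
    eta = config.step_size
    converged = False
    for _ in range(config.max_iters):
        grad = problem.gradient(f)
        if not np.all(np.isfinite(grad)):
            raise DivergenceError("non-finite gradient", np.asarray(trace))
        accepted = False
        for _bt in range(_MAX_BACKTRACKS):
            f_new = f - eta * grad
            e_new = problem.energy(f_new).total
            if np.isfinite(e_new) and e_new <= e:
                accepted = True
                break
            eta *= config.backtrack
        if not accepted:
            converged = True  # no descent step exists at machine scale
            break
        drop = e - e_new
        f, e = f_new, e_new
        trace.append(e)
        eta = min(eta / config.backtrack ** 0.5, 1e3 * config.step_size)
        if drop <= config.energy_tol * max(abs(e), 1.0):
            converged = True
            break
    return f, np.asarray(trace), converged


def _slice_observation(obs: Observation, iy: int) -> Observation:
    lat = obs.g.lattice
    ys = lat.axis_coords(1)
    slat = LatticeSpec((lat.shape[0], 1, lat.shape[2]), lat.spacing,
                       (lat.origin[0], float(ys[iy]), lat.origin[2]))
    g = Volume3D(slat, obs.g.values[:, iy:iy + 1, :], obs.g.domain_tag)
    mask = SampleMask(slat, obs.mask.observed[:, iy:iy + 1, :])
    return Observation(g, mask, obs.geometry, obs.psf_bank)


def reconstruct_slice(obs: Observation, bank=None, config: MCRFConfig | None = None,
                      f0: Volume3D | None = None) -> ReconResult:
    """MAP reconstruction of a single (x, z) slice.

    The observation is log-compressed if still linear; the initial estimate
    is the interpolation baseline (warm start); sigma is estimated from the
    observed-voxel residuals at initialization unless fixed in the config.
    The energy trace is non-increasing by construction (backtracking).
    """
    config = config or MCRFConfig()
    if bank is None:
        bank = obs.psf_bank
    if obs.g.lattice.shape[1] != 1:
        raise ValueError("reconstruct_slice expects a single-slice (ny = 1) observation")
    if obs.g.domain_tag == "linear":
        obs = obs.to_log(config.log_floor_eps)
    lat = obs.g.lattice
    g2 = obs.g.values[:, 0, :]
    observed2 = obs.mask.observed[:, 0, :]
    op = SystemOperator(bank, lat)

    if f0 is None:
        f0 = baseline_interpolation(obs)
    f0_2 = f0.values[:, 0, :]

    sigma = config.sigma
    if sigma is None:
        with np.errstate(divide="ignore"):
            resid = g2 - np.log(np.maximum(op.apply(np.exp(f0_2)), 1e-300))
        try:
            sigma = estimate_sigma(resid[observed2])
        except ValueError:
            sigma = 1.0 / math.sqrt(2.0)  # centered Fisher-Tippett fallback
    log.debug("reconstruct_slice: sigma=%.4g coverage=%.2f", sigma, observed2.mean())

    problem = SliceProblem(g2, observed2, op, config, sigma)
    f, trace, converged = _descend(problem, f0_2, config)

    # Linear rendering with flux normalization: mean-1 speckle makes the
    # observed linear readings an unbiased flux reference, so matching the
    # re-blurred estimate's observed-voxel flux to the data removes the
    # downward bias of mode-matched, log-averaged despeckling.
    f_lin2 = np.exp(f)
    flux_model = float(op.apply(f_lin2)[observed2].sum())
    flux_obs = float(np.exp(g2[observed2]).sum())
    gain = flux_obs / flux_model if flux_model > 0 else 1.0
    f_log = Volume3D(lat, f[:, None, :], "log")
    f_lin = Volume3D(lat, (f_lin2 * gain)[:, None, :], "linear")
    return ReconResult(f_log, f_lin, trace, len(trace) - 1, converged, sigma, config,
                       flux_gain=gain)


def reconstruct_volume(obs: Observation, bank=None,
                       config: MCRFConfig | None = None) -> ReconResult:
    """Slice-independent MAP reconstruction of a 3-D observation.

    Each slice along ``config.slice_axis`` is reconstructed independently;
    the PSF bank remains indexed by true voxel depth.  Only slicing along
    the elevation axis (y) is implemented, matching the acquisition layout.
    """
    config = config or MCRFConfig()
    if config.slice_axis != 1:
        raise ValueError("only slice_axis=1 (elevation) is implemented")
    if bank is None:
        bank = obs.psf_bank
    ny = obs.g.lattice.shape[1]
    f_log = np.empty(obs.g.lattice.shape)
    f_lin = np.empty(obs.g.lattice.shape)
    traces = []
    sigmas = []
    for iy in range(ny):
        try:
            res = reconstruct_slice(_slice_observation(obs, iy), bank, config)
        except ValueError as exc:
            raise ValueError(f"slice {iy} failed: {exc}") from exc
        f_log[:, iy, :] = res.f_log.values[:, 0, :]
        f_lin[:, iy, :] = res.f_linear.values[:, 0, :]
        traces.append(res.energy_trace)
        sigmas.append(res.sigma)
    n = max(len(t) for t in traces)
    total = np.zeros(n)
    for t in traces:
        total += np.concatenate([t, np.full(n - len(t), t[-1])])
    return ReconResult(
        Volume3D(obs.g.lattice, f_log, "log"),
        Volume3D(obs.g.lattice, f_lin, "linear"),
        total, n - 1, True, float(np.mean(sigmas)), config, slice_traces=traces,
    )
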