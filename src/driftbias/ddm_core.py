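"""Wiener diffusion first-passage-time mathematics.

Two-boundary drift-diffusion model of a binary choice: evidence accumulates
as a Wiener process with drift ``v`` between an upper boundary ``a`` and a
lower boundary 0, starting at ``zr * a``.  The first boundary reached gives
the choice; observed response time adds a non-decision component ``t0``
(optionally asymmetric between responses via ``d``).  Inter-trial
variability follows the classical extension: uniform in starting point
(``szr``) and non-decision time (``st0``), normal in drift (``sv``).

Throughout this package the upper boundary is the high-reward response and
the lower boundary the low-reward response.  The diffusion coefficient is
fixed at 1, so ``a``, ``v`` and the variability parameters are expressed in
that scale convention; values are comparable only across analyses using the
same convention.

Density evaluation switches between the small-time and large-time series
expansions of the first-passage density with an analytically chosen
truncation, keeping the per-evaluation error below ``SERIES_EPS``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss

__all__ = [
    "DDMParams",
    "ParameterError",
    "absorption_probability",
    "fpt_density",
    "fpt_cdf",
    "simulate_trial",
    "simulate_trials",
    "euler_maruyama_trials",
]

Boundary = Literal["upper", "lower"]

#: per-evaluation truncation tolerance of the series expansions
SERIES_EPS = 1e-7

#: quadrature nodes for uniform variability in zr and t0
N_UNIFORM_NODES = 10
#: quadrature nodes for normal drift variability where no closed form exists
N_HERMITE_NODES = 24

_GL_NODES, _GL_WEIGHTS = leggauss(N_UNIFORM_NODES)
_GH_NODES, _GH_WEIGHTS = hermgauss(N_HERMITE_NODES)
_CDF_QUAD_NODES, _CDF_QUAD_WEIGHTS = leggauss(48)


class ParameterError(ValueError):
    """A DDM parameter set violates its domain constraints."""


@dataclass(frozen=True)
class DDMParams:
    """Decision-process parameters for one subject/condition.

    Parameters
    ----------
    a : float
        Boundary separation (evidence units), > 0.
    zr : float
        Relative starting point, fraction of ``a``, in (0, 1).
    v : float
        Drift rate (evidence units per second).
    t0 : float
        Mean non-decision time (s), >= 0.
    d : float
        Difference in non-decision time between responses (s); the upper
        response takes ``t0 + d/2``, the lower ``t0 - d/2``.
    szr : float
        Full range of uniform starting-point variability (fraction of a).
    sv : float
        SD of normal drift-rate variability (evidence/s).
    st0 : float
        Full range of uniform non-decision-time variability (s).
    """

    a: float
    zr: float
    v: float
    t0: float = 0.0
    d: float = 0.0
    szr: float = 0.0
    sv: float = 0.0
    st0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.a, self.zr, self.v, self.t0, self.d,
                            self.szr, self.sv, self.st0]).all():
            raise ParameterError("all parameters must be finite")
        if self.a <= 0:
            raise ParameterError(f"boundary separation a={self.a} must be > 0")
        if not 0 < self.zr < 1:
            raise ParameterError(f"relative start zr={self.zr} must lie in (0, 1)")
        if self.t0 < 0:
            raise ParameterError(f"non-decision time t0={self.t0} must be >= 0")
        if self.szr < 0 or self.sv < 0 or self.st0 < 0:
            raise ParameterError("variability parameters szr, sv, st0 must be >= 0")
        if self.zr - self.szr / 2 <= 0 or self.zr + self.szr / 2 >= 1:
            raise ParameterError(
                f"starting-point range zr±szr/2 = {self.zr}±{self.szr / 2} "
                "must stay inside (0, 1)")
        if self.t0 - self.st0 / 2 - abs(self.d) / 2 < 0:
            raise ParameterError(
                "t0 - st0/2 - |d|/2 must be >= 0 so response times stay positive")

    def replace(self, **changes: float) -> "DDMParams":
        """Return a copy with the given fields changed (revalidated)."""
        return replace(self, **changes)


def _check_boundary(boundary: str) -> bool:
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary == "upper"


# ---------------------------------------------------------------------------
# absorption probabilities
# ---------------------------------------------------------------------------

def _p_upper_core(v, w, a):
    """P(hit upper boundary first), elementwise; no inter-trial variability.

    For v != 0 this is expm1(-2 v a w) / expm1(-2 v a); the v -> 0 limit is w.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    v, w = np.broadcast_arrays(v, w)
    out = np.empty_like(v, dtype=float)
    small = np.abs(v) * a < 1e-8
    out[small] = np.broadcast_to(w, v.shape)[small]
    vn = v[~small]
    wn = w[~small] if w.shape else w
    out[~small] = np.expm1(-2.0 * vn * a * wn) / np.expm1(-2.0 * vn * a)
    return out


def absorption_probability(params: DDMParams, boundary: Boundary = "upper") -> float:
    """Probability that the process is absorbed at the named boundary.

    Inter-trial variability in starting point (uniform) and drift (normal) is
    integrated out by Gauss-Legendre and Gauss-Hermite quadrature.
    """
    upper = _check_boundary(boundary)
    w_nodes, w_weights = _zr_nodes(params)
    v_nodes, v_weights = _drift_nodes(params)
    p = _p_upper_core(v_nodes[:, None], w_nodes[None, :], params.a)
    p_upper = float(v_weights @ p @ w_weights)
    return p_upper if upper else 1.0 - p_upper


def _zr_nodes(params: DDMParams):
    if params.szr == 0:
        return np.array([params.zr]), np.array([1.0])
    w = params.zr + 0.5 * params.szr * _GL_NODES
    return w, 0.5 * _GL_WEIGHTS  # weights sum to 1


def _drift_nodes(params: DDMParams):
    if params.sv == 0:
        return np.array([params.v]), np.array([1.0])
    v = params.v + np.sqrt(2.0) * params.sv * _GH_NODES
    return v, _GH_WEIGHTS / np.sqrt(np.pi)


def _t0_nodes(params: DDMParams, upper: bool):
    base = params.t0 + (0.5 * params.d if upper else -0.5 * params.d)
    if params.st0 == 0:
        return np.array([base]), np.array([1.0])
    t0 = base + 0.5 * params.st0 * _GL_NODES
    return t0, 0.5 * _GL_WEIGHTS


# ---------------------------------------------------------------------------
# series expansions of the dimensionless first-passage density
# ---------------------------------------------------------------------------

def _n_terms_small(u, eps: float):
    """Terms needed by the small-time expansion at scaled time u (array ok)."""
    u = np.asarray(u, dtype=float)
    arg = 2.0 * eps * np.sqrt(2.0 * np.pi * np.maximum(u, 1e-300))
    ks = np.where(arg < 1.0,
                  2.0 + np.sqrt(-2.0 * u * np.log(np.minimum(arg, 1.0 - 1e-16))),
                  2.0)
    ks = np.maximum(ks, np.sqrt(u) + 1.0)
    return (np.ceil(ks / 2.0) + 1).astype(int)


def _n_terms_large(u, eps: float):
    """Terms needed by the large-time expansion at scaled time u (array ok)."""
    u = np.asarray(u, dtype=float)
    arg = np.pi * np.maximum(u, 1e-300) * eps
    floor_k = 1.0 / (np.pi * np.sqrt(np.maximum(u, 1e-300)))
    kl = np.where(arg < 1.0,
                  np.maximum(np.sqrt(-2.0 * np.log(np.minimum(arg, 1.0 - 1e-16))
                                     / (np.pi ** 2 * np.maximum(u, 1e-300))),
                             floor_k),
                  floor_k)
    return np.ceil(kl).astype(int)


def _ft_small(u: np.ndarray, w: np.ndarray, n_terms: int) -> np.ndarray:
    """Small-time series of the dimensionless lower-boundary FPT density."""
    u = np.asarray(u, dtype=float)
    k = np.arange(-n_terms, n_terms + 1)
    x = np.asarray(w)[..., None] + 2.0 * k  # (..., 2K+1)
    uu = u[..., None]
    terms = x * np.exp(-(x * x) / (2.0 * uu))
    return terms.sum(axis=-1) / np.sqrt(2.0 * np.pi * u ** 3)


def _ft_large(u: np.ndarray, w: np.ndarray, n_terms: int) -> np.ndarray:
    """Large-time series of the dimensionless lower-boundary FPT density."""
    u = np.asarray(u, dtype=float)
    k = np.arange(1, n_terms + 1)
    uu = u[..., None]
    ww = np.asarray(w)[..., None]
    terms = k * np.exp(-(k * k) * np.pi ** 2 * uu / 2.0) * np.sin(k * np.pi * ww)
    return np.pi * terms.sum(axis=-1)


def _ft_auto(u: np.ndarray, w: np.ndarray, eps: float = SERIES_EPS) -> np.ndarray:
    """Dimensionless density, switching expansions by predicted effort."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    w = np.broadcast_to(np.asarray(w, dtype=float), u.shape)
    out = np.zeros_like(u)
    pos = u > 0
    if not pos.any():
        return out
    up, wp = u[pos], w[pos]
    ks = _n_terms_small(up, eps)
    kl = _n_terms_large(up, eps)
    use_small = 2 * ks + 1 <= kl  # small-time sums 2k+1 terms
    vals = np.empty_like(up)
    if use_small.any():
        vals[use_small] = _ft_small(up[use_small], wp[use_small],
                                    int(ks[use_small].max()))
    if (~use_small).any():
        vals[~use_small] = _ft_large(up[~use_small], wp[~use_small],
                                     int(kl[~use_small].max()))
    out[pos] = vals
    return out


def _density_lower_core(t, v, w, a, sv=0.0):
    """Lower-boundary FPT density at decision time t (array-friendly).

    Normal drift variability (``sv``) is integrated in closed form: with
    v ~ N(v0, sv^2) the drift-dependent factor exp(-a w v - v^2 t / 2)
    averages to
    (1 + sv^2 t)^{-1/2} exp((a^2 w^2 sv^2 - 2 a w v0 - v0^2 t) / (2 (1 + sv^2 t))).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v = np.broadcast_to(np.asarray(v, dtype=float), t.shape)
    w = np.broadcast_to(np.asarray(w, dtype=float), t.shape)
    out = np.zeros_like(t)
    pos = t > 0
    if not pos.any():
        return out
    tp, vp, wp = t[pos], v[pos], w[pos]
    if sv > 0:
        denom = 1.0 + sv ** 2 * tp
        amp = np.exp((a ** 2 * wp ** 2 * sv ** 2 - 2.0 * a * wp * vp
                      - vp ** 2 * tp) / (2.0 * denom)) / np.sqrt(denom)
    else:
        amp = np.exp(-a * wp * vp - vp ** 2 * tp / 2.0)
    out[pos] = amp / a ** 2 * _ft_auto(tp / a ** 2, wp)
    return out


# ---------------------------------------------------------------------------
# cumulative distribution (defective: limits to the absorption probability)
# ---------------------------------------------------------------------------

#: scaled time below which the accumulated lower-boundary mass is < ~exp(-30)
def _u_negligible(w):
    return np.asarray(w) ** 2 / 60.0


_U_SERIES_MIN = 0.05  # below this, integrate the small-time density instead


def _cdf_lower_core(t, v, w, a):
    """Lower-boundary defective CDF at decision time t; no variability.

    Uses the term-by-term integral of the large-time series for the tail,
        F(t) = P_lower - (pi/a^2) e^{-v a w} sum_k k sin(k pi w) e^{-l_k t}/l_k,
    with l_k = (v^2 + (k pi / a)^2) / 2, and Gauss-Legendre integration of
    the small-time density when t/a^2 is too small for that series.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v = np.broadcast_to(np.asarray(v, dtype=float), t.shape).copy()
    w = np.broadcast_to(np.asarray(w, dtype=float), t.shape).copy()
    out = np.zeros_like(t)
    u = t / a ** 2
    live = u > _u_negligible(w)

    quad = live & (u < _U_SERIES_MIN)
    if quad.any():
        tq, vq, wq = t[quad], v[quad], w[quad]
        # nodes on [0, t]; density there is in the small-time regime
        s = 0.5 * tq[:, None] * (_CDF_QUAD_NODES[None, :] + 1.0)
        dens = _density_lower_core(s.ravel(), np.repeat(vq, s.shape[1]),
                                   np.repeat(wq, s.shape[1]), a)
        dens = dens.reshape(s.shape)
        out[quad] = 0.5 * tq * (dens @ _CDF_QUAD_WEIGHTS)

    ser = live & ~quad
    if ser.any():
        ts, vs, ws = t[ser], v[ser], w[ser]
        p_low = 1.0 - _p_upper_core(vs, ws, a)
        n_terms = int(_n_terms_large(_U_SERIES_MIN, 1e-10)) + 5
        k = np.arange(1, n_terms + 1)
        lam = (vs[:, None] ** 2 + (k[None, :] * np.pi / a) ** 2) / 2.0
        tail = (k[None, :] * np.sin(k[None, :] * np.pi * ws[:, None])
                * np.exp(-lam * ts[:, None]) / lam).sum(axis=1)
        f = p_low - np.pi / a ** 2 * np.exp(-vs * a * ws) * tail
        out[ser] = np.clip(f, 0.0, p_low)
    return out


def fpt_density(params: DDMParams, t, boundary: Boundary = "upper",
                rt: bool = False):
    """First-passage-time density at the named boundary.

    Parameters
    ----------
    params : DDMParams
    t : float or array
        Decision time (s); with ``rt=True``, observed response time, in
        which case non-decision time (t0, d, st0) is convolved in.
    boundary : {"upper", "lower"}
    rt : bool
        Interpret ``t`` as response time rather than decision time.

    Returns a defective density: each boundary's density integrates to its
    absorption probability.
    """
    upper = _check_boundary(boundary)
    if not np.all(np.isfinite(np.asarray(t, dtype=float))):
        raise ValueError("t must be finite")
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    # reflection: the upper-boundary problem is the lower-boundary problem
    # of the mirrored process (v -> -v, zr -> 1 - zr)
    sign = -1.0 if upper else 1.0
    w_nodes, w_weights = _zr_nodes(params)
    if upper:
        w_nodes = 1.0 - w_nodes
    t0_nodes, t0_weights = _t0_nodes(params, upper) if rt else (
        np.array([0.0]), np.array([1.0]))
    out = np.zeros_like(t)
    for t0i, t0w in zip(t0_nodes, t0_weights):
        for wi, ww in zip(w_nodes, w_weights):
            out += t0w * ww * _density_lower_core(
                t - t0i, sign * params.v, wi, params.a, sv=params.sv)
    return float(out[0]) if scalar else out


def fpt_cdf(params: DDMParams, t, boundary: Boundary = "upper",
            rt: bool = False):
    """Defective CDF of first passage at the named boundary.

    Nondecreasing in ``t``; its limit as t -> inf is the boundary's
    absorption probability.  Drift variability has no closed form at the
    CDF level and is integrated by Gauss-Hermite quadrature.
    """
    upper = _check_boundary(boundary)
    if not np.all(np.isfinite(np.asarray(t, dtype=float))):
        raise ValueError("t must be finite")
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    sign = -1.0 if upper else 1.0
    w_nodes, w_weights = _zr_nodes(params)
    if upper:
        w_nodes = 1.0 - w_nodes
    v_nodes, v_weights = _drift_nodes(params)
    t0_nodes, t0_weights = _t0_nodes(params, upper) if rt else (
        np.array([0.0]), np.array([1.0]))
    out = np.zeros_like(t)
    for t0i, t0w in zip(t0_nodes, t0_weights):
        for vi, vw in zip(v_nodes, v_weights):
            for wi, ww in zip(w_nodes, w_weights):
                out += t0w * vw * ww * _cdf_lower_core(
                    t - t0i, sign * vi, wi, params.a)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# exact trial simulation by conditional inverse-CDF
# ---------------------------------------------------------------------------

def _invert_cdf(targets, v, w, a, max_doublings=60, n_bisect=60):
    """Solve F_lower(t; v, w) = target per element by bracketed bisection."""
    t_lo = np.maximum(_u_negligible(w) * a ** 2, 1e-12)
    t_hi = np.full_like(targets, a ** 2)
    for _ in range(max_doublings):
        f_hi = _cdf_lower_core(t_hi, v, w, a)
        need = f_hi < targets
        if not need.any():
            break
        t_hi[need] *= 2.0
    for _ in range(n_bisect):
        mid = 0.5 * (t_lo + t_hi)
        f_mid = _cdf_lower_core(mid, v, w, a)
        go_up = f_mid < targets
        t_lo = np.where(go_up, mid, t_lo)
        t_hi = np.where(go_up, t_hi, mid)
    return 0.5 * (t_lo + t_hi)


def simulate_trials(params: DDMParams, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` trials exactly via conditional inverse-CDF sampling.

    Per trial, the effective starting point and drift are drawn from their
    inter-trial distributions, the boundary from the absorption probability,
    and the decision time by inverting the conditional first-passage CDF
    (vectorised bisection).  Returns ``(upper, rt)``: a boolean array (True
    for the upper/high-reward boundary) and response times in seconds.

    Reproducible: the same rng state and ``n`` yield identical draws.
    Variates are drawn in (4, n) blocks, so calls with different ``n`` are
    *not* prefix-consistent; reproducibility is per (state, n) pair.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    u = rng.random((4, n))
    w_i = params.zr + params.szr * (u[0] - 0.5)
    v_i = params.v + params.sv * _norm_ppf(u[1])
    p_up = _p_upper_core(v_i, w_i, params.a)
    upper = u[2] < p_up
    # reflect upper-choice trials onto the lower-boundary problem
    v_eff = np.where(upper, -v_i, v_i)
    w_eff = np.where(upper, 1.0 - w_i, w_i)
    p_hit = np.where(upper, p_up, 1.0 - p_up)
    targets = np.clip(u[3], 1e-12, 1.0 - 1e-12) * p_hit
    t_dec = _invert_cdf(targets, v_eff, w_eff, params.a)
    t0 = params.t0 + np.where(upper, 0.5 * params.d, -0.5 * params.d)
    if params.st0 > 0:
        t0 = t0 + params.st0 * (rng.random(n) - 0.5)
    return upper, t_dec + t0


def _norm_ppf(q):
    from scipy.special import ndtri
    return ndtri(q)


def simulate_trial(params: DDMParams, rng) -> tuple[str, float]:
    """Draw a single trial; returns (boundary name, response time)."""
    upper, t = simulate_trials(params, 1, rng)
    return ("upper" if upper[0] else "lower"), float(t[0])


def euler_maruyama_trials(params: DDMParams, n: int, rng, dt: float = 1e-4,
                          max_time: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate trials by Euler-Maruyama path discretisation.

    Slow and biased at O(sqrt(dt)) by boundary overshoot; retained purely as
    an independent oracle for the analytic densities and the exact sampler.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    w_i = params.zr + params.szr * (rng.random(n) - 0.5)
    v_i = params.v + params.sv * rng.standard_normal(n)
    x = params.a * w_i
    upper = np.zeros(n, dtype=bool)
    t_dec = np.full(n, np.nan)
    alive = np.arange(n)
    block = 400
    sqdt = np.sqrt(dt)
    step0 = 0
    while alive.size and step0 * dt < max_time:
        dx = v_i[alive][:, None] * dt + sqdt * rng.standard_normal((alive.size, block))
        path = x[alive][:, None] + np.cumsum(dx, axis=1)
        hit = (path >= params.a) | (path <= 0.0)
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        done = alive[any_hit]
        f = first[any_hit]
        upper[done] = path[any_hit, f] >= params.a
        t_dec[done] = (step0 + f + 1) * dt
        x[alive] = path[:, -1]
        alive = alive[~any_hit]
        step0 += block
    # censor never-absorbed paths (negligible mass) at max_time
    t_dec[np.isnan(t_dec)] = max_time
    t0 = params.t0 + np.where(upper, 0.5 * params.d, -0.5 * params.d)
    if params.st0 > 0:
        t0 = t0 + params.st0 * (rng.random(n) - 0.5)
    return upper, t_dec + t0
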