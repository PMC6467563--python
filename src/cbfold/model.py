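"""Multi-phase variational model of cerebellar folding initiation.

The cerebellum near E16.5 is idealised as a fluid-like external granule
layer (EGL) of thickness ``t(theta)`` riding on an incompressible core, the
outer surface at radius ``r(theta)`` from the section center.  Radial glia
and the pial membrane penalise radial excursions (stiffness ``k_r``),
proliferation supplies a growth potential on the EGL thickness (``k_t``),
and Bergmann-glia fibers resist thickness gradients (``beta``).  The energy

    E[r, t] = integral dtheta { k_r (r - r0)^2 - k_t (t - t0)^2
                                + beta (dt/dtheta)^2 }

is made stationary subject to the incompressible-core constraint
``(1/2) integral (r - t)^2 dtheta = A0`` (Lagrange multiplier ``mu``) and a
fixed mean EGL thickness ``t0`` (set by the uniform proliferation rate).
Stationarity gives a driven harmonic oscillator for ``t`` whose solutions
are sinusoids,

    t(theta) = At sin(q theta + phi) + t0,
    r(theta) = -(eps / (1 - eps)) At sin(q theta + phi) + C3,
    C3 = (r0 - eps t0) / (1 - eps),      eps = mu / k_r,

so that for 0 < eps < 1 the thickness and surface-height oscillations are
exactly out of phase (the EGL is thickest where the surface is lowest, at
the anchoring centers) and the amplitude ratio is Ar/At = eps/(1 - eps) --
the opposite phase relation, and a far milder amplitude hierarchy, than
elastic bilayer wrinkling.

The dimensionless parameterisation calibrated at E16.5 is

    c = k_r / k_t = 0.06 / eps,  At / r0 = eps / 9.6,
    t0 / r0 = eps / 4.8,         q = 6,

which at eps = 0.3 reproduces the measured At/t0 = 0.5 and r0/t0 = 16 and
the three invaginations of the semicircular half section (q/2 = 3).  The
time course is eps(T) = 0.3 (T - 15.5) with T in embryonic days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from cbfold.contour import Contour, SectionGeometry

EPSILON_RATE_PER_DAY = 0.3
EPSILON_ONSET_DAY = 15.5
#: c * eps = (k_r/k_t) * (mu/k_r) = mu/k_t is held constant by the mapping.
MU_OVER_KT = 0.06
AT_SLOPE = 1.0 / 9.6  # At/r0 per unit eps
T0_SLOPE = 1.0 / 4.8  # t0/r0 per unit eps
DEFAULT_Q = 6.0
#: t0/r0 used for the degenerate eps = 0 (unfolded annulus) limit, where the
#: eps-linear mapping would give zero thickness; this is the E16.5 ratio.
ANNULUS_T0_OVER_R0 = 1.0 / 16.0


class ModelDomainError(ValueError):
    """Raised when parameters leave the model's validity domain."""


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter set of the multi-phase model (plus scale r0)."""

    epsilon: float  # mu / k_r, the time-like control parameter
    c: float  # k_r / k_t
    at_over_r0: float  # thickness oscillation amplitude / preferred radius
    t0_over_r0: float  # preferred EGL thickness / preferred radius
    q: float = DEFAULT_Q  # angular wavenumber
    phi: float = 0.0  # phase (radians)
    r0: float = 1.0  # preferred radius, um (1 = dimensionless mode)

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 1.0:
            raise ModelDomainError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if self.c <= 0 or self.t0_over_r0 <= 0 or self.r0 <= 0:
            raise ModelDomainError("c, t0/r0 and r0 must be positive")
        if self.at_over_r0 < 0:
            raise ModelDomainError("At/r0 must be >= 0")
        if self.q <= 0:
            raise ModelDomainError("q must be positive")

    @property
    def at(self) -> float:
        """Thickness oscillation amplitude At (um)."""
        return self.at_over_r0 * self.r0

    @property
    def t0(self) -> float:
        """Preferred (mean) EGL thickness t0 (um)."""
        return self.t0_over_r0 * self.r0

    @property
    def mu_over_kt(self) -> float:
        return self.epsilon * self.c

    def physical(self, kt: float = 1.0, q_convention: str = "derived") -> dict:
        """Dimensional coefficients {k_r, k_t, beta, mu, r0, t0, At}.

        ``k_t`` sets the energy scale; ``beta`` is calibrated so the shape
        equation selects wavenumber ``q`` under the chosen ``q_convention``
        (see :func:`wavenumber_squared`).
        """
        kr = self.c * kt
        mu = self.epsilon * kr
        q2 = wavenumber_squared(1.0, self.mu_over_kt, self.epsilon, q_convention)
        beta = kt * q2 / self.q**2
        return {
            "k_r": kr,
            "k_t": kt,
            "beta": beta,
            "mu": mu,
            "r0": self.r0,
            "t0": self.t0,
            "At": self.at,
        }


def params_from_epsilon(
    epsilon: float, r0: float = 1.0, phi: float = 0.0, q: float = DEFAULT_Q
) -> ModelParams:
    """Map the time-like parameter eps through the E16.5-calibrated relations.

    c = 0.06/eps, At/r0 = eps/9.6, t0/r0 = eps/4.8, q = 6.  The ratio
    At/t0 = 0.5 is independent of eps; at eps = 0.3 also r0/t0 = 16.
    """
    if not 0.0 < epsilon < 1.0:
        raise ModelDomainError(f"epsilon must be in (0, 1), got {epsilon}")
    return ModelParams(
        epsilon=epsilon,
        c=MU_OVER_KT / epsilon,
        at_over_r0=AT_SLOPE * epsilon,
        t0_over_r0=T0_SLOPE * epsilon,
        q=q,
        phi=phi,
        r0=r0,
    )


def annulus_params(r0: float = 1.0, t0_over_r0: float = ANNULUS_T0_OVER_R0) -> ModelParams:
    """Degenerate eps = 0 parameters: a circle of radius r0 with a uniform
    EGL annulus of thickness ``t0_over_r0 * r0`` (default 1/16, the E16.5
    measured ratio, since the eps-linear thickness map vanishes at eps = 0)."""
    return ModelParams(
        epsilon=0.0, c=1.0, at_over_r0=0.0, t0_over_r0=t0_over_r0, r0=r0
    )


def epsilon_of_time(stage: float) -> float:
    """Linear time course eps(T) = 0.3 (T - 15.5), T in embryonic days."""
    eps = EPSILON_RATE_PER_DAY * (stage - EPSILON_ONSET_DAY)
    if eps < 0:
        raise ModelDomainError(f"stage {stage} is before the eps = 0 onset (E{EPSILON_ONSET_DAY})")
    if eps >= 1.0:
        bound = EPSILON_ONSET_DAY + 1.0 / EPSILON_RATE_PER_DAY
        raise ModelDomainError(
            f"stage {stage} gives eps = {eps:.3g} >= 1; the model is only valid for "
            f"eps < 1, i.e. stages below E{bound:.3g}"
        )
    return eps


def amplitude_ratio(epsilon: float) -> float:
    """Surface-height to thickness oscillation amplitude ratio Ar/At = eps/(1-eps)."""
    if not 0.0 <= epsilon < 1.0:
        raise ModelDomainError(f"epsilon must be in [0, 1), got {epsilon}")
    return epsilon / (1.0 - epsilon)


def wavenumber_squared(
    kt_over_beta: float, mu_over_kt: float, epsilon: float, convention: str = "printed"
) -> float:
    """Squared wavenumber selected by the shape equation.

    Two conventions are provided and neither is silently preferred:

    * ``printed``: q^2 = (k_t/beta) (1 + mu/k_t) / (1 - eps)
    * ``derived``: q^2 = (k_t/beta) ((1 - eps) + mu/k_t) / (1 - eps), the form
      a direct Euler-Lagrange elimination of r yields; it is the one under
      which the analytic sinusoid is exactly stationary (the numerical oracle
      in :mod:`cbfold.oracle` agrees with it).
    """
    if convention == "printed":
        return kt_over_beta * (1.0 + mu_over_kt) / (1.0 - epsilon)
    if convention == "derived":
        return kt_over_beta * ((1.0 - epsilon) + mu_over_kt) / (1.0 - epsilon)
    raise ValueError(f"unknown q^2 convention {convention!r}")


def fold_count_formula(
    kt_over_beta: float, mu_over_kt: float, epsilon: float, convention: str = "printed"
) -> float:
    """Number of initial folds n = sqrt(q^2) from the shape equation; depends
    only on material ratios, not on any length scale."""
    return math.sqrt(wavenumber_squared(kt_over_beta, mu_over_kt, epsilon, convention))


@dataclass(frozen=True)
class ModelShape:
    """Sampled model solution: t(theta), r(theta), inner boundary r - t."""

    theta: np.ndarray
    t: np.ndarray
    r: np.ndarray
    c1: float
    c3: float
    a0: float  # core area implied by the shape, (1/2) integral (r-t)^2
    domain: str  # "full" | "half"
    params: ModelParams

    @property
    def inner(self) -> np.ndarray:
        return self.r - self.t

    def scaled(self, factor: float) -> "ModelShape":
        """Rescale all lengths by ``factor`` (areas scale by factor^2)."""
        return ModelShape(
            theta=self.theta,
            t=self.t * factor,
            r=self.r * factor,
            c1=self.c1 * factor,
            c3=self.c3 * factor,
            a0=self.a0 * factor**2,
            domain=self.domain,
            params=replace(self.params, r0=self.params.r0 * factor),
        )


def _theta_grid(n_theta: int, domain: str) -> np.ndarray:
    if domain == "full":
        return np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    if domain == "half":
        return np.linspace(0.0, np.pi, n_theta)
    raise ValueError(f"unknown domain {domain!r}")


def model_shape(params: ModelParams, n_theta: int = 720, domain: str = "full") -> ModelShape:
    """Sample the analytic model solution on a theta grid.

    ``t = At sin(q theta + phi) + t0`` (mean thickness pinned at t0) and
    ``r = -(eps/(1-eps)) At sin(q theta + phi) + C3`` with
    ``C3 = (r0 - eps t0)/(1-eps)`` from the radial stationarity relation.
    In the eps -> 0 limit the shape is the preferred circle plus annulus.

    Half-domain solutions live on theta in [0, pi] with zero-slope (Neumann)
    thickness boundary conditions, which requires cos(phi) = 0; use
    phi = -pi/2 to put a thickness maximum (an AC) at the domain midpoint.
    """
    if n_theta < 16 * params.q:
        raise ValueError(f"n_theta must be >= 16 q = {16 * params.q:.0f}")
    if domain == "half" and params.at_over_r0 > 0:
        if not math.isclose(math.cos(params.phi), 0.0, abs_tol=1e-9):
            raise ModelDomainError(
                "half-domain solutions need zero-slope thickness ends: "
                "phi must be +/- pi/2 (mod pi); use phi = -pi/2"
            )
        if (params.q / 2.0) != int(params.q / 2.0):
            raise ModelDomainError("half-domain solutions need an even integer q")
    theta = _theta_grid(n_theta, domain)
    eps = params.epsilon
    osc = np.sin(params.q * theta + params.phi) if params.at > 0 else np.zeros_like(theta)
    c1 = params.t0
    c3 = (params.r0 - eps * params.t0) / (1.0 - eps)
    t = params.at * osc + c1
    r = -(eps / (1.0 - eps)) * params.at * osc + c3
    if np.any(t <= 0):
        raise ModelDomainError("parameters give non-positive EGL thickness")
    if np.any(r - t <= 0):
        raise ModelDomainError("parameters give non-positive inner (core) radius")
    a0 = core_area(theta, r, t, periodic=(domain == "full"))
    return ModelShape(theta=theta, t=t, r=r, c1=c1, c3=c3, a0=a0, domain=domain, params=params)


# ---------------------------------------------------------------------------
# Quadrature of the energy functional and the core-area constraint


def _check_grid(theta: np.ndarray, *fields: np.ndarray) -> None:
    theta = np.asarray(theta)
    d = np.diff(theta)
    if len(theta) < 4 or not np.allclose(d, d[0]):
        raise ValueError("theta must be a uniform grid with >= 4 points")
    for f in fields:
        if np.shape(f) != theta.shape:
            raise ValueError("field sampled on a different grid than theta")


def _integrate(theta: np.ndarray, values: np.ndarray, periodic: bool) -> float:
    dtheta = theta[1] - theta[0]
    if periodic:
        return float(values.sum() * dtheta)
    return float(np.trapezoid(values, dx=dtheta))


def _dtheta_derivative(theta: np.ndarray, values: np.ndarray, periodic: bool) -> np.ndarray:
    if periodic:
        n = len(theta)
        period = n * (theta[1] - theta[0])
        k = 2.0 * np.pi * np.fft.rfftfreq(n, d=period / n)
        return np.fft.irfft(1j * k * np.fft.rfft(values), n=n)
    return np.gradient(values, theta)


def energy_functional(
    theta: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    k_r: float,
    k_t: float,
    beta: float,
    r0: float,
    t0: float,
    periodic: bool = True,
) -> float:
    """E = integral { k_r (r-r0)^2 - k_t (t-t0)^2 + beta (dt/dtheta)^2 } dtheta.

    Rectangle-rule quadrature (spectrally exact for trigonometric fields) on
    periodic grids, trapezoid otherwise; dt/dtheta is spectral on periodic
    grids and second-order finite differences otherwise.
    """
    _check_grid(theta, r, t)
    dt = _dtheta_derivative(theta, t, periodic)
    integrand = k_r * (r - r0) ** 2 - k_t * (t - t0) ** 2 + beta * dt**2
    return _integrate(theta, integrand, periodic)


def core_area(theta: np.ndarray, r: np.ndarray, t: np.ndarray, periodic: bool = True) -> float:
    """Core area in the polar measure: (1/2) integral (r - t)^2 dtheta."""
    _check_grid(theta, r, t)
    return _integrate(theta, 0.5 * (r - t) ** 2, periodic)


def euler_lagrange_residuals(shape: ModelShape, kt: float = 1.0, q_convention: str = "derived"):
    """Pointwise stationarity residuals of a sampled shape.

    Returns ``(res_r, res_t)`` where ``res_r = k_r (r - r0) - mu (r - t)``
    must vanish identically and ``res_t = beta t'' + k_t (t - t0) - mu (r - t)``
    must be constant (the constant is the multiplier of the fixed-mean-
    thickness condition); the returned ``res_t`` has that constant removed.
    Both are normalised by ``k_r * r0``.
    """
    p = shape.params.physical(kt=kt, q_convention=q_convention)
    periodic = shape.domain == "full"
    if periodic:
        tpp = _dtheta_derivative(shape.theta, _dtheta_derivative(shape.theta, shape.t, True), True)
    else:
        # phi = +/- pi/2 solutions are even about both ends: even extension
        ext_theta = np.concatenate([shape.theta, shape.theta[1:] + np.pi])
        ext_t = np.concatenate([shape.t, shape.t[-2::-1]])
        tpp = np.gradient(np.gradient(ext_t, ext_theta), ext_theta)[: len(shape.theta)]
    res_r = p["k_r"] * (shape.r - p["r0"]) - p["mu"] * (shape.r - shape.t)
    res_t = p["beta"] * tpp + p["k_t"] * (shape.t - p["t0"]) - p["mu"] * (shape.r - shape.t)
    res_t = res_t - res_t.mean()
    scale = p["k_r"] * p["r0"]
    return res_r / scale, res_t / scale


# ---------------------------------------------------------------------------
# Fold counting


def fold_count_model(shape_or_params, n_theta: int = 1440) -> int:
    """Count strict local maxima of t(theta): q folds on the full circle,
    q/2 on the half domain."""
    if isinstance(shape_or_params, ModelParams):
        shape = model_shape(shape_or_params, n_theta=n_theta, domain="full")
    elif isinstance(shape_or_params, ModelShape):
        shape = shape_or_params
    else:
        raise TypeError("expected ModelParams or ModelShape")
    t = shape.t
    if shape.domain == "full":
        prev = np.roll(t, 1)
        nxt = np.roll(t, -1)
        return int(np.sum((t > prev) & (t > nxt)))
    if shape.domain != "half":
        raise ValueError("fold counting needs a periodic domain or Neumann half domain")
    interior = (t[1:-1] > t[:-2]) & (t[1:-1] > t[2:])
    count = int(np.sum(interior))
    # Neumann ends: an endpoint above its neighbour is a (half-)fold maximum
    count += int(t[0] > t[1]) + int(t[-1] > t[-2])
    return count


# ---------------------------------------------------------------------------
# Bridges to section geometry and the stage series


def shape_to_section(shape: ModelShape, n_points: int | None = None) -> SectionGeometry:
    """Convert a half-domain model shape into a SectionGeometry.

    The outer EGL contour is (r cos, r sin) over theta in [0, pi] traversed
    anterior (theta = 0) to posterior, the inner contour is r - t, the base
    joins the inner endpoints along the diameter, and AC positions are the
    arc-length coordinates of the thickness maxima along the inner contour.
    """
    if shape.domain != "half":
        raise ValueError("only half-domain shapes map to sections")
    theta, t, r = shape.theta, shape.t, shape.r
    if n_points is not None and n_points != len(theta):
        theta_new = np.linspace(0.0, np.pi, n_points)
        t = np.interp(theta_new, theta, t)
        r = np.interp(theta_new, theta, r)
        theta = theta_new
    rho = r - t
    outer = Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    inner = Contour(np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))
    # thickness maxima along theta -> arc length along the inner contour
    tmax = np.where((t[1:-1] > t[:-2]) & (t[1:-1] > t[2:]))[0] + 1
    s_inner = inner.arclength_coords
    ac_positions = s_inner[tmax]
    base = np.array([inner.points[-1], inner.points[0]])
    try:
        stage = EPSILON_ONSET_DAY + shape.params.epsilon / EPSILON_RATE_PER_DAY
    except ZeroDivisionError:  # pragma: no cover
        stage = float("nan")
    return SectionGeometry(
        outer_egl=outer, inner_egl=inner, base=base,
        ac_positions=ac_positions, stage=stage,
    )


def section_shape_factor(section: SectionGeometry) -> float:
    """Shape factor of a half section measured from its contours: outer arc
    length over sqrt(area enclosed by the outer arc and the base)."""
    from cbfold.morphometrics import shape_factor

    area = section.cerebellar_polygon().area
    return shape_factor(section.outer_egl, area)


def predict_stage_series(
    stages, r0: float = 1.0, n_theta: int = 1441
) -> list[tuple[float, ModelShape, float]]:
    """Model prediction across embryonic days.

    For each stage: eps(T) -> calibrated parameters -> half-domain shape
    (phi = -pi/2, AC at the top) -> shape factor measured from the sampled
    contours.  Returns a list of (stage, shape, shape_factor).
    """
    out = []
    for stage in stages:
        eps = epsilon_of_time(stage)
        if eps == 0.0:
            params = annulus_params(r0=r0)
        else:
            params = params_from_epsilon(eps, r0=r0, phi=-math.pi / 2.0)
        shape = model_shape(params, n_theta=n_theta, domain="half")
        sf = section_shape_factor(shape_to_section(shape))
        out.append((stage, shape, sf))
    return out
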