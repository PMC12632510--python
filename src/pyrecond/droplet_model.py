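"""Reduced quasi-steady single-droplet model with chemical switching.

A dense condensate of sticky protein (equilibrium volume fraction phi_plus)
sits in a dilute bath (phi_minus).  Outside and inside, the linearized
screened-diffusion equation

    0 = lap(phi) - phi + k_drop (1 - phi)

holds, in units of the length ell = sqrt(D / k_{s->ns}) and time
t_c = ell^2 / D.  NOTE on conventions: the droplet model's switching ratio
``k_drop = k_{ns->s} / k_{s->ns}`` is the *reciprocal* of the full model's
``k_tilde = k_{s->ns} / k_{ns->s}``; the two are kept as distinctly named
fields with explicit converters because confusing them inverts every regime
boundary.

With spherical symmetry, regularity at the origin and a no-flux far field,
the concentration profiles are screened exponentials; matching them to the
fixed interface values phi_plus / phi_minus yields the interface mass
balance (the droplet-radius ODE).  Below a critical switching ratio
``k_c ~ (phi_plus + phi_minus) / (2 - phi_plus - phi_minus)`` the ODE has a
stable fixed point (an equilibrium radius, i.e. condensate size control);
above it the droplet grows without bound.  A 2-D (cylindrically symmetric)
variant using modified Bessel functions is provided for tighter comparison
against the 2-D phase-field simulations; the 3-D form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Literal, Optional, Tuple

import numpy as np
from scipy import optimize, special


@dataclass(frozen=True)
class DropletParams:
    """Parameters of the reduced droplet model (dimensionless unless noted).

    phi_plus / phi_minus  dense / dilute equilibrium volume fractions
    phi_inf               far-field fraction (passive limit only; optional)
    k_drop                k_{ns->s}/k_{s->ns} (reciprocal of the full model's
                          k_tilde)
    geometry              "3d" spherical (default) or "2d" cylindrical
    """

    phi_plus: float
    phi_minus: float
    k_drop: float
    phi_inf: Optional[float] = None
    geometry: Literal["3d", "2d"] = "3d"

    def __post_init__(self):
        if not (0.0 <= self.phi_minus < self.phi_plus <= 1.0):
            raise ValueError("require 0 <= phi_minus < phi_plus <= 1")
        if self.k_drop < 0:
            raise ValueError("k_drop must be >= 0")

    @property
    def beta(self) -> float:
        """Inverse screening length sqrt(1 + k_drop)."""
        return float(np.sqrt(1.0 + self.k_drop))

    @property
    def phi_far(self) -> float:
        """Far-field switching balance k_drop/(1 + k_drop)."""
        return self.k_drop / (1.0 + self.k_drop)


def k_drop_from_k_tilde(k_tilde: float) -> float:
    """Convert the full model's kinase/phosphatase ratio to the droplet
    model's phosphatase/kinase ratio."""
    if k_tilde <= 0:
        raise ValueError("k_tilde must be > 0 to define its reciprocal")
    return 1.0 / k_tilde


def k_tilde_from_k_drop(k_drop: float) -> float:
    if k_drop <= 0:
        raise ValueError("k_drop must be > 0 to define its reciprocal")
    return 1.0 / k_drop


@dataclass
class DropletFixedPoints:
    """Roots of the radius ODE with their local stability and the regime."""

    fixed_points: List[Tuple[float, str]]    # (R_tilde, "stable"|"unstable")
    regime: str                              # size_controlled | unbounded_growth | full_dissolution

    @property
    def stable_radius(self) -> Optional[float]:
        for r, s in self.fixed_points:
            if s == "stable":
                return r
        return None


# --------------------------------------------------------------------- #
# concentration profiles
# --------------------------------------------------------------------- #
def profiles(R_tilde: float, params: DropletParams
             ) -> Tuple[Callable, Callable]:
    """Quasi-steady profiles phi_in(r), phi_out(r) for a droplet of radius R.

    Both satisfy 0 = lap(phi) - (1+k) phi + k; phi_in is regular at r=0 and
    equals phi_plus at R; phi_out decays to k/(1+k) far away and equals
    phi_minus at R.
    """
    if R_tilde <= 0:
        raise ValueError("R_tilde must be > 0")
    b = params.beta
    pf = params.phi_far
    dp, dm = params.phi_plus - pf, params.phi_minus - pf
    if params.geometry == "3d":

        def phi_in(r):
            r = np.asarray(r, dtype=float)
            # sinh(b r)/r -> b as r -> 0; analytic continuation past R is
            # returned as-is (used by finite-difference cross-checks)
            ratio = np.where(r > 0, np.sinh(b * r) / np.where(r > 0, r, 1.0), b)
            return pf + dp * R_tilde * ratio / np.sinh(b * R_tilde)

        def phi_out(r):
            r = np.asarray(r, dtype=float)
            return pf + dm * (R_tilde / r) * np.exp(b * (R_tilde - r))

    else:  # 2-D cylindrical: I0 inside, K0 outside

        def phi_in(r):
            r = np.asarray(r, dtype=float)
            return pf + dp * special.i0(b * r) / special.i0(b * R_tilde)

        def phi_out(r):
            r = np.asarray(r, dtype=float)
            return pf + dm * special.k0(b * r) / special.k0(b * R_tilde)

    return phi_in, phi_out


def _profile_slopes(R: float, params: DropletParams) -> Tuple[float, float]:
    """Analytic d(phi)/dr of both profiles at the interface r=R."""
    b = params.beta
    dp = params.phi_plus - params.phi_far
    dm = params.phi_minus - params.phi_far
    if params.geometry == "3d":
        slope_in = dp * (b / np.tanh(b * R) - 1.0 / R)
        slope_out = dm * (-b - 1.0 / R)
    else:
        # exponentially scaled Bessel ratios (overflow-safe at large b*R)
        slope_in = dp * b * special.i1e(b * R) / special.i0e(b * R)
        slope_out = -dm * b * special.k1e(b * R) / special.k0e(b * R)
    return float(slope_in), float(slope_out)


def radius_rate(R_tilde: float, params: DropletParams) -> float:
    """dR/dt from the interfacial mass balance of the two profile fluxes.

    The diffusive flux density is J = -grad(phi); the interface advances at
    n.(J_in - J_out)/(phi_in - phi_out) = (phi_out' - phi_in')/(phi_+ - phi_-).
    """
    if params.phi_plus == params.phi_minus:
        raise ZeroDivisionError("degenerate phases: phi_plus == phi_minus")
    if R_tilde <= 0:
        raise ValueError("R_tilde must be > 0")
    slope_in, slope_out = _profile_slopes(R_tilde, params)
    return (slope_out - slope_in) / (params.phi_plus - params.phi_minus)


def interface_fluxes(R_tilde: float, params: DropletParams) -> Tuple[float, float]:
    """Total fluxes (area x density) just inside / outside the interface.

    Defined as J_i = -(surface area) * d(phi_i)/dr at r=R; in the
    size-controlled regime the small-R expansions scale as R^3 (inner, the
    bath converting to sticky inside) and as R^2 + R/beta (outer).
    """
    slope_in, slope_out = _profile_slopes(R_tilde, params)
    area = 4.0 * np.pi * R_tilde**2 if params.geometry == "3d" \
        else 2.0 * np.pi * R_tilde
    return -area * slope_in, -area * slope_out


def flux_scaling_exponents(params: DropletParams,
                           r_window: Tuple[float, float] = (0.05, 0.3),
                           n: int = 40) -> Tuple[float, float]:
    """Log-log fitted exponents of |J_in| and |J_out| over a radius window."""
    r = np.geomspace(r_window[0], r_window[1], n)
    jin = np.empty(n)
    jout = np.empty(n)
    for i, ri in enumerate(r):
        jin[i], jout[i] = interface_fluxes(ri, params)
    e_in = np.polyfit(np.log(r), np.log(np.abs(jin)), 1)[0]
    e_out = np.polyfit(np.log(r), np.log(np.abs(jout)), 1)[0]
    return float(e_in), float(e_out)


def fixed_points(params: DropletParams,
                 R_range: Tuple[float, float] = (1e-3, 1e3),
                 n_scan: int = 600) -> DropletFixedPoints:
    """All roots of radius_rate in ``R_range`` with stability and regime."""
    lo, hi = R_range
    if not (0 < lo < hi):
        raise ValueError("R_range must be a positive interval")
    R = np.geomspace(lo, hi, n_scan)
    rate = np.array([radius_rate(r, params) for r in R])
    fps: List[Tuple[float, str]] = []
    for i in range(n_scan - 1):
        if np.sign(rate[i]) * np.sign(rate[i + 1]) < 0:
            root = optimize.brentq(lambda r: radius_rate(r, params),
                                   R[i], R[i + 1], rtol=1e-10)
            eps = 1e-6 * root
            slope = (radius_rate(root + eps, params)
                     - radius_rate(root - eps, params)) / (2 * eps)
            fps.append((float(root), "stable" if slope < 0 else "unstable"))
    if any(s == "stable" for _, s in fps):
        regime = "size_controlled"
    elif rate[-1] > 0:
        regime = "unbounded_growth"
    else:
        regime = "full_dissolution"
    return DropletFixedPoints(fixed_points=fps, regime=regime)


def critical_ratio(phi_plus: float, phi_minus: float,
                   method: str = "closed_form",
                   geometry: str = "3d") -> float:
    """Critical switching ratio k_c separating size control from unbounded
    growth.

    ``closed_form`` evaluates (phi_+ + phi_-)/(2 - phi_+ - phi_-), the
    large-R limit of the radius ODE; ``numeric`` bisects on the existence of
    a stable fixed point of the full rate.
    """
    if method == "closed_form":
        return (phi_plus + phi_minus) / (2.0 - phi_plus - phi_minus)
    if method != "numeric":
        raise ValueError("method must be 'closed_form' or 'numeric'")

    def has_stable_fp(k):
        p = DropletParams(phi_plus=phi_plus, phi_minus=phi_minus,
                          k_drop=k, geometry=geometry)
        return fixed_points(p, (1e-3, 1e4), n_scan=400).stable_radius is not None

    # a stable droplet needs a supersaturated far field: phi_far > phi_minus,
    # i.e. k_drop > phi_minus/(1 - phi_minus); start just above that floor
    k_lo = 2.0 * phi_minus / (1.0 - phi_minus)
    k_hi = 1e4
    if not has_stable_fp(k_lo):
        raise ValueError("no size-controlled regime found at small k_drop")
    if has_stable_fp(k_hi):
        raise ValueError("size control persists at the top of the scan range")
    for _ in range(60):
        mid = np.sqrt(k_lo * k_hi)
        if has_stable_fp(mid):
            k_lo = mid
        else:
            k_hi = mid
        if k_hi / k_lo < 1 + 1e-6:
            break
    return float(np.sqrt(k_lo * k_hi))


def passive_growth(R_init_tilde: float, params: DropletParams,
                   t_tilde) -> np.ndarray:
    """Diffusion-limited growth without switching:
    R^2 = R_init^2 + 2 (phi_inf - phi_minus)/(phi_plus - phi_minus) t.

    Requires ``params.phi_inf``; if the far field is undersaturated
    (phi_inf < phi_minus) the droplet shrinks and the returned radii hit
    zero at the dissolution time (clipped there).
    """
    if params.phi_inf is None:
        raise ValueError("passive growth requires phi_inf")
    if params.k_drop != 0:
        raise ValueError("passive growth is defined for k_drop = 0")
    t = np.asarray(t_tilde, dtype=float)
    c = 2.0 * (params.phi_inf - params.phi_minus) / (params.phi_plus - params.phi_minus)
    r2 = R_init_tilde**2 + c * t
    return np.sqrt(np.clip(r2, 0.0, None))


def passive_growth_ode(R_init_tilde: float, params: DropletParams,
                       t_tilde) -> np.ndarray:
    """Independent check: integrate dR/dt = (phi_inf - phi_minus) /
    ((phi_plus - phi_minus) R) by quadrature-free ODE stepping."""
    from scipy.integrate import solve_ivp

    if params.phi_inf is None:
        raise ValueError("requires phi_inf")
    c = (params.phi_inf - params.phi_minus) / (params.phi_plus - params.phi_minus)
    t = np.atleast_1d(np.asarray(t_tilde, dtype=float))
    sol = solve_ivp(lambda _, r: c / np.maximum(r, 1e-12), (0.0, float(t.max())),
                    [R_init_tilde], t_eval=t, rtol=1e-10, atol=1e-12)
    return sol.y[0]
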