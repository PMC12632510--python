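"""Growth-rate spectrum of perturbations about the uniform state.

Perturbing (phi_s, phi_ns) = (phi_s0, phi_ns0) + (a_s, a_ns) exp(i q x +
omega t) and linearizing the kinetic equations yields a 2x2 eigenvalue
problem omega = eig(M(q)).  The Jacobian is assembled analytically:

    M(q) = -q^2 D [[phi_s0*mu_ss + kappa_s q^2 phi_s0,  phi_s0*(mu_x + q^2)],
                   [phi_ns0*(mu_x + q^2), phi_ns0*mu_nn + kappa_ns q^2 phi_ns0]]
           + [[-k, 1], [k, -1]]

with mu_ss = 1/phi_s0 + 1/phi_sol0 - 2 chi, mu_x = 1/phi_sol0,
mu_nn = 1/phi_ns0 + 1/phi_sol0 (products with phi_i0 are expanded so the
k=0, phi_ns0=0 limit is regular).  Eigenvalues are computed numerically from
this matrix rather than from a transcription of the closed-form dispersion
polynomial, and validated against its exact q->0 limits: the branches at
q=0 are {0, -(1+k)} (conserved mass mode and switching relaxation mode).

Classification of the phase behavior follows the amplification curve:
``uniform_stable`` if no mode grows; ``arrested_candidate`` if some mode
grows while the upper branch is negatively convex at q=0 (small-q modes
suppressed, so coarsening may arrest at a finite wavelength);
``continued_coarsening`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model_core import ModelParams, uniform_steady_state


@dataclass
class DispersionResult:
    """Both growth-rate branches on a wavenumber grid plus the diagnostics
    used for classification."""

    q_grid: np.ndarray
    omega: np.ndarray            # shape (n_q, 2), branches sorted descending
    omega_max: float
    q_max: float
    lambda_max: float            # 2*pi/q_max (inf when nothing grows)
    curvature0: float            # d^2 omega/dq^2 of the upper branch at q=0
    classification: str


def _jacobian(params: ModelParams, q2):
    """Stacked 2x2 Jacobians M(q) for an array of q^2 values."""
    phi_s0, phi_ns0 = uniform_steady_state(params.phi_tot, params.k_tilde)
    phi_sol0 = 1.0 - params.phi_tot
    q2 = np.atleast_1d(np.asarray(q2, dtype=float))
    D, k = params.D_tilde, params.k_tilde
    # products phi_i0 * d(mu_i)/d(phi_j), written to stay finite at phi_ns0=0
    s_mu_ss = 1.0 + phi_s0 / phi_sol0 - 2.0 * params.chi * phi_s0
    s_mu_x = phi_s0 / phi_sol0
    ns_mu_x = phi_ns0 / phi_sol0
    ns_mu_nn = 1.0 + phi_ns0 / phi_sol0
    M = np.empty(q2.shape + (2, 2))
    M[..., 0, 0] = -q2 * D * (s_mu_ss + params.kappa_s_tilde * q2 * phi_s0) - k
    M[..., 0, 1] = -q2 * D * (s_mu_x + q2 * phi_s0) + 1.0
    M[..., 1, 0] = -q2 * D * (ns_mu_x + q2 * phi_ns0) + k
    M[..., 1, 1] = -q2 * D * (ns_mu_nn + params.kappa_ns_tilde * q2 * phi_ns0) - 1.0
    return M


def dispersion(params: ModelParams, q_tilde) -> np.ndarray:
    """Real parts of the two growth-rate branches at wavenumber(s) q_tilde.

    Returns an array of shape (..., 2) with branches sorted descending.
    """
    q = np.atleast_1d(np.asarray(q_tilde, dtype=float))
    if np.any(q < 0):
        raise ValueError("q_tilde must be >= 0")
    M = _jacobian(params, q**2)
    w = np.linalg.eigvals(M)
    w = np.sort(w.real, axis=-1)[..., ::-1]
    if np.isscalar(q_tilde) or np.ndim(q_tilde) == 0:
        return w[0]
    return w


def _upper(params: ModelParams, q):
    return dispersion(params, np.atleast_1d(q))[..., 0]


def classify(params: ModelParams, q_max_scan: float = None,
             n_scan: int = 400) -> DispersionResult:
    """Scan the amplification curve and classify the phase behavior."""
    if q_max_scan is None:
        # the kappa q^4 terms guarantee decay beyond q ~ sqrt(2 chi / kappa)
        q_max_scan = 2.0 * np.sqrt(
            max(2.0 * params.chi, 1.0) / min(params.kappa_s_tilde, 1.0))
    q_grid = np.linspace(0.0, q_max_scan, n_scan)
    omega = dispersion(params, q_grid)
    # the conserved-mass mode pins omega(0)=0 exactly; the stability question
    # concerns q > 0, so exclude the first grid point from the maximum
    upper = omega[:, 0].copy()
    upper[0] = -np.inf
    i_best = int(np.argmax(upper))
    omega_max, q_max = float(upper[i_best]), float(q_grid[i_best])
    if 0 < i_best < n_scan - 1:
        res = optimize.minimize_scalar(
            lambda q: -_upper(params, q)[0],
            bounds=(q_grid[i_best - 1], q_grid[i_best + 1]), method="bounded")
        q_max = float(res.x)
        omega_max = float(-res.fun)
    # curvature at q=0 of the upper branch: Richardson-extrapolated second
    # difference using omega(0)=0 exactly (conserved mass mode)
    h = 1e-3
    w_h = _upper(params, h)[0]
    w_2h = _upper(params, 2 * h)[0]
    c_h = 2.0 * w_h / h**2          # from omega ~ (c/2) q^2
    c_2h = 2.0 * w_2h / (2 * h) ** 2
    curvature0 = float((4.0 * c_h - c_2h) / 3.0)
    if omega_max <= 0.0:
        cls = "uniform_stable"
        q_at_max, lam = 0.0, np.inf
    else:
        q_at_max, lam = q_max, 2.0 * np.pi / q_max
        cls = "arrested_candidate" if curvature0 < 0 else "continued_coarsening"
    return DispersionResult(q_grid=q_grid, omega=omega, omega_max=omega_max,
                            q_max=q_at_max, lambda_max=lam,
                            curvature0=curvature0, classification=cls)


def dissolution_threshold(params: ModelParams, k_lo: float = 0.0,
                          k_hi: float = 20.0, rtol: float = 1e-4) -> float:
    """Switching ratio k* at which the maximum growth rate crosses zero.

    Above k* the uniform state is linearly stable (condensates dissolve).
    Requires the system to be unstable at ``k_lo``; raises otherwise.
    """

    def omega_max(k):
        return classify(params.with_k(k)).omega_max

    lo = omega_max(k_lo)
    if lo <= 0:
        raise ValueError("system is not unstable at the lower end of the scan")
    hi = omega_max(k_hi)
    if hi >= 0:
        raise ValueError("no sign change of omega_max in the scan range")
    return float(optimize.brentq(omega_max, k_lo, k_hi, rtol=rtol))
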