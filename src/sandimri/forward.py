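"""Closed-form compartment signals and the spherical-mean SANDI forward model.

The SANDI model decomposes the direction-averaged (powder-averaged)
gray-matter signal into three non-exchanging compartments::

    S(b)/S0 = f_in * A_in(b; D_in) + f_is * A_is(b; r_s, D_is) + f_ec * A_ec(b; D_ec)

with T2-weighted signal fractions on the simplex f_in + f_is + f_ec = 1.
Neurites are zero-radius impermeable "sticks" (parallel diffusivity D_in
only), somas are impermeable spheres of apparent radius r_s with
intrinsic diffusivity D_is (fixed at 3 um^2/ms), and the extracellular
space is an isotropic Gaussian pool with apparent diffusivity D_ec.

Units: b in ms/um^2, diffusivities in um^2/ms, radii in um, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .protocol import (
    CONNECTOME_DELTA_BIG,
    CONNECTOME_DELTA_SMALL,
    CONNECTOME_SHELLS,
    AcquisitionProtocol,
    ShellTable,
    SphericalMeanSignal,
)

D_IS_DEFAULT = 3.0  # intra-soma intrinsic diffusivity, um^2/ms (fixed)

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class SANDIParams:
    """The five free SANDI tissue parameters plus the fixed D_is.

    Fractions are T2-weighted signal fractions on the unit simplex;
    ``r_s`` is the apparent soma radius in um; diffusivities in um^2/ms.
    """

    f_in: float
    f_is: float
    f_ec: float
    r_s: float
    D_in: float
    D_ec: float
    D_is: float = D_IS_DEFAULT

    def __post_init__(self) -> None:
        for name in ("f_in", "f_is", "f_ec"):
            v = getattr(self, name)
            if not -_SIMPLEX_TOL <= v <= 1 + _SIMPLEX_TOL:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.f_in + self.f_is + self.f_ec - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"signal fractions sum to {self.f_in + self.f_is + self.f_ec}, not 1"
            )
        if self.r_s <= 0:
            raise ValueError("soma radius must be positive")
        for name in ("D_in", "D_ec", "D_is"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_free(cls, f_in, f_is, r_s, D_in, D_ec, D_is=D_IS_DEFAULT):
        """Build from the five free parameters; f_ec by the simplex constraint."""
        return cls(f_in=f_in, f_is=f_is, f_ec=1.0 - f_in - f_is,
                   r_s=r_s, D_in=D_in, D_ec=D_ec, D_is=D_is)


@dataclass(frozen=True)
class GPDSeriesConfig:
    """Truncation control for the Gaussian-phase-distribution sphere series."""

    n_roots: int = 30
    root_tolerance: float = 1e-12
    convergence_ratio: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_roots < 10:
            raise ValueError("n_roots must be at least 10")


def _j1_prime(x: float) -> float:
    # d/dx of spherical Bessel j1(x) = sin x / x^2 - cos x / x
    return (x**2 - 2.0) / x**3 * np.sin(x) + 2.0 / x**2 * np.cos(x)


@lru_cache(maxsize=None)
def _cached_roots(n_roots: int, tol: float) -> tuple:
    roots = []
    # j1' roots interlace near (m + 1/2) pi for large m; bracket generously
    lo = 1.0
    m = 0
    while len(roots) < n_roots:
        hi = lo + np.pi
        f_lo, f_hi = _j1_prime(lo), _j1_prime(hi)
        # walk until a sign change is bracketed
        while f_lo * f_hi > 0:
            lo, f_lo = hi, f_hi
            hi = lo + np.pi
            f_hi = _j1_prime(hi)
        roots.append(brentq(_j1_prime, lo, hi, xtol=tol))
        lo = roots[-1] + 0.1
        m += 1
        if m > 10 * n_roots:
            raise RuntimeError("root finder failed to converge")
    return tuple(roots)


def bessel_alpha_roots(n_roots: int = 30, tolerance: float = 1e-12) -> np.ndarray:
    """First ``n_roots`` positive roots of d/dx[j1(x)] = 0, x > 0.

    These are the reflecting-boundary eigenvalue constants of diffusion
    inside an impermeable sphere; the first is ~2.0816.
    """
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    return np.array(_cached_roots(int(n_roots), float(tolerance)))


def sphere_gpd_signal(r_s, D_is, b, delta=CONNECTOME_DELTA_SMALL,
                      Delta=CONNECTOME_DELTA_BIG,
                      config: GPDSeriesConfig = GPDSeriesConfig()):
    """PGSE signal attenuation for diffusion restricted in an impermeable sphere.

    Gaussian-phase-distribution (Murday-Cotts) series::

        -ln A = 2 g2 * sum_m  [alpha_m^2 (alpha_m^2 r_s^2 - 2)]^-1 *
                [ 2 delta / (alpha_m^2 D)
                  - (2 + e^{-a(Delta-delta)} - 2 e^{-a delta} - 2 e^{-a Delta}
                     + e^{-a(Delta+delta)}) / (alpha_m^2 D)^2 ]

    with alpha_m = mu_m / r_s (mu_m the roots of j1'(x)=0),
    a = alpha_m^2 D, and g2 = (gamma g)^2 = b / (delta^2 (Delta - delta/3))
    in 1/(um^2 ms^2).  Vectorized over ``b``.
    """
    if r_s <= 0 or D_is <= 0:
        raise ValueError("r_s and D_is must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b")
    mu = bessel_alpha_roots(config.n_roots, config.root_tolerance)
    alpha = mu / r_s  # 1/um
    a = alpha**2 * D_is  # 1/ms
    bracket = (2.0 * delta / a
               - (2.0
                  + np.exp(-a * (Delta - delta))
                  - 2.0 * np.exp(-a * delta)
                  - 2.0 * np.exp(-a * Delta)
                  + np.exp(-a * (Delta + delta))) / a**2)
    weight = 1.0 / (alpha**2 * (alpha**2 * r_s**2 - 2.0))
    terms = weight * bracket  # um^2 ms^2 per unit g2
    series = np.sum(terms)
    if abs(terms[-1]) > config.convergence_ratio * max(abs(series), 1e-300):
        raise RuntimeError(
            "GPD series not converged at n_roots="
            f"{config.n_roots}; last-term ratio {abs(terms[-1]) / abs(series):.2e}"
        )
    g2 = b / (delta**2 * (Delta - delta / 3.0))  # (gamma g)^2, 1/(um^2 ms^2)
    att = np.exp(-2.0 * g2 * series)
    return att if att.ndim else float(att)


def stick_spherical_mean(b, D_in):
    """Powder-averaged stick signal sqrt(pi/(4 b D)) erf(sqrt(b D)).

    Below b*D = 1e-6 the 3-term Taylor expansion 1 - bD/3 + (bD)^2/10 is
    used to avoid 0/0.
    """
    if D_in <= 0:
        raise ValueError("D_in must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b")
    x = b * D_in
    small = x < 1e-6
    x_safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        1.0 - x / 3.0 + x**2 / 10.0,
        np.sqrt(np.pi / (4.0 * x_safe)) * erf(np.sqrt(x_safe)),
    )
    return out if out.ndim else float(out)


def stick_directional_signal(b, D_in, direction, orientation):
    """Stick signal exp(-b D_in (n . u)^2) for gradient n and stick axis u."""
    direction = np.asarray(direction, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    for v in (direction, orientation):
        if abs(np.linalg.norm(v, axis=-1) - 1.0).max() > 1e-6:
            raise ValueError("direction and orientation must be unit vectors")
    c = np.sum(direction * orientation, axis=-1)
    return np.exp(-np.asarray(b, dtype=float) * D_in * c**2)


def ball_signal(b, D_ec):
    """Isotropic Gaussian compartment exp(-b D_ec)."""
    if D_ec <= 0:
        raise ValueError("D_ec must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b")
    out = np.exp(-b * D_ec)
    return out if out.ndim else float(out)


def sandi_signal(params: SANDIParams,
                 protocol: AcquisitionProtocol | None = None,
                 shells: ShellTable | None = None,
                 config: GPDSeriesConfig = GPDSeriesConfig(),
                 shell_b=None, delta=None, Delta=None) -> SphericalMeanSignal:
    """Spherical-mean SANDI signal at the protocol's nonzero shells.

    Either pass a protocol (optionally with a precomputed shell table) or
    give ``shell_b`` (+ ``delta``/``Delta``) directly.
    """
    if shell_b is None:
        if protocol is None:
            shell_b = np.asarray(CONNECTOME_SHELLS)
            delta = CONNECTOME_DELTA_SMALL
            Delta = CONNECTOME_DELTA_BIG
        else:
            if shells is None:
                from .protocol import group_shells

                shells = group_shells(protocol)
            shell_b = shells.b_values
            delta = protocol.delta
            Delta = protocol.Delta
    else:
        shell_b = np.asarray(shell_b, dtype=float)
        delta = CONNECTOME_DELTA_SMALL if delta is None else delta
        Delta = CONNECTOME_DELTA_BIG if Delta is None else Delta
    a_in = stick_spherical_mean(shell_b, params.D_in)
    a_is = sphere_gpd_signal(params.r_s, params.D_is, shell_b, delta, Delta, config)
    a_ec = ball_signal(shell_b, params.D_ec)
    values = params.f_in * a_in + params.f_is * a_is + params.f_ec * a_ec
    return SphericalMeanSignal(values=np.atleast_1d(values),
                               shell_b=np.atleast_1d(shell_b))


def sandi_signal_array(f_in, f_is, r_s, D_in, D_ec, shell_b,
                       delta=CONNECTOME_DELTA_SMALL, Delta=CONNECTOME_DELTA_BIG,
                       D_is=D_IS_DEFAULT,
                       config: GPDSeriesConfig = GPDSeriesConfig()) -> np.ndarray:
    """Vectorized forward model over parameter arrays.

    All parameter arguments broadcast against each other along axis 0;
    returns an (n_samples, n_shells) array.  The sphere attenuation is
    the only non-separable term, so it is evaluated per unique radius
    when few, else per sample.
    """
    f_in = np.atleast_1d(np.asarray(f_in, dtype=float))
    f_is = np.atleast_1d(np.asarray(f_is, dtype=float))
    r_s = np.atleast_1d(np.asarray(r_s, dtype=float))
    D_in = np.atleast_1d(np.asarray(D_in, dtype=float))
    D_ec = np.atleast_1d(np.asarray(D_ec, dtype=float))
    n = max(a.size for a in (f_in, f_is, r_s, D_in, D_ec))
    f_in, f_is, r_s, D_in, D_ec = (np.broadcast_to(a, (n,)) for a in
                                   (f_in, f_is, r_s, D_in, D_ec))
    shell_b = np.asarray(shell_b, dtype=float)
    if np.any(f_in + f_is > 1 + _SIMPLEX_TOL) or np.any(f_in < 0) or np.any(f_is < 0):
        raise ValueError("fraction simplex violated")
    f_ec = 1.0 - f_in - f_is

    x = np.clip(shell_b[None, :] * D_in[:, None], 1e-300, None)
    small = x < 1e-6
    a_in = np.where(small, 1.0 - x / 3.0 + x**2 / 10.0,
                    np.sqrt(np.pi / (4.0 * x)) * erf(np.sqrt(x)))
    a_ec = np.exp(-shell_b[None, :] * D_ec[:, None])

    mu = bessel_alpha_roots(config.n_roots, config.root_tolerance)
    # series sum per sample: alpha depends on r_s -> vectorize over samples
    alpha2 = (mu[None, :] / r_s[:, None]) ** 2  # (n, m)
    a = alpha2 * D_IS_DEFAULT if D_is is None else alpha2 * D_is
    bracket = (2.0 * delta / a
               - (2.0
                  + np.exp(-a * (Delta - delta))
                  - 2.0 * np.exp(-a * delta)
                  - 2.0 * np.exp(-a * Delta)
                  + np.exp(-a * (Delta + delta))) / a**2)
    weight = 1.0 / (alpha2 * (alpha2 * r_s[:, None] ** 2 - 2.0))
    series = np.sum(weight * bracket, axis=1)  # (n,)
    g2 = shell_b / (delta**2 * (Delta - delta / 3.0))
    a_is = np.exp(-2.0 * g2[None, :] * series[:, None])

    return f_in[:, None] * a_in + f_is[:, None] * a_is + f_ec[:, None] * a_ec
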