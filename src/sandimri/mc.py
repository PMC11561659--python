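"""Monte-Carlo random-walk simulator for restricted diffusion in a sphere.

Independent numerical oracle for the Gaussian-phase-distribution sphere
signal: spins random-walk inside an impermeable sphere with specular
reflection at the boundary, accrue phase under a rectangular PGSE
gradient pair, and the magnitude signal is the ensemble mean of
cos(phase).  Because the trajectory does not depend on the gradient
amplitude, one simulation per radius yields the signal at every b-value
simultaneously.
"""

from __future__ import annotations

import numpy as np

from .protocol import CONNECTOME_DELTA_BIG, CONNECTOME_DELTA_SMALL


def _reflect_into_sphere(pos: np.ndarray, radius: float) -> None:
    """Radially mirror positions that left the sphere, in place.

    A step long enough to need more than one mirror is re-mirrored until
    inside (vanishingly rare for step << radius).
    """
    for _ in range(8):
        r = np.linalg.norm(pos, axis=1)
        out = r > radius
        if not np.any(out):
            return
        pos[out] *= ((2.0 * radius - r[out]) / r[out])[:, None]
    raise RuntimeError("reflection failed; step size too large for radius")


def sphere_random_walk_signal(r_s: float, D: float, b_values,
                              delta: float = CONNECTOME_DELTA_SMALL,
                              Delta: float = CONNECTOME_DELTA_BIG,
                              n_walkers: int = 100_000,
                              n_steps: int = 1000,
                              seed: int = 0) -> np.ndarray:
    """PGSE magnitude signal from walkers confined to an impermeable sphere.

    Parameters in the package's internal units: ``r_s`` um, ``D``
    um^2/ms, ``b_values`` ms/um^2, timings ms.  Walkers start uniformly
    inside the sphere; each step is an isotropic Gaussian displacement of
    per-axis standard deviation sqrt(2 D dt) followed by specular
    reflection.  Phase accrues along z as gamma*g * integral f(t) z(t) dt
    with f = +1 during the first lobe and -1 during the second, and
    gamma*g = sqrt(b / (delta^2 (Delta - delta/3))).

    Returns one signal value per b-value.
    """
    if r_s <= 0 or D <= 0:
        raise ValueError("r_s and D must be positive")
    b_values = np.atleast_1d(np.asarray(b_values, dtype=float))
    rng = np.random.default_rng(seed)

    t_total = Delta + delta
    dt = t_total / n_steps
    step_sd = np.sqrt(2.0 * D * dt)

    # uniform start inside the sphere
    pos = rng.standard_normal((n_walkers, 3))
    pos *= (r_s * rng.random(n_walkers) ** (1.0 / 3.0)
            / np.linalg.norm(pos, axis=1))[:, None]

    integral = np.zeros(n_walkers)
    t = 0.0
    for _ in range(n_steps):
        pos += step_sd * rng.standard_normal((n_walkers, 3))
        _reflect_into_sphere(pos, r_s)
        t_mid = t + 0.5 * dt
        if t_mid < delta:
            integral += pos[:, 2] * dt
        elif Delta <= t_mid < Delta + delta:
            integral -= pos[:, 2] * dt
        t += dt

    gamma_g = np.sqrt(b_values / (delta**2 * (Delta - delta / 3.0)))  # 1/(um ms)
    return np.array([np.mean(np.cos(g * integral)) for g in gamma_g])
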