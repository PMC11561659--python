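"""Rician noise synthesis, noise-level estimation, and noise propagation.

Magnitude MRI noise: S_n = sqrt((S + N_r)^2 + N_i^2) with N_r, N_i
independent Normal(0, sigma^2) and normalized level sigma = 1/SNR of the
b=0 signal.  The noise-propagation experiment draws tissue parameters
uniformly from stated ranges, simulates spherical-mean signals, corrupts
them at each SNR level, inverts with the random-forest regressor, and
reports per-parameter bias, RMSE and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import sandi_signal_array
from .protocol import CONNECTOME_DELTA_BIG, CONNECTOME_DELTA_SMALL, CONNECTOME_SHELLS

FREE_PARAMS = ("f_in", "f_is", "r_s", "D_in", "D_ec")

#: Parameter ranges of the noise-propagation experiment (narrower than
#: the fitting priors: prior-interior ground truths).
NOISEPROP_RANGES = {
    "f_in": (0.1, 0.5),
    "f_is": (0.1, 0.5),
    "r_s": (5.0, 11.0),
    "D_in": (1.0, 2.0),
    "D_ec": (0.5, 1.5),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Normalized Rician noise level; sigma = 1/snr."""

    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def sigma(self) -> float:
        return 1.0 / self.snr


@dataclass
class RecoveryReport:
    """Parameter-recovery summary of the noise-propagation experiment."""

    snr_levels: tuple
    n_iterations: int
    bias: dict = field(default_factory=dict)  # {snr: {param: value}}
    rmse: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)  # {param: array}
    estimates: dict = field(default_factory=dict)  # {snr: {param: array}}

    def to_dict(self) -> dict:
        return {
            "snr_levels": list(self.snr_levels),
            "n_iterations": self.n_iterations,
            "bias": {str(k): v for k, v in self.bias.items()},
            "rmse": {str(k): v for k, v in self.rmse.items()},
            "correlation": {str(k): v for k, v in self.correlation.items()},
        }


def add_rician_noise(signal, sigma=None, rng=None, spec: NoiseSpec | None = None):
    """Corrupt non-negative normalized signals with Rician noise.

    Accepts either ``sigma`` (+ optional ``rng`` / integer seed) or a
    :class:`NoiseSpec`.  sigma = 0 returns the input unchanged.
    """
    if spec is not None:
        sigma = spec.sigma
        if rng is None:
            rng = spec.seed
    if sigma is None:
        raise ValueError("either sigma or spec is required")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise ValueError("signal must be non-negative")
    if sigma == 0:
        return s.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    real = s + rng.normal(0.0, sigma, s.shape)
    imag = rng.normal(0.0, sigma, s.shape)
    return np.sqrt(real**2 + imag**2)


def estimate_noise_level(b0_volumes, mask=None) -> NoiseSpec:
    """Estimate sigma from repeated b=0 acquisitions.

    ``b0_volumes`` has replicates along the last axis (>= 3).  Per voxel,
    sigma-hat is the sample SD across replicates divided by the replicate
    mean; the mask-wide estimate is the median.  Returns the matched
    :class:`NoiseSpec` (SNR = 1/sigma-hat).
    """
    v = np.asarray(b0_volumes, dtype=float)
    if v.shape[-1] < 3:
        raise ValueError("need at least 3 b=0 replicates")
    flat = v.reshape(-1, v.shape[-1])
    if mask is not None:
        flat = flat[np.asarray(mask, dtype=bool).ravel()]
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1, ddof=1)
    valid = mean > 0
    if not np.any(valid):
        raise ValueError("no voxel with positive b=0 mean")
    sigma = float(np.median(sd[valid] / mean[valid]))
    if sigma == 0:
        return NoiseSpec(snr=np.inf)
    return NoiseSpec(snr=1.0 / sigma)


def draw_uniform_params(ranges: dict, n: int, rng: np.random.Generator,
                        enforce_simplex: bool = True) -> dict:
    """Draw parameter sets uniformly within per-parameter ranges.

    With ``enforce_simplex`` draws violating f_in + f_is > 1 are
    rejection-resampled so f_ec >= 0 holds.
    """
    out = {p: rng.uniform(*ranges[p], size=n) for p in FREE_PARAMS}
    if enforce_simplex:
        for _ in range(200):
            bad = out["f_in"] + out["f_is"] > 1.0
            if not np.any(bad):
                break
            k = int(bad.sum())
            out["f_in"][bad] = rng.uniform(*ranges["f_in"], size=k)
            out["f_is"][bad] = rng.uniform(*ranges["f_is"], size=k)
        else:
            raise RuntimeError("simplex rejection rate too high")
    return out


def run_noise_propagation(model=None, ranges=None, n_iterations: int = 1000,
                          snr_levels=(1e10, 50.0), seed: int = 0,
                          shell_b=CONNECTOME_SHELLS,
                          delta=CONNECTOME_DELTA_SMALL,
                          Delta=CONNECTOME_DELTA_BIG,
                          n_train: int = 20_000, n_trees: int = 50,
                          train_at_matching_sigma: bool = True) -> RecoveryReport:
    """Parameter-recovery experiment under Rician noise.

    Draws ``n_iterations`` parameter sets uniformly from ``ranges``
    (defaults to :data:`NOISEPROP_RANGES`), simulates spherical-mean
    signals on the 8-shell protocol, corrupts them at each SNR in
    ``snr_levels``, inverts with a random-forest regressor, and reports
    bias, RMSE and Pearson correlation per parameter and SNR.  The same
    parameter draws are reused across SNR levels (paired comparison).

    If ``model`` is None a regressor is trained per SNR level at the
    matching sigma (or once at sigma of the last level if
    ``train_at_matching_sigma`` is False) with ``n_train`` samples and
    ``n_trees`` trees.
    """
    from .rf import PriorRanges, build_training_set, predict_params, train_regressor

    ranges = dict(NOISEPROP_RANGES if ranges is None else ranges)
    master = np.random.SeedSequence(seed)
    param_seed, noise_seed, train_seed = master.spawn(3)
    rng_params = np.random.default_rng(param_seed)

    truth = draw_uniform_params(ranges, n_iterations, rng_params)
    clean = sandi_signal_array(truth["f_in"], truth["f_is"], truth["r_s"],
                               truth["D_in"], truth["D_ec"],
                               np.asarray(shell_b), delta, Delta)

    report = RecoveryReport(snr_levels=tuple(snr_levels),
                            n_iterations=n_iterations, truth=truth)
    noise_rng = np.random.default_rng(noise_seed)
    for snr in snr_levels:
        sigma = 1.0 / snr
        if model is None:
            priors = PriorRanges()
            features, labels = build_training_set(
                priors, sigma=sigma if train_at_matching_sigma else 1.0 / snr_levels[-1],
                n_train=n_train, seed=train_seed, shell_b=shell_b,
                delta=delta, Delta=Delta)
            rf = train_regressor(features, labels, n_trees=n_trees,
                                 seed=train_seed, priors=priors,
                                 shell_b=shell_b, delta=delta, Delta=Delta,
                                 sigma=sigma)
        else:
            rf = model
        noisy = add_rician_noise(clean, sigma=sigma, rng=noise_rng)
        est = predict_params(rf, noisy, as_dict=True)
        report.estimates[snr] = est
        report.bias[snr] = {p: float(np.mean(est[p] - truth[p])) for p in FREE_PARAMS}
        report.rmse[snr] = {
            p: float(np.sqrt(np.mean((est[p] - truth[p]) ** 2))) for p in FREE_PARAMS
        }
        report.correlation[snr] = {
            p: float(np.corrcoef(truth[p], est[p])[0, 1]) for p in FREE_PARAMS
        }
    return report
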