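"""Random-forest inversion of the spherical-mean SANDI model.

The forward model is simulated at parameter sets drawn uniformly within
fitting priors (rejection-sampled so f_in + f_is <= 1), Rician noise is
added at the acquisition's normalized noise level, and a multi-output
random forest (200 trees by default) learns the map from the 8-shell
b0-normalized spherical-mean feature vector back to the five free tissue
parameters.  f_ec is computed from the simplex constraint
f_in + f_is + f_ec = 1 at prediction time.

Because forest predictions are averages of in-range training labels,
predicted parameters can never leave the prior bounds.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .forward import D_IS_DEFAULT, sandi_signal_array
from .noise import FREE_PARAMS, add_rician_noise, draw_uniform_params
from .protocol import (
    CONNECTOME_DELTA_BIG,
    CONNECTOME_DELTA_SMALL,
    CONNECTOME_SHELLS,
    AcquisitionProtocol,
    ShellTable,
    compute_spherical_mean,
    group_shells,
)


@dataclass(frozen=True)
class PriorRanges:
    """Uniform fitting priors for the five free SANDI parameters.

    Defaults: D_ec, D_in in [0.25, 3] um^2/ms, r_s in [1, 12] um,
    f_in, f_is in [0, 1] (jointly restricted to f_in + f_is <= 1);
    D_is fixed at 3 um^2/ms.
    """

    f_in: tuple = (0.0, 1.0)
    f_is: tuple = (0.0, 1.0)
    r_s: tuple = (1.0, 12.0)
    D_in: tuple = (0.25, 3.0)
    D_ec: tuple = (0.25, 3.0)
    D_is_fixed: float = D_IS_DEFAULT

    def __post_init__(self) -> None:
        for p in FREE_PARAMS:
            lo, hi = getattr(self, p)
            if not lo < hi:
                raise ValueError(f"{p}: lower bound must be below upper")
        if self.r_s[0] <= 0 or self.D_in[0] <= 0 or self.D_ec[0] <= 0:
            raise ValueError("physical parameters need positive lower bounds")

    def as_dict(self) -> dict:
        return {p: getattr(self, p) for p in FREE_PARAMS}


@dataclass
class RFModel:
    """Trained regressor plus everything needed to reproduce or verify it."""

    regressor: RandomForestRegressor
    priors: PriorRanges
    shell_b: np.ndarray  # protocol fingerprint: nonzero-shell b-values
    delta: float
    Delta: float
    sigma: float  # training noise level
    n_train: int
    seed: int
    param_names: tuple = FREE_PARAMS

    def fingerprint_matches(self, shell_b, tol: float = 1e-6) -> bool:
        shell_b = np.asarray(shell_b, dtype=float)
        return (shell_b.shape == self.shell_b.shape
                and bool(np.all(np.abs(shell_b - self.shell_b) <= tol)))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "RFModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("file does not contain an RFModel")
        return model


def build_training_set(priors: PriorRanges = PriorRanges(), sigma: float = 0.02,
                       n_train: int = 100_000, seed: int = 0,
                       shell_b=CONNECTOME_SHELLS,
                       delta=CONNECTOME_DELTA_SMALL,
                       Delta=CONNECTOME_DELTA_BIG):
    """Simulate a labeled training set under the priors.

    Labels are uniform in the priors subject to f_in + f_is <= 1
    (rejection sampling); features are the forward spherical-mean
    signals with Rician noise at ``sigma``.  Returns
    ``(features (n, n_shells), labels (n, 5))`` with label columns in
    :data:`FREE_PARAMS` order.
    """
    if n_train < 1000:
        raise ValueError("n_train must be at least 1000")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    draw_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    params = draw_uniform_params(priors.as_dict(), n_train, draw_rng)
    clean = sandi_signal_array(params["f_in"], params["f_is"], params["r_s"],
                               params["D_in"], params["D_ec"],
                               np.asarray(shell_b), delta, Delta,
                               D_is=priors.D_is_fixed)
    features = add_rician_noise(clean, sigma=sigma, rng=noise_rng)
    labels = np.column_stack([params[p] for p in FREE_PARAMS])
    return features, labels


def train_regressor(features, labels, n_trees: int = 200, seed: int = 0,
                    priors: PriorRanges = PriorRanges(),
                    shell_b=CONNECTOME_SHELLS,
                    delta=CONNECTOME_DELTA_SMALL, Delta=CONNECTOME_DELTA_BIG,
                    sigma: float = 0.02, oob_score: bool = False) -> RFModel:
    """Fit the multi-output random forest (200 trees by default)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if features.shape[0] != labels.shape[0]:
        raise ValueError(
            f"{features.shape[0]} feature rows vs {labels.shape[0]} label rows"
        )
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite feature")
    if isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed.generate_state(1)[0] % (2**31))
    else:
        seed_int = int(seed) % (2**31)
    # scale labels to the unit cube so the multi-output split criterion
    # weighs all five parameters equally (r_s spans 1-12 vs fractions 0-1)
    lo = np.array([getattr(priors, p)[0] for p in FREE_PARAMS])
    hi = np.array([getattr(priors, p)[1] for p in FREE_PARAMS])
    reg = RandomForestRegressor(n_estimators=n_trees, random_state=seed_int,
                                n_jobs=1, oob_score=oob_score)
    reg.fit(features, (labels - lo) / (hi - lo))
    return RFModel(regressor=reg, priors=priors,
                   shell_b=np.asarray(shell_b, dtype=float),
                   delta=delta, Delta=Delta, sigma=sigma,
                   n_train=features.shape[0], seed=seed_int)


def predict_params(model: RFModel, signals, shell_b=None, as_dict: bool = False):
    """Predict SANDI parameters for spherical-mean records.

    ``signals`` is (n_records, n_shells) or a single record; if
    ``shell_b`` is given it is checked against the model fingerprint.
    Returns a dict of parameter arrays (including the constrained
    ``f_ec`` and a ``f_ec_clipped`` flag) when ``as_dict``, else an
    (n_records, 6) array in order f_in, f_is, f_ec, r_s, D_in, D_ec.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if shell_b is not None and not model.fingerprint_matches(shell_b):
        raise ValueError("protocol fingerprint mismatch between model and data")
    if x.shape[1] != model.shell_b.size:
        raise ValueError(
            f"signal length {x.shape[1]} does not match model fingerprint "
            f"({model.shell_b.size} shells)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite signal")
    pred = model.regressor.predict(x)
    lo = np.array([getattr(model.priors, p)[0] for p in model.param_names])
    hi = np.array([getattr(model.priors, p)[1] for p in model.param_names])
    pred = pred * (hi - lo) + lo
    out = {p: pred[:, i] for i, p in enumerate(model.param_names)}
    f_ec_raw = 1.0 - out["f_in"] - out["f_is"]
    clipped = (f_ec_raw < 0) | (f_ec_raw > 1)
    out["f_ec"] = np.clip(f_ec_raw, 0.0, 1.0)
    out["f_ec_clipped"] = clipped
    if as_dict:
        return out
    return np.column_stack([out["f_in"], out["f_is"], out["f_ec"],
                            out["r_s"], out["D_in"], out["D_ec"]])


MAP_NAMES = ("f_in", "f_is", "f_ec", "r_s", "D_in", "D_ec")


def fit_dataset(dwi, protocol: AcquisitionProtocol, mask, model: RFModel,
                shells: ShellTable | None = None) -> dict:
    """Voxel-wise SANDI maps from a 4D DWI array.

    Computes the spherical mean per masked voxel, predicts with the
    forest, and returns a dict of 3D maps (keys :data:`MAP_NAMES`) plus
    a boolean ``valid`` map; voxels outside the mask or with
    non-positive b=0 mean are flagged invalid, not zero-filled (NaN).
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask grid does not match DWI grid")
    if not mask.any():
        raise ValueError("empty mask")
    if shells is None:
        shells = group_shells(protocol)
    if not model.fingerprint_matches(shells.b_values):
        raise ValueError("protocol fingerprint mismatch between model and data")

    idx = np.argwhere(mask)
    feats = np.empty((idx.shape[0], shells.n_shells))
    valid_rows = np.ones(idx.shape[0], dtype=bool)
    for row, (i, j, k) in enumerate(idx):
        try:
            sm = compute_spherical_mean(dwi[i, j, k], protocol, shells)
            feats[row] = sm.values
        except ValueError:
            valid_rows[row] = False
    maps = {name: np.full(mask.shape, np.nan) for name in MAP_NAMES}
    valid = np.zeros(mask.shape, dtype=bool)
    if valid_rows.any():
        pred = predict_params(model, feats[valid_rows], as_dict=True)
        good = idx[valid_rows]
        for col, name in enumerate(MAP_NAMES):
            maps[name][good[:, 0], good[:, 1], good[:, 2]] = pred[name]
        valid[good[:, 0], good[:, 1], good[:, 2]] = True
    maps["valid"] = valid
    return maps
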