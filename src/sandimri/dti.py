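"""DTI and DKI scalar metrics from restricted shell subsets.

DTI (FA, MD, AD, RD) is fitted to the b = {0, 0.8} ms/um^2 data and DKI
(AK, RK, MK) to b = {0, 0.8, 1.5, 2.4, 3.45} ms/um^2, mirroring the
standard practice of keeping the cumulant expansion inside its
convergence radius.  Both use a two-pass weighted linear least squares
on the log signal: an OLS pass provides predicted signals whose squares
are the WLLS weights.

Kurtosis design: ln S = ln S0 - b D(n) + (b^2/6) MD^2 W(n), where D(n)
and W(n) are the apparent diffusion and (dimensionless) kurtosis along
direction n; the 15 fitted kurtosis coefficients are V = MD^2 * W and W
is recovered after MD is known.  The apparent kurtosis along n is
K(n) = MD^2 W(n) / D(n)^2; AK/RK are along/perpendicular to the
principal eigenvector and MK averages K(n) over 256 quasi-uniform
directions.
"""

from __future__ import annotations

import numpy as np

from .protocol import AcquisitionProtocol, ShellTable, _fibonacci_directions, group_shells

DTI_SHELLS = (0.8,)
DKI_SHELLS = (0.8, 1.5, 2.4, 3.45)

# symmetric tensor index books
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1, 1, 1, 2, 2, 2], dtype=float)
_W_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_W_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)


def _select_shell_volumes(protocol: AcquisitionProtocol, shells: ShellTable,
                          wanted, tol: float = 0.049):
    """Volume indices for b=0 plus the wanted nonzero shells; errors if absent."""
    keep = [np.asarray(shells.b0_members)]
    b_per_vol = [np.zeros(shells.b0_members.size)]
    for bw in wanted:
        hit = np.flatnonzero(np.abs(shells.b_values - bw) <= tol)
        if hit.size != 1:
            raise ValueError(f"shell b={bw} not found uniquely in protocol")
        m = shells.members[hit[0]]
        keep.append(np.asarray(m))
        b_per_vol.append(np.full(len(m), shells.b_values[hit[0]]))
    idx = np.concatenate(keep)
    return idx, np.concatenate(b_per_vol)


def _dti_design(b, dirs):
    # columns: ln S0, -b * mult * n_i n_j (6)
    g = np.stack([dirs[:, i] * dirs[:, j] for i, j in _D_IDX], axis=1) * _D_MULT
    return np.column_stack([np.ones(b.size), -(b[:, None] * g)])


def _dki_design(b, dirs):
    g2 = np.stack([dirs[:, i] * dirs[:, j] for i, j in _D_IDX], axis=1) * _D_MULT
    g4 = np.stack([dirs[:, i] * dirs[:, j] * dirs[:, k] * dirs[:, l]
                   for i, j, k, l in _W_IDX], axis=1) * _W_MULT
    return np.column_stack([np.ones(b.size),
                            -(b[:, None] * g2),
                            (b[:, None] ** 2 / 6.0) * g4])


def _wlls(design, log_s, n_pass: int = 2):
    """OLS followed by WLLS with weights = squared predicted signals."""
    beta, *_ = np.linalg.lstsq(design, log_s, rcond=None)
    for _ in range(n_pass - 1):
        w = np.exp(design @ beta)  # predicted signals
        sw = design * w[:, None] ** 1  # weight sqrt = predicted signal
        beta, *_ = np.linalg.lstsq(sw, log_s * w, rcond=None)
    return beta


def _tensor_from_coeffs(d6):
    t = np.empty((3, 3))
    for c, (i, j) in zip(d6, _D_IDX):
        t[i, j] = c
        t[j, i] = c
    return t


def _dti_scalars(tensor):
    lam = np.linalg.eigvalsh(tensor)[::-1]  # descending
    md = lam.mean()
    denom = np.sqrt((lam**2).sum())
    fa = 0.0 if denom == 0 else float(
        np.sqrt(1.5 * ((lam - md) ** 2).sum()) / denom)
    return {
        "FA": min(max(fa, 0.0), 1.0),
        "MD": float(md),
        "AD": float(lam[0]),
        "RD": float((lam[1] + lam[2]) / 2.0),
        "eigenvalues": lam,
    }


def fit_dti_voxel(signals, b, dirs):
    """Tensor fit for one voxel; returns the scalar dict plus the tensor."""
    s = np.asarray(signals, dtype=float)
    if np.any(s <= 0):
        raise ValueError("non-positive signal; voxel unfittable")
    design = _dti_design(np.asarray(b, float), np.asarray(dirs, float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient tensor design (need >= 6 unique directions)")
    beta = _wlls(design, np.log(s))
    tensor = _tensor_from_coeffs(beta[1:7])
    out = _dti_scalars(tensor)
    out["tensor"] = tensor
    return out


def _apparent_d_w(d6, w15, dirs):
    g2 = np.stack([dirs[:, i] * dirs[:, j] for i, j in _D_IDX], axis=1) * _D_MULT
    g4 = np.stack([dirs[:, i] * dirs[:, j] * dirs[:, k] * dirs[:, l]
                   for i, j, k, l in _W_IDX], axis=1) * _W_MULT
    return g2 @ d6, g4 @ w15


def fit_dki_voxel(signals, b, dirs, n_mk_dirs: int = 256):
    """Joint diffusion + kurtosis tensor fit for one voxel.

    Returns AK, RK, MK together with the DTI scalars of the diffusion
    tensor part.  RK averages the apparent kurtosis over 64 directions
    on the circle perpendicular to the principal eigenvector; MK over
    ``n_mk_dirs`` quasi-uniform sphere directions.
    """
    s = np.asarray(signals, dtype=float)
    if np.any(s <= 0):
        raise ValueError("non-positive signal; voxel unfittable")
    b = np.asarray(b, float)
    dirs = np.asarray(dirs, float)
    design = _dki_design(b, dirs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient kurtosis design "
                         "(need >= 15 directions over >= 2 nonzero shells)")
    beta = _wlls(design, np.log(s))
    d6, v15 = beta[1:7], beta[7:22]
    tensor = _tensor_from_coeffs(d6)
    scalars = _dti_scalars(tensor)
    md = scalars["MD"]
    if md <= 0:
        raise ValueError("non-positive mean diffusivity")
    w15 = v15 / md**2

    lam, vec = np.linalg.eigh(tensor)
    e1 = vec[:, np.argmax(lam)]

    def kurtosis_along(n):
        dn, wn = _apparent_d_w(d6, w15, np.atleast_2d(n))
        return md**2 * wn / dn**2

    scalars["AK"] = float(kurtosis_along(e1)[0])
    # orthonormal frame perpendicular to e1
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(tmp @ e1) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, tmp)
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    theta = np.linspace(0, np.pi, 64, endpoint=False)
    perp = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    scalars["RK"] = float(np.mean(kurtosis_along(perp)))
    sphere = _fibonacci_directions(n_mk_dirs)
    scalars["MK"] = float(np.mean(kurtosis_along(sphere)))
    scalars["tensor"] = tensor
    scalars["kurtosis_tensor"] = w15
    return scalars


def _fit_maps(dwi, protocol, mask, wanted, voxel_fn, metric_names):
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    shells = group_shells(protocol)
    idx, b = _select_shell_volumes(protocol, shells, wanted)
    dirs = protocol.directions[idx]
    maps = {m: np.full(mask.shape, np.nan) for m in metric_names}
    valid = np.zeros(mask.shape, dtype=bool)
    for i, j, k in np.argwhere(mask):
        try:
            res = voxel_fn(dwi[i, j, k, idx], b, dirs)
        except ValueError:
            continue
        for m in metric_names:
            maps[m][i, j, k] = res[m]
        valid[i, j, k] = True
    maps["valid"] = valid
    return maps


def fit_dti(dwi, protocol: AcquisitionProtocol, mask, shells=DTI_SHELLS) -> dict:
    """FA/MD/AD/RD maps from the b={0, 0.8} subset (configurable)."""
    return _fit_maps(dwi, protocol, mask, shells, fit_dti_voxel,
                     ("FA", "MD", "AD", "RD"))


def fit_dki(dwi, protocol: AcquisitionProtocol, mask, shells=DKI_SHELLS) -> dict:
    """AK/RK/MK (+ tensor scalars) maps from the b<=3.45 subset."""
    return _fit_maps(dwi, protocol, mask, shells, fit_dki_voxel,
                     ("FA", "MD", "AD", "RD", "AK", "RK", "MK"))
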