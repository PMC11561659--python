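"""Acquisition protocol, shell grouping, spherical means, and DWI I/O.

b-values are carried internally in ms/um^2 (1 ms/um^2 = 1000 s/mm^2).
FSL-dialect bval/bvec readers convert from s/mm^2 when magnitudes make
the file unit unambiguous (any b > 50 implies s/mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

GYROMAGNETIC_RATIO = 2.6752218744e8  # rad s^-1 T^-1, proton

#: b-values (ms/um^2) of the 8 nonzero shells of the Connectome gradient
#: protocol used throughout: diffusion time Delta=19 ms, pulse width
#: delta=8 ms, 32 directions per shell below b=2.3, 64 above.
CONNECTOME_SHELLS = (0.05, 0.35, 0.8, 1.5, 2.4, 3.45, 4.75, 6.0)
CONNECTOME_DELTA_SMALL = 8.0  # gradient duration delta, ms
CONNECTOME_DELTA_BIG = 19.0  # diffusion time Delta, ms


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Per-volume diffusion weighting and gradient directions.

    Parameters
    ----------
    b_per_volume : ndarray, shape (n_volumes,)
        Diffusion weighting per volume in ms/um^2.
    directions : ndarray, shape (n_volumes, 3)
        Unit gradient directions; zero vectors for b=0 volumes.
    delta : float
        Gradient pulse duration (ms).
    Delta : float
        Gradient pulse separation, i.e. diffusion time (ms).
    gamma : float
        Gyromagnetic ratio (rad s^-1 T^-1).
    """

    b_per_volume: np.ndarray
    directions: np.ndarray
    delta: float = CONNECTOME_DELTA_SMALL
    Delta: float = CONNECTOME_DELTA_BIG
    gamma: float = GYROMAGNETIC_RATIO

    def __post_init__(self) -> None:
        b = np.asarray(self.b_per_volume, dtype=float)
        d = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "b_per_volume", b)
        object.__setattr__(self, "directions", d)
        if b.ndim != 1:
            raise ValueError("b_per_volume must be 1-D")
        if d.shape != (b.size, 3):
            raise ValueError(
                f"directions shape {d.shape} does not match {b.size} volumes"
            )
        if np.any(b < 0):
            raise ValueError("negative b-value")
        if not self.delta < self.Delta:
            raise ValueError("require delta < Delta")
        norms = np.linalg.norm(d, axis=1)
        dw = b > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("non-unit direction on a diffusion-weighted volume")

    @property
    def n_volumes(self) -> int:
        return int(self.b_per_volume.size)


@dataclass(frozen=True)
class ShellTable:
    """Grouping of protocol volumes into b-shells.

    ``b_values`` holds the nonzero shell centres sorted ascending;
    ``members`` the volume indices per nonzero shell; ``b0_members`` the
    b=0 volume indices.
    """

    b_values: np.ndarray
    members: tuple
    b0_members: np.ndarray

    @property
    def n_shells(self) -> int:
        return int(self.b_values.size)

    @property
    def directions_per_shell(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])


@dataclass(frozen=True)
class SphericalMeanSignal:
    """Direction-averaged, b0-normalized signal, one value per nonzero shell."""

    values: np.ndarray
    shell_b: np.ndarray
    source_id: object = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        b = np.asarray(self.shell_b, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "shell_b", b)
        if v.shape != b.shape:
            raise ValueError("values and shell_b lengths differ")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite spherical-mean value")


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionProtocol:
    """Read FSL-dialect bval/bvec files into an :class:`AcquisitionProtocol`.

    bvec files may be 3 x N (FSL convention) or N x 3; orientation is
    auto-detected.  b-values larger than 50 are interpreted as s/mm^2 and
    divided by 1000; otherwise they are taken as ms/um^2 already.
    """
    try:
        bvals = np.loadtxt(bval_path, dtype=float).ravel()
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in bval file {bval_path}") from exc
    try:
        bvecs = np.loadtxt(bvec_path, dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in bvec file {bvec_path}") from exc
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1) if bvals.size == 1 else bvecs.reshape(-1, 3)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention (3 rows of components) assumed
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec table with {bvecs.shape} entries does not match "
            f"{bvals.size} b-values"
        )
    if np.nanmax(bvals, initial=0.0) > 50.0:
        bvals = bvals / 1000.0  # s/mm^2 -> ms/um^2
    norms = np.linalg.norm(bvecs, axis=1)
    dirs = np.zeros_like(bvecs)
    dw = bvals > 0
    if np.any(norms[dw] == 0):
        raise ValueError("zero-norm direction on a diffusion-weighted volume")
    dirs[dw] = bvecs[dw] / norms[dw, None]
    return AcquisitionProtocol(b_per_volume=bvals, directions=dirs)


def write_bvals_bvecs(protocol: AcquisitionProtocol, bval_path, bvec_path,
                      unit: str = "s/mm2") -> None:
    """Write FSL-dialect bval (one row) and bvec (3 rows) files."""
    b = protocol.b_per_volume * (1000.0 if unit == "s/mm2" else 1.0)
    np.savetxt(bval_path, b[None, :], fmt="%.6g")
    np.savetxt(bvec_path, protocol.directions.T, fmt="%.8f")


def group_shells(protocol: AcquisitionProtocol, tolerance: float = 0.049) -> ShellTable:
    """Cluster volumes into b-shells within ``tolerance`` (ms/um^2).

    The b=0 shell is kept separate from the lowest diffusion-weighted
    shell (b=0.05 in the Connectome protocol).  Raises on ambiguous
    clustering, i.e. a b-value within tolerance of two cluster centres.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    b = protocol.b_per_volume
    b0_members = np.flatnonzero(b == 0)
    dw = np.flatnonzero(b > 0)
    centres: list[float] = []
    assignment = np.empty(dw.size, dtype=int)
    for rank, i in enumerate(dw[np.argsort(b[dw], kind="stable")]):
        hits = [k for k, c in enumerate(centres) if abs(b[i] - c) <= tolerance]
        if len(hits) > 1:
            raise ValueError(
                f"ambiguous shell assignment: b={b[i]} within {tolerance} of "
                f"centres {[centres[k] for k in hits]}"
            )
        if hits:
            assignment[rank] = hits[0]
        else:
            centres.append(float(b[i]))
            assignment[rank] = len(centres) - 1
    order = np.argsort(b[dw], kind="stable")
    members: list[list[int]] = [[] for _ in centres]
    for rank, i in enumerate(dw[order]):
        members[assignment[rank]].append(int(i))
    shell_b = np.array([np.mean(b[m]) for m in members])
    # final pass: every volume must sit within tolerance of exactly one
    # shell centre, otherwise the clustering is order-dependent
    for i in dw:
        hits = np.flatnonzero(np.abs(b[i] - shell_b) <= tolerance)
        if hits.size != 1:
            raise ValueError(
                f"ambiguous shell assignment: b={b[i]} within {tolerance} of "
                f"shell centres {shell_b[hits]}"
            )
    sort = np.argsort(shell_b)
    return ShellTable(
        b_values=shell_b[sort],
        members=tuple(np.array(sorted(members[k]), dtype=int) for k in sort),
        b0_members=b0_members,
    )


def compute_spherical_mean(dwi_values, protocol: AcquisitionProtocol,
                           shells: ShellTable | None = None,
                           source_id=None) -> SphericalMeanSignal:
    """Direction-average one voxel's signals per shell and b0-normalize.

    ``dwi_values`` holds one magnitude value per volume.  Per nonzero
    shell the unweighted arithmetic mean over member volumes is divided
    by the mean over all b=0 volumes.  Raises if the b=0 mean is not
    positive (voxel unfittable).
    """
    if shells is None:
        shells = group_shells(protocol)
    s = np.asarray(dwi_values, dtype=float)
    if s.shape[-1] != protocol.n_volumes:
        raise ValueError("one value per volume required")
    if shells.b0_members.size == 0:
        raise ValueError("protocol contains no b=0 volume")
    s0 = float(np.mean(s[..., shells.b0_members]))
    if s0 <= 0:
        raise ValueError("mean b=0 signal is not positive; voxel unfittable")
    values = np.array([np.mean(s[..., m]) for m in shells.members]) / s0
    return SphericalMeanSignal(values=values, shell_b=shells.b_values.copy(),
                               source_id=source_id)


def b_to_gradient(b: float, delta: float, Delta: float,
                  gamma: float = GYROMAGNETIC_RATIO) -> float:
    """Gradient amplitude (mT/m) for a rectangular PGSE pair.

    Inverts b = gamma^2 g^2 delta^2 (Delta - delta/3) with b in ms/um^2
    and timings in ms.
    """
    if delta <= 0 or Delta <= 0 or not delta < Delta:
        raise ValueError("require 0 < delta < Delta")
    if b < 0:
        raise ValueError("negative b")
    b_si = b * 1e9  # ms/um^2 -> s/m^2
    g_tesla_per_m = np.sqrt(b_si / (gamma**2 * (delta * 1e-3) ** 2
                                    * (Delta - delta / 3.0) * 1e-3))
    return float(g_tesla_per_m * 1e3)  # T/m -> mT/m


def gradient_to_b(g_mT_per_m: float, delta: float, Delta: float,
                  gamma: float = GYROMAGNETIC_RATIO) -> float:
    """Inverse of :func:`b_to_gradient`; returns b in ms/um^2."""
    g = g_mT_per_m * 1e-3
    b_si = gamma**2 * g**2 * (delta * 1e-3) ** 2 * (Delta - delta / 3.0) * 1e-3
    return float(b_si / 1e9)


def load_dwi(nifti_path, bval_path, bvec_path):
    """Load a 4D DWI NIfTI plus its gradient tables.

    Returns ``(data, affine, protocol)``; the 4th dimension must match
    the gradient-table length.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D DWI, got {data.ndim}D")
    protocol = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != protocol.n_volumes:
        raise ValueError(
            f"DWI has {data.shape[3]} volumes but gradient table has "
            f"{protocol.n_volumes}"
        )
    return data, img.affine, protocol


def save_nifti(path, data, affine=None) -> None:
    """Write an array as NIfTI-1, identity affine by default."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def connectome_protocol(interspersed_b0_every: int = 16,
                        lead_b0: int = 1) -> AcquisitionProtocol:
    """Build the 8-shell Connectome acquisition used for simulation.

    Shells at ``CONNECTOME_SHELLS`` ms/um^2 with 32 quasi-uniform
    directions for b < 2.3 and 64 otherwise; b=0 volumes interspersed
    every ``interspersed_b0_every`` diffusion-weighted volumes after
    ``lead_b0`` leading b=0 volumes.
    """
    bvals: list[float] = [0.0] * lead_b0
    dirs: list[np.ndarray] = [np.zeros(3)] * lead_b0
    count_since_b0 = 0
    for b in CONNECTOME_SHELLS:
        n_dir = 32 if b < 2.3 else 64
        for d in _fibonacci_directions(n_dir):
            bvals.append(b)
            dirs.append(d)
            count_since_b0 += 1
            if interspersed_b0_every and count_since_b0 >= interspersed_b0_every:
                bvals.append(0.0)
                dirs.append(np.zeros(3))
                count_since_b0 = 0
    return AcquisitionProtocol(
        b_per_volume=np.array(bvals), directions=np.vstack(dirs)
    )
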