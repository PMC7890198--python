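"""Normal modes: full diagonalization and an iterative mixed-basis
(block) diagonalization that converges the lowest-frequency eigenpairs of
large mass-weighted Hessians without ever diagonalizing the full matrix.

Mode numbering is 1-based throughout; modes 1–6 are the trivial rigid-body
translations/rotations of a free molecule and carry zero frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import scipy.linalg

from .constants import EIGVAL_TO_CM1
from .energetics import HessianMatrix
from .structure import AtomSelection, DisplacementVector, Structure

__all__ = [
    "ModeSet",
    "diagonalize_full",
    "dimb_diagonalize",
    "frequency_from_eigenvalue",
    "rigid_body_vectors",
    "cartesian_displacement",
    "export_nmd",
    "import_nmd",
]


@dataclass
class ModeSet:
    """Eigenpairs of a mass-weighted Hessian.

    ``eigenvectors`` holds one mass-weighted unit column per mode,
    ``eigenvalues`` are in kcal/mol/Å²/amu and ``frequencies`` in cm⁻¹
    (negative entries flag imaginary frequencies).  Columns are ordered by
    ascending frequency; ``mode(1)`` is the first trivial mode.
    """

    eigenvectors: np.ndarray  # (3N, n_modes)
    eigenvalues: np.ndarray  # (n_modes,)
    frequencies: np.ndarray  # (n_modes,) cm⁻¹, signed
    masses: np.ndarray  # (N,) amu
    n_trivial: int = 6
    atom_map: AtomSelection | None = None
    converged: bool = True
    residuals: np.ndarray | None = None  # per-mode convergence metric (DIMB)

    def __post_init__(self) -> None:
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def mode(self, m: int) -> np.ndarray:
        """Mass-weighted eigenvector of 1-based mode ``m``."""
        if not 1 <= m <= self.n_modes:
            raise IndexError(f"mode {m} out of range 1..{self.n_modes}")
        return self.eigenvectors[:, m - 1]

    def cartesian_mode(self, m: int) -> np.ndarray:
        """(N, 3) Cartesian displacement pattern of mode ``m``
        (components divided by sqrt(m_i); not renormalized)."""
        q = self.mode(m).reshape(-1, 3)
        return q / np.sqrt(self.masses)[:, None]

    def nontrivial_range(self, upper: int | None = None) -> range:
        """1-based mode indices from the first nontrivial mode up."""
        stop = self.n_modes if upper is None else min(upper, self.n_modes)
        return range(self.n_trivial + 1, stop + 1)


def frequency_from_eigenvalue(lam: float) -> float:
    """Wavenumber in cm⁻¹ from an eigenvalue in kcal/mol/Å²/amu.

    Negative eigenvalues (saddle directions) return the negated magnitude,
    the conventional flag for an imaginary frequency.
    """
    return float(np.sign(lam) * np.sqrt(abs(lam)) * EIGVAL_TO_CM1)


_freqs = np.vectorize(frequency_from_eigenvalue, otypes=[float])


def _count_trivial(eigvals: np.ndarray) -> int:
    lam_max = float(np.abs(eigvals).max()) if eigvals.size else 0.0
    tol = 1e-6 * max(lam_max, 1e-30)
    return int(np.sum(np.abs(eigvals) < tol))


def diagonalize_full(H: HessianMatrix) -> ModeSet:
    """All 3N eigenpairs of a mass-weighted Hessian, ascending.

    This is the reference the iterative method converges to; negative
    eigenvalues are reported as (flagged) imaginary frequencies rather
    than errors, since they simply mean the geometry is not a minimum.
    """
    if not H.mass_weighted:
        raise ValueError("diagonalize_full expects a mass-weighted Hessian")
    eigvals, eigvecs = scipy.linalg.eigh(H.array)
    if np.any(eigvals < -1e-6 * max(abs(eigvals[-1]), 1.0)):
        warnings.warn(
            "negative eigenvalues present: structure is not at a minimum",
            RuntimeWarning,
            stacklevel=2,
        )
    return ModeSet(
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        frequencies=_freqs(eigvals),
        masses=H.masses.copy(),
        n_trivial=_count_trivial(eigvals),
        atom_map=H.atom_map,
    )


def rigid_body_vectors(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted rigid-body basis (3N × k, k ≤ 6).

    Three uniform translations plus rotations about the mass-weighted
    centroid; linear systems yield k = 5.
    """
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float)
    sq = np.sqrt(m)
    n = x.shape[0]
    com = np.average(x, axis=0, weights=m)
    rel = x - com
    vecs = []
    for a in range(3):
        v = np.zeros((n, 3))
        v[:, a] = sq
        vecs.append(v.reshape(-1))
    for a in range(3):
        axis = np.zeros(3)
        axis[a] = 1.0
        v = np.cross(np.tile(axis, (n, 1)), rel) * sq[:, None]
        vecs.append(v.reshape(-1))
    V = np.column_stack(vecs)
    # orthonormalize, dropping rank-deficient directions (linear molecules)
    q, r = np.linalg.qr(V)
    keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1e-30)
    return q[:, keep]


def dimb_diagonalize(
    H: HessianMatrix,
    n_modes: int = 200,
    conv_tol: float = 0.03,
    block_size: int | None = None,
    max_sweeps: int = 50,
) -> ModeSet:
    """Lowest nontrivial eigenpairs by iterative diagonalization in a
    mixed basis of current approximate modes and one block of Cartesian
    coordinates at a time.

    The six rigid-body vectors are projected out of the Hessian before the
    iteration and re-reported as modes 1–6 with zero frequency.  Each sweep
    visits every contiguous coordinate block once; per-mode convergence is
    1 − |q_new · q_old| and the run stops when the maximum over the
    requested modes drops below ``conv_tol`` (0.03 by default).  If
    ``max_sweeps`` is exhausted the best iterate is returned with
    ``converged=False`` and per-mode residuals attached.
    """
    if not H.mass_weighted:
        raise ValueError("dimb_diagonalize expects a mass-weighted Hessian")
    dof = H.order
    if block_size is None:
        block_size = max(3 * ((dof // 4) // 3), 6)
    if H.coords is None:
        raise ValueError("Hessian carries no reference coordinates")

    R = rigid_body_vectors(H.coords, H.masses)
    k_triv = R.shape[1]
    if n_modes + k_triv > dof:
        raise ValueError("n_modes + trivial modes exceeds the number of DoF")

    # project rigid-body motion out (stabilizes the iteration)
    P = np.eye(dof) - R @ R.T
    Hp = P @ H.array @ P
    Hp = 0.5 * (Hp + Hp.T)

    blocks = [
        np.arange(start, min(start + block_size, dof))
        for start in range(0, dof, block_size)
    ]

    # working subspace is wider than requested: the extra Ritz vectors act
    # as a buffer that keeps block-wise information between inner steps
    n_work = min(n_modes + max(10, n_modes // 2), dof - k_triv)

    # initial guess: Rayleigh–Ritz over the union of low block eigenvectors
    per_block = max(1, int(np.ceil((n_work + 3) / len(blocks))))
    basis_cols = []
    for blk in blocks:
        sub = Hp[np.ix_(blk, blk)]
        w, v = scipy.linalg.eigh(sub)
        take = v[:, : min(per_block + 3, blk.size)]
        cols = np.zeros((dof, take.shape[1]))
        cols[blk, :] = take
        basis_cols.append(cols)
    B = _orthonormalize(np.hstack(basis_cols), against=R)
    lam, Q = _rayleigh_ritz(Hp, B, n_work)

    residuals = np.full(n_modes, np.inf)
    converged = False
    for _ in range(max_sweeps):
        Q_old = Q
        for blk in blocks:
            E = np.zeros((dof, blk.size))
            E[blk, np.arange(blk.size)] = 1.0
            B = _orthonormalize(np.hstack([Q, E]), against=R)
            lam, Q = _rayleigh_ritz(Hp, B, n_work)
        overlaps = np.abs(np.sum(Q[:, :n_modes] * Q_old[:, :n_modes], axis=0))
        residuals = 1.0 - np.clip(overlaps, 0.0, 1.0)
        if residuals.max() < conv_tol:
            converged = True
            break
    lam, Q = lam[:n_modes], Q[:, :n_modes]
    if not converged:
        warnings.warn(
            f"mixed-basis iteration not converged after {max_sweeps} sweeps "
            f"(max residual {residuals.max():.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    eigvecs = np.hstack([R, Q])
    eigvals = np.concatenate([np.zeros(k_triv), lam])
    return ModeSet(
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        frequencies=_freqs(eigvals),
        masses=H.masses.copy(),
        n_trivial=k_triv,
        atom_map=H.atom_map,
        converged=converged,
        residuals=residuals,
    )


def _orthonormalize(B: np.ndarray, against: np.ndarray | None = None) -> np.ndarray:
    """QR-orthonormalize columns, optionally deflating a fixed subspace."""
    if against is not None and against.size:
        B = B - against @ (against.T @ B)
    q, r = np.linalg.qr(B)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1e-30)
    return q[:, keep]


def _rayleigh_ritz(
    Hp: np.ndarray, B: np.ndarray, n_modes: int
) -> tuple[np.ndarray, np.ndarray]:
    small = B.T @ Hp @ B
    small = 0.5 * (small + small.T)
    w, v = scipy.linalg.eigh(small)
    take = min(n_modes, w.size)
    return w[:take], B @ v[:, :take]


def cartesian_displacement(
    ms: ModeSet, m: int, amplitude: float
) -> DisplacementVector:
    """Cartesian displacement along 1-based mode ``m`` scaled so the
    mass-weighted RMSD of the displacement equals ``amplitude`` Å.

    The sign convention makes the largest-magnitude Cartesian component
    positive.  Requesting a trivial mode warns but still computes.
    """
    if m <= ms.n_trivial:
        warnings.warn(f"mode {m} is a trivial rigid-body mode", RuntimeWarning, stacklevel=2)
    disp = ms.cartesian_mode(m)  # (N, 3)
    if amplitude == 0.0:
        return _as_dv(ms, np.zeros_like(disp))
    sq = np.sqrt(ms.masses)[:, None]
    mw = disp * sq
    mw_rmsd = float(np.sqrt(np.mean(np.sum(mw**2, axis=1))))
    if mw_rmsd == 0.0:
        return _as_dv(ms, np.zeros_like(disp))
    disp = disp * (amplitude / mw_rmsd)
    flat = disp.reshape(-1)
    if flat[np.argmax(np.abs(flat))] < 0:
        disp = -disp
    return _as_dv(ms, disp)


def _as_dv(ms: ModeSet, comps: np.ndarray) -> DisplacementVector:
    sel = ms.atom_map or AtomSelection(tuple(range(ms.n_atoms)), label="all")
    return DisplacementVector(selection=sel, components=comps, frame="mode")


# --------------------------------------------------------------------------
# NMD export / import (plain-text normal-mode exchange format)
# --------------------------------------------------------------------------

def export_nmd(ms: ModeSet, s: Structure, path: str, title: str = "nmakit") -> None:
    """Write modes in the plain-text NMD dialect used by normal-mode
    viewers: atom metadata lines followed by one ``mode`` line per mode
    (index, inverse-frequency-derived scale, Cartesian components)."""
    sel = ms.atom_map or AtomSelection(tuple(range(len(s.atoms))))
    if len(sel) != ms.n_atoms:
        raise ValueError("atom-count mismatch between ModeSet and Structure")
    atoms = [s.atoms[i] for i in sel.indices]
    with open(path, "w") as fh:
        fh.write(f"nmwiz_load {path}\n")
        fh.write(f"name {title}\n")
        fh.write("atomnames " + " ".join(a.name for a in atoms) + "\n")
        fh.write("resnames " + " ".join(a.resname for a in atoms) + "\n")
        fh.write("resids " + " ".join(str(a.resid) for a in atoms) + "\n")
        fh.write("chainids " + " ".join(a.chain or "A" for a in atoms) + "\n")
        fh.write("bfactors " + " ".join(f"{a.bfactor:.3f}" for a in atoms) + "\n")
        fh.write("masses " + " ".join(f"{m:.8g}" for m in ms.masses) + "\n")
        fh.write(
            "coordinates "
            + " ".join(f"{c:.6f}" for a in atoms for c in a.coord)
            + "\n"
        )
        for m in range(1, ms.n_modes + 1):
            lam = ms.eigenvalues[m - 1]
            scale = 1.0 / np.sqrt(lam) if lam > 1e-12 else 1.0
            comps = ms.cartesian_mode(m).reshape(-1)
            fh.write(
                f"mode {m} {scale:.9g} "
                + " ".join(f"{c:.9g}" for c in comps)
                + "\n"
            )


def import_nmd(path: str) -> tuple[ModeSet, np.ndarray]:
    """Read an NMD file back; returns (ModeSet, coordinates).

    Frequencies are reconstructed from the stored per-mode scale
    (scale = λ^−1/2), so a round trip preserves eigenvectors to 1e-6.
    """
    meta: dict[str, list[str]] = {}
    modes: list[tuple[int, float, np.ndarray]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if key == "mode":
                idx = int(parts[1])
                scale = float(parts[2])
                comps = np.array([float(v) for v in parts[3:]])
                modes.append((idx, scale, comps))
            else:
                meta[key] = parts[1:]
    if "coordinates" not in meta or not modes:
        raise ValueError(f"not a valid NMD file: {path}")
    coords = np.array([float(v) for v in meta["coordinates"]]).reshape(-1, 3)
    masses = (
        np.array([float(v) for v in meta["masses"]])
        if "masses" in meta
        else np.ones(coords.shape[0])
    )
    modes.sort(key=lambda t: t[0])
    cols = []
    lams = []
    sq = np.sqrt(np.repeat(masses, 3))
    for _, scale, comps in modes:
        mw = comps * sq
        norm = np.linalg.norm(mw)
        cols.append(mw / norm if norm > 0 else mw)
        lams.append(1.0 / scale**2 if scale != 1.0 else 0.0)
    eigvals = np.array(lams)
    return (
        ModeSet(
            eigenvectors=np.column_stack(cols),
            eigenvalues=eigvals,
            frequencies=_freqs(eigvals),
            masses=masses,
            n_trivial=_count_trivial(eigvals) if eigvals.size else 0,
        ),
        coords,
    )
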