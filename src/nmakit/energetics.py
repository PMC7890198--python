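"""Hessians and the minimization protocol.

Two Hessian backends are provided: an analytic anisotropic-network-model
(ANM) Hessian over Cα nodes for desk-scale protein work, and a central
finite-difference Hessian of any pluggable :class:`PotentialModel` (used
for the toy potentials that carry closed-form spectra).  The minimizer
follows the classic two-stage protocol: a fixed number of adaptive
steepest-descent steps, then Polak–Ribière conjugate gradient until the
root-mean-square gradient (GRMS) falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np

from .structure import AtomSelection, Structure

__all__ = [
    "PotentialModel",
    "ANMParameters",
    "HessianMatrix",
    "MinimizationTrace",
    "anm_hessian",
    "numerical_hessian",
    "switching_function",
    "switched_pair_potential",
    "minimize",
    "mass_weight",
    "save_hessian",
    "load_hessian",
    "grms",
]


@dataclass
class PotentialModel:
    """Energy surface over 3N Cartesian coordinates (Å → kcal/mol).

    ``gradient`` must be the exact derivative of ``energy``; ``fixed_mask``
    marks per-atom frozen degrees of freedom (no contribution to the
    minimization or to reduced Hessians).
    """

    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    n_atoms: int
    fixed_mask: np.ndarray | None = None  # (N,) bool, True = frozen
    label: str = ""

    def free_dof(self) -> np.ndarray:
        """Boolean (3N,) mask of free coordinates."""
        if self.fixed_mask is None:
            return np.ones(3 * self.n_atoms, dtype=bool)
        return ~np.repeat(np.asarray(self.fixed_mask, dtype=bool), 3)


@dataclass
class ANMParameters:
    """Uniform-spring elastic network parameters."""

    cutoff: float = 15.0  # Å
    gamma: float = 1.0  # kcal/mol/Å²
    masses: np.ndarray | None = None  # per-node amu, default uniform 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gamma <= 0:
            raise ValueError("cutoff and gamma must be positive")


@dataclass
class HessianMatrix:
    """Symmetric 3N×3N second-derivative matrix in kcal/mol/Å²
    (divided by sqrt(m_i m_j) once mass-weighted)."""

    array: np.ndarray
    masses: np.ndarray  # per-atom amu
    mass_weighted: bool = False
    atom_map: AtomSelection | None = None
    coords: np.ndarray | None = None  # (N,3) reference geometry, Å

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        n = self.array.shape[0]
        if self.array.shape != (n, n) or n % 3 != 0:
            raise ValueError("Hessian must be square with order divisible by 3")
        scale = max(np.abs(self.array).max(), 1e-30)
        if np.abs(self.array - self.array.T).max() > 1e-9 * scale:
            raise ValueError("Hessian is not symmetric")
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n // 3,):
            raise ValueError("one mass per atom required")

    @property
    def order(self) -> int:
        return self.array.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.order // 3


@dataclass
class MinimizationTrace:
    """Per-step energy and GRMS record of a minimization run."""

    energies: list[float] = field(default_factory=list)
    grms: list[float] = field(default_factory=list)
    stage: list[str] = field(default_factory=list)

    def append(self, e: float, g: float, stage: str) -> None:
        self.energies.append(float(e))
        self.grms.append(float(g))
        self.stage.append(stage)


# --------------------------------------------------------------------------
# ANM Hessian
# --------------------------------------------------------------------------

def anm_hessian(
    s: Structure, sel: AtomSelection, p: ANMParameters | None = None
) -> HessianMatrix:
    """Anisotropic-network Hessian over the selected nodes.

    Pairs within the cutoff contribute the super-element −γ (d⊗d)/|d|²;
    diagonal blocks are the negative sums of the off-diagonal blocks, which
    makes the matrix exactly translation invariant.
    """
    p = p or ANMParameters()
    if len(sel) < 2:
        raise ValueError("ANM needs at least 2 selected atoms")
    xyz = s.coords[list(sel.indices)]
    n = len(sel)
    H = np.zeros((3 * n, 3 * n))
    d2cut = p.cutoff**2
    neighbor_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = xyz[j] - xyz[i]
            r2 = float(d @ d)
            if r2 > d2cut or r2 == 0.0:
                continue
            block = -p.gamma * np.outer(d, d) / r2
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
            neighbor_count[i] += 1
            neighbor_count[j] += 1
    if np.any(neighbor_count == 0):
        warnings.warn(
            f"{int(np.sum(neighbor_count == 0))} node(s) have no neighbor within "
            f"{p.cutoff} Å; the network is disconnected",
            RuntimeWarning,
            stacklevel=2,
        )
    masses = (
        np.asarray(p.masses, dtype=float) if p.masses is not None else np.ones(n)
    )
    return HessianMatrix(array=H, masses=masses, atom_map=sel, coords=xyz)


def anm_potential(
    coords0: np.ndarray, p: ANMParameters | None = None
) -> PotentialModel:
    """The ANM energy 0.5 γ Σ (|r_ij| − |r⁰_ij|)² as a PotentialModel
    (used to cross-check the analytic Hessian by finite differences)."""
    p = p or ANMParameters()
    x0 = np.asarray(coords0, dtype=float).reshape(-1, 3)
    n = x0.shape[0]
    pairs = [
        (i, j, float(np.linalg.norm(x0[j] - x0[i])))
        for i in range(n)
        for j in range(i + 1, n)
        if 0 < np.linalg.norm(x0[j] - x0[i]) <= p.cutoff
    ]

    def energy(x: np.ndarray) -> float:
        xr = x.reshape(-1, 3)
        e = 0.0
        for i, j, r0 in pairs:
            r = float(np.linalg.norm(xr[j] - xr[i]))
            e += 0.5 * p.gamma * (r - r0) ** 2
        return e

    def gradient(x: np.ndarray) -> np.ndarray:
        xr = x.reshape(-1, 3)
        g = np.zeros_like(xr)
        for i, j, r0 in pairs:
            d = xr[j] - xr[i]
            r = float(np.linalg.norm(d))
            f = p.gamma * (r - r0) / r * d
            g[j] += f
            g[i] -= f
        return g.reshape(-1)

    return PotentialModel(energy=energy, gradient=gradient, n_atoms=n, label="ANM")


# --------------------------------------------------------------------------
# Numerical Hessian of a pluggable potential
# --------------------------------------------------------------------------

def numerical_hessian(
    pot: PotentialModel,
    coords: np.ndarray,
    step: float = 1e-4,
    masses: np.ndarray | None = None,
) -> HessianMatrix:
    """Central finite differences of the gradient, symmetrized as
    (H + Hᵀ)/2.  Fixed atoms' rows and columns are removed."""
    x = np.asarray(coords, dtype=float).reshape(-1)
    if x.size != 3 * pot.n_atoms:
        raise ValueError("coordinate size mismatch with potential")
    free = pot.free_dof()
    idx = np.nonzero(free)[0]
    m = idx.size
    H = np.zeros((m, m))
    for col, k in enumerate(idx):
        xp = x.copy()
        xm = x.copy()
        xp[k] += step
        xm[k] -= step
        gp = np.asarray(pot.gradient(xp), dtype=float)
        gm = np.asarray(pot.gradient(xm), dtype=float)
        if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
            raise FloatingPointError(f"non-finite gradient in stencil at dof {k}")
        H[:, col] = (gp[idx] - gm[idx]) / (2.0 * step)
    H = 0.5 * (H + H.T)
    if masses is None:
        masses_full = np.ones(pot.n_atoms)
    else:
        masses_full = np.asarray(masses, dtype=float)
    if pot.fixed_mask is not None:
        masses_red = masses_full[~np.asarray(pot.fixed_mask, dtype=bool)]
    else:
        masses_red = masses_full
    return HessianMatrix(array=H, masses=masses_red, coords=x.reshape(-1, 3))


# --------------------------------------------------------------------------
# Switched nonbonded pair potential
# --------------------------------------------------------------------------

def switching_function(r: float, cut_on: float = 6.0, cut_off: float = 10.0) -> float:
    """C¹-continuous cubic energy switch:
    S = 1 for r ≤ cut_on, 0 for r ≥ cut_off, and in between
    S(r) = (r_off² − r²)² (r_off² + 2r² − 3 r_on²) / (r_off² − r_on²)³.
    """
    if not 0 < cut_on < cut_off:
        raise ValueError("require 0 < cut_on < cut_off")
    if r <= cut_on:
        return 1.0
    if r >= cut_off:
        return 0.0
    ron2, roff2, r2 = cut_on**2, cut_off**2, r**2
    return (roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2) / (roff2 - ron2) ** 3


def switched_pair_potential(
    qi: float,
    qj: float,
    lj_params: tuple[float, float],
    r: float,
    cut_on: float = 6.0,
    cut_off: float = 10.0,
    rel_dielectric: float = 3.0,
) -> float:
    """Coulomb (scaled by the relative dielectric) + Lennard-Jones pair
    energy, multiplied by the cubic switching function.

    ``lj_params`` is (ε_min kcal/mol, r_min Å) in the well-depth/minimum-
    distance convention: E_LJ = ε[(r_min/r)¹² − 2(r_min/r)⁶].
    """
    from .constants import COULOMB_KCAL_A

    if r <= 0:
        raise ZeroDivisionError("pair distance must be positive")
    eps, rmin = lj_params
    coul = COULOMB_KCAL_A * qi * qj / (rel_dielectric * r)
    s6 = (rmin / r) ** 6
    lj = eps * (s6 * s6 - 2.0 * s6)
    return (coul + lj) * switching_function(r, cut_on, cut_off)


# --------------------------------------------------------------------------
# Minimization
# --------------------------------------------------------------------------

def grms(g: np.ndarray, free: np.ndarray | None = None) -> float:
    """Root-mean-square of the gradient over free coordinates,
    kcal/mol/Å."""
    g = np.asarray(g, dtype=float)
    if free is not None:
        g = g[free]
    return float(np.sqrt(np.mean(g**2))) if g.size else 0.0


def minimize(
    pot: PotentialModel,
    coords: np.ndarray,
    sd_steps: int = 1000,
    grms_tol: float = 1e-4,
    max_cg_steps: int = 20000,
    sd_initial_step: float = 0.02,
) -> tuple[np.ndarray, MinimizationTrace]:
    """Steepest descent with adaptive step size followed by Polak–Ribière
    conjugate gradient until GRMS < ``grms_tol``.

    The SD step halves on an energy increase (step rejected) and grows by
    1.2× on a decrease.  CG restarts on loss of descent direction.  Fixed
    atoms never move.
    """
    x = np.asarray(coords, dtype=float).reshape(-1).copy()
    free = pot.free_dof()
    trace = MinimizationTrace()

    e = float(pot.energy(x))
    if not np.isfinite(e):
        raise FloatingPointError("non-finite initial energy")
    g = np.asarray(pot.gradient(x), dtype=float).copy()
    g[~free] = 0.0
    trace.append(e, grms(g, free), "start")

    # --- stage 1: adaptive steepest descent -------------------------------
    step = sd_initial_step
    for _ in range(sd_steps):
        if grms(g, free) < grms_tol:
            break
        gnorm = np.linalg.norm(g)
        if gnorm == 0.0:
            break
        direction = -g / gnorm
        x_trial = x + step * direction
        e_trial = float(pot.energy(x_trial))
        if not np.isfinite(e_trial):
            raise FloatingPointError("non-finite energy during steepest descent")
        if e_trial < e:
            x, e = x_trial, e_trial
            g = np.asarray(pot.gradient(x), dtype=float).copy()
            g[~free] = 0.0
            step *= 1.2
        else:
            step *= 0.5
        trace.append(e, grms(g, free), "sd")

    # --- stage 2: Polak–Ribière conjugate gradient ------------------------
    d = -g
    g_old = g
    n_free = int(np.sum(free))
    since_restart = 0
    for _ in range(max_cg_steps):
        if grms(g_old, free) < grms_tol:
            break
        alpha = _line_search(pot, x, d, g_old, e, free)
        if alpha is None:
            # restart along steepest descent; if that also fails, stop
            if np.allclose(d, -g_old):
                break
            d = -g_old
            since_restart = 0
            continue
        x = x + alpha * d
        e = float(pot.energy(x))
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during conjugate gradient")
        g_new = np.asarray(pot.gradient(x), dtype=float).copy()
        g_new[~free] = 0.0
        beta = float(g_new @ (g_new - g_old)) / max(float(g_old @ g_old), 1e-300)
        since_restart += 1
        if beta < 0.0 or since_restart >= n_free:
            beta = 0.0
            since_restart = 0
        d = -g_new + beta * d
        if float(d @ g_new) >= 0.0:  # not a descent direction
            d = -g_new
            since_restart = 0
        g_old = g_new
        trace.append(e, grms(g_old, free), "cg")
    return x, trace


def _line_search(
    pot: PotentialModel,
    x: np.ndarray,
    d: np.ndarray,
    g: np.ndarray,
    e0: float,
    free: np.ndarray,
) -> float | None:
    """Backtracking/expanding Armijo line search along ``d``.
    Returns the accepted step or None."""
    slope = float(g @ d)
    if slope >= 0.0:
        return None
    dnorm = float(np.linalg.norm(d))
    alpha = min(1.0, 0.5 / dnorm) if dnorm > 0 else 1.0
    # expand while the quadratic keeps improving
    best = None
    e_prev = e0
    for _ in range(60):
        e_trial = float(pot.energy(x + alpha * d))
        if np.isfinite(e_trial) and e_trial <= e0 + 1e-4 * alpha * slope:
            if best is None or e_trial < best[1]:
                best = (alpha, e_trial)
            if e_trial > e_prev:  # passed the minimum along the line
                break
            e_prev = e_trial
            alpha *= 2.0
        else:
            if best is not None:
                break
            alpha *= 0.5
            if alpha * dnorm < 1e-14:
                return None
    return best[0] if best else None


# --------------------------------------------------------------------------
# Mass weighting & plain-text export
# --------------------------------------------------------------------------

def mass_weight(H: HessianMatrix, masses: np.ndarray | None = None) -> HessianMatrix:
    """Divide each 3×3 block by sqrt(m_i m_j); flags the result."""
    if H.mass_weighted:
        raise ValueError("Hessian is already mass-weighted")
    m = np.asarray(masses, dtype=float) if masses is not None else H.masses
    if m.shape != (H.n_atoms,) or np.any(m <= 0):
        raise ValueError("need one positive mass per atom")
    invs = 1.0 / np.sqrt(np.repeat(m, 3))
    A = H.array * np.outer(invs, invs)
    return HessianMatrix(
        array=A, masses=m, mass_weighted=True, atom_map=H.atom_map, coords=H.coords
    )


def save_hessian(H: HessianMatrix, path: str, threshold: float = 0.0) -> None:
    """Plain-text sparse triplet export with a small header."""
    with open(path, "w") as fh:
        fh.write(f"# nmakit hessian order={H.order} mass_weighted={int(H.mass_weighted)}\n")
        fh.write("# masses: " + " ".join(f"{m:.8g}" for m in H.masses) + "\n")
        rows, cols = np.nonzero(np.triu(np.abs(H.array) > threshold))
        for i, j in zip(rows, cols):
            fh.write(f"{i} {j} {H.array[i, j]:.17g}\n")


def load_hessian(path: str) -> HessianMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        order = int(next(t.split("=")[1] for t in header if t.startswith("order=")))
        mw = bool(int(next(t.split("=")[1] for t in header if t.startswith("mass_weighted="))))
        masses = np.array([float(v) for v in fh.readline().split(":")[1].split()])
        A = np.zeros((order, order))
        for line in fh:
            i_s, j_s, v_s = line.split()
            i, j, v = int(i_s), int(j_s), float(v_s)
            A[i, j] = v
            A[j, i] = v
    return HessianMatrix(array=A, masses=masses, mass_weighted=mw)
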