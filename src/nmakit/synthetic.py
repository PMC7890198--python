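"""Synthetic fixtures with known ground truth.

Every generator is pure given (parameters, seed): toy potentials with
closed-form vibrational spectra, ideal α/3₁₀/π polyalanine helices built
from canonical backbone dihedrals, two-conformation hinge systems whose
softest internal motion is the open↔closed transition, and structures
decorated with prescribed B-factor profiles.  These stand in for
experimental systems so the entire analysis surface can be validated
offline.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import scipy.linalg

from .energetics import PotentialModel
from .flexibility import fluct_to_bfactor
from .structure import Atom, Structure

__all__ = [
    "harmonic_chain",
    "ideal_helix",
    "hinge_pair",
    "decorated_structure",
    "perturbed_copy",
    "random_cloud_structure",
    "CANONICAL_DIHEDRALS",
]

#: Conventional backbone dihedrals (φ, ψ) in degrees per helix type.
CANONICAL_DIHEDRALS: dict[str, tuple[float, float]] = {
    "alpha": (-57.0, -47.0),
    "310": (-49.0, -26.0),
    "pi": (-57.0, -70.0),
}


# --------------------------------------------------------------------------
# Harmonic chain: toy potential with a closed-form longitudinal spectrum
# --------------------------------------------------------------------------

def harmonic_chain(
    N: int,
    k: float = 1.0,
    m: float = 1.0,
    ends: str = "free",
    spacing: float = 1.0,
    k_transverse: float = 100.0,
) -> tuple[PotentialModel, np.ndarray, np.ndarray]:
    """1-D harmonic chain embedded in 3-D along x.

    Longitudinal nearest-neighbour springs of constant ``k`` plus stiff
    harmonic transverse restraints decouple the x spectrum exactly; the
    returned analytic eigenvalues (kcal/mol/Å²/amu, ascending) come from
    direct diagonalization of the N×N tridiagonal stiffness matrix — the
    independent oracle for the Hessian/modes pipeline.  ``ends="fixed"``
    freezes the two end beads (their DoF drop out).

    Returns ``(potential, coords, longitudinal_eigenvalues)``.
    """
    if N < 2:
        raise ValueError("chain needs at least 2 beads")
    if ends not in ("free", "fixed"):
        raise ValueError("ends must be 'free' or 'fixed'")
    coords = np.zeros((N, 3))
    coords[:, 0] = spacing * np.arange(N)
    ref = coords.copy()

    def energy(x: np.ndarray) -> float:
        xr = x.reshape(-1, 3)
        dx = np.diff(xr[:, 0]) - spacing
        e = 0.5 * k * float(np.sum(dx**2))
        e += 0.5 * k_transverse * float(np.sum((xr[:, 1:] - ref[:, 1:]) ** 2))
        return e

    def gradient(x: np.ndarray) -> np.ndarray:
        xr = x.reshape(-1, 3)
        g = np.zeros_like(xr)
        dx = np.diff(xr[:, 0]) - spacing
        g[:-1, 0] -= k * dx
        g[1:, 0] += k * dx
        g[:, 1:] = k_transverse * (xr[:, 1:] - ref[:, 1:])
        return g.reshape(-1)

    fixed = None
    if ends == "fixed":
        fixed = np.zeros(N, dtype=bool)
        fixed[0] = fixed[-1] = True

    pot = PotentialModel(
        energy=energy, gradient=gradient, n_atoms=N, fixed_mask=fixed,
        label=f"harmonic chain N={N}",
    )

    # tridiagonal stiffness oracle (x DoF only)
    K = np.zeros((N, N))
    for i in range(N - 1):
        K[i, i] += k
        K[i + 1, i + 1] += k
        K[i, i + 1] -= k
        K[i + 1, i] -= k
    if ends == "fixed":
        K = K[1:-1, 1:-1]
    lam = np.sort(scipy.linalg.eigvalsh(K / m))
    return pot, coords, lam


# --------------------------------------------------------------------------
# Ideal helices (NeRF internal-coordinate builder)
# --------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.01}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8, "C-N-H": 119.5}
_OMEGA = 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D from A-B-C internal coordinates (angle/dihedral in deg)."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m_ = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m_ + d_local[2] * n


def ideal_helix(
    n_res: int,
    helix_type: str = "alpha",
    build_H: bool = False,
    chain: str = "A",
    phi: float | None = None,
    psi: float | None = None,
) -> Structure:
    """Polyalanine backbone (N, CA, C, O, optional amide H) with ideal bond
    geometry and the canonical (φ, ψ) of the requested helix type."""
    if n_res < 6:
        raise ValueError("need at least 6 residues for a meaningful helix")
    if phi is None or psi is None:
        try:
            phi, psi = CANONICAL_DIHEDRALS[helix_type]
        except KeyError as exc:
            raise ValueError(f"unknown helix type {helix_type!r}") from exc

    # seed residue placed explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = backbone[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"], _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca = _nerf(prev["CA"], prev["C"], n, _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
        c = _nerf(prev["C"], n, ca, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        backbone.append({"N": n, "CA": ca, "C": c})

    # carbonyl O anti to the next amide N (dihedral ψ+180); last O uses ψ+180 too
    for i, res in enumerate(backbone):
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _BOND["C-O"],
                         _ANGLE["CA-C-O"], psi + 180.0)
        if build_H and i > 0:
            prev = backbone[i - 1]
            res["H"] = _nerf(prev["O"], prev["C"], res["N"], _BOND["N-H"],
                             _ANGLE["C-N-H"], 180.0)

    atoms: list[Atom] = []
    serial = 1
    order = ["N", "H", "CA", "C", "O"] if build_H else ["N", "CA", "C", "O"]
    masses = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999, "H": 1.008}
    for i, res in enumerate(backbone):
        for name in order:
            if name not in res:
                continue
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="H" if name == "H" else name[0],
                    resname="ALA",
                    resid=i + 1,
                    chain=chain,
                    altloc="",
                    coord=res[name],
                    mass=masses[name],
                )
            )
            serial += 1
    return Structure(atoms=atoms, title=f"ideal {helix_type} helix", source="synthetic")


def bent_helix(
    n_res: int, bend_deg: float, helix_type: str = "alpha", junction: int | None = None
) -> Structure:
    """Ideal helix whose second half is rigidly rotated by ``bend_deg``
    about an axis perpendicular to the helix axis through the junction Cα —
    a constructed ground truth for kink-angle recovery.  Backbone geometry
    at the junction is not repaired (only the Cα trace matters here)."""
    s = ideal_helix(n_res, helix_type)
    junction = junction if junction is not None else n_res // 2
    ca = np.array([a.coord for a in s.atoms if a.name == "CA"])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    t = math.radians(bend_deg)
    K = np.array(
        [[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]], [-perp[1], perp[0], 0]]
    )
    R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
    pivot = ca[junction - 1]
    out = s.copy()
    for a in out.atoms:
        if a.resid > junction:
            a.coord = (a.coord - pivot) @ R.T + pivot
    return out


# --------------------------------------------------------------------------
# Hinge pair: two-domain toy with a known open↔closed motion
# --------------------------------------------------------------------------

def hinge_pair(
    n_per_domain: int = 20,
    hinge_angle_open: float = 30.0,
    hinge_angle_closed: float = 60.0,
    seed: int = 0,
    spacing: float = 3.8,
    jitter: float = 0.3,
) -> tuple[Structure, Structure]:
    """Two compact pseudo-domains (jittered cubic lattices of Cα beads)
    joined by a 3-bead linker; the closed form rigidly rotates the second
    domain about the hinge axis.  Same topology and atom order in both.
    """
    if abs(hinge_angle_open - hinge_angle_closed) < 10.0:
        raise ValueError("hinge angles must differ by at least 10°")
    rng = np.random.default_rng(seed)

    def lattice(n: int) -> np.ndarray:
        side = int(math.ceil(n ** (1.0 / 3.0)))
        pts = []
        for ix in range(side):
            for iy in range(side):
                for iz in range(side):
                    pts.append((ix, iy, iz))
                    if len(pts) == n:
                        return np.array(pts, dtype=float) * spacing
        return np.array(pts[:n], dtype=float) * spacing

    domA = lattice(n_per_domain)
    domA += rng.normal(0.0, jitter, domA.shape)
    domB = lattice(n_per_domain)
    domB += rng.normal(0.0, jitter, domB.shape)

    extentA = domA[:, 0].max()
    linker = np.array(
        [[extentA + spacing * (i + 1), 0.0, 0.0] for i in range(3)]
    )
    hinge_point = linker[1].copy()
    domB = domB + linker[2] + np.array([spacing, 0.0, 0.0])

    def rotate_about_z(pts: np.ndarray, angle_deg: float) -> np.ndarray:
        t = math.radians(angle_deg)
        Rz = np.array(
            [[math.cos(t), -math.sin(t), 0.0], [math.sin(t), math.cos(t), 0.0], [0.0, 0.0, 1.0]]
        )
        return (pts - hinge_point) @ Rz.T + hinge_point

    def build(angle: float) -> Structure:
        pts = np.vstack([domA, linker[:2], rotate_about_z(np.vstack([linker[2:], domB]), angle)])
        atoms = [
            Atom(
                serial=i + 1,
                name="CA",
                element="C",
                resname="GLY",
                resid=i + 1,
                chain="A",
                altloc="",
                coord=p,
                mass=12.011,
            )
            for i, p in enumerate(pts)
        ]
        return Structure(atoms=atoms, title=f"hinge toy {angle:g} deg", source="synthetic")

    return build(hinge_angle_open), build(hinge_angle_closed)


# --------------------------------------------------------------------------
# Decorations & perturbations
# --------------------------------------------------------------------------

def decorated_structure(
    base: Structure,
    bfactor_profile: np.ndarray | None = None,
    fluct_profile: np.ndarray | None = None,
) -> Structure:
    """Copy of ``base`` with the B-factor column overwritten by a
    per-residue profile (given directly in Å², or as fluctuations in Å
    through B = 8π²f²/3)."""
    if (bfactor_profile is None) == (fluct_profile is None):
        raise ValueError("give exactly one of bfactor_profile / fluct_profile")
    if bfactor_profile is None:
        bfactor_profile = fluct_to_bfactor(np.asarray(fluct_profile, dtype=float))
    bfactor_profile = np.asarray(bfactor_profile, dtype=float)
    residues = base.residues()
    if bfactor_profile.shape != (len(residues),):
        raise ValueError(
            f"profile length {bfactor_profile.size} != residue count {len(residues)}"
        )
    value_of = {
        (ch, ri): b for (ch, ri, _), b in zip(residues, bfactor_profile)
    }
    out = base.copy()
    for a in out.atoms:
        a.bfactor = float(value_of[(a.chain, a.resid)])
    return out


def perturbed_copy(base: Structure, amplitude: float, seed: int = 0) -> Structure:
    """i.i.d. Gaussian displacement of every atom (σ = amplitude per
    Cartesian component), deterministic per seed."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    out = base.copy()
    if amplitude > 0:
        out.coords = out.coords + rng.normal(0.0, amplitude, (len(base), 3))
    return out


def folded_chain_structure(
    n: int, step: float = 3.8, seed: int = 0, compactness: float = 0.15
) -> Structure:
    """Compact self-intersection-free-ish random walk of Cα beads with a
    fixed step; consecutive beads are always within one step, so an
    elastic network with any cutoff ≥ ``step`` is connected."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    for _ in range(1, n):
        d = rng.normal(size=3)
        d -= compactness * pts[-1] / step  # gentle pull toward the origin
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + step * d)
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element="C",
            resname="GLY",
            resid=i + 1,
            chain="A",
            altloc="",
            coord=p,
            mass=12.011,
        )
        for i, p in enumerate(pts)
    ]
    return Structure(atoms=atoms, title="folded chain", source="synthetic")


def random_cloud_structure(n: int, extent: float = 10.0, seed: int = 0) -> Structure:
    """Uniform random Cα bead cloud — generic geometry fixture."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-extent, extent, (n, 3))
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element="C",
            resname="GLY",
            resid=i + 1,
            chain="A",
            altloc="",
            coord=p,
            mass=12.011,
        )
        for i, p in enumerate(pts)
    ]
    return Structure(atoms=atoms, title="random cloud", source="synthetic")
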