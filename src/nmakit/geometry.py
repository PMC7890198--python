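"""Structural measurements: group minimum distances, hydrogen bonds,
backbone H-bond-pattern helix classification and helix axis curvature/kink.

Helix typing follows the hydrogen-bond ladder definition: a residue whose
backbone carbonyl O accepts from the amide N of residue i+3 belongs to a
3₁₀ helix, i+4 to an α helix and i+5 to a π helix.  When hydrogens are
absent (crystal structures) a heavy-atom donor–acceptor distance criterion
is used instead of the H···A distance/angle test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal
import math
import warnings

import numpy as np

from .structure import Atom, AtomSelection, SelectionError, Structure

__all__ = [
    "HBond",
    "HelixAssignment",
    "min_group_distance",
    "hbond_detect",
    "classify_helix",
    "helix_axis_and_kink",
    "PROTEIN_DONORS",
    "PROTEIN_ACCEPTORS",
]

#: Sidechain/backbone donor heavy atoms per residue type ("*" = any residue).
PROTEIN_DONORS: dict[str, set[str]] = {
    "*": {"N"},
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "HOH": {"O"},
}

#: Acceptor heavy atoms per residue type.
PROTEIN_ACCEPTORS: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HOH": {"O"},
}


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond with its geometry and which criterion
    fired."""

    donor: Atom
    acceptor: Atom
    hydrogen: Atom | None
    d_DA: float
    d_HA: float | None
    angle_DHA: float | None
    criterion: Literal["geometric", "heavy-atom-only"]


@dataclass
class HelixAssignment:
    """Per-residue helix label and maximal segments (runs ≥ 3)."""

    resids: list[int]
    labels: list[str]  # "alpha" | "310" | "pi" | "none"
    segments: list[tuple[str, int, int]]  # (label, start resid, end resid)
    alternates: dict[int, list[str]] | None = None  # extra patterns per resid


def min_group_distance(
    s: Structure, selA: AtomSelection, selB: AtomSelection
) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum Euclidean distance over all cross pairs and the realizing
    atom pair."""
    if selA.empty or selB.empty:
        raise SelectionError("both selections must be non-empty")
    xa = s.coords[list(selA.indices)]
    xb = s.coords[list(selB.indices)]
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return (
        float(math.sqrt(d2[i, j])),
        (s.atoms[selA.indices[i]], s.atoms[selB.indices[j]]),
    )


def _attached_hydrogens(s: Structure, max_bond: float = 1.25) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of bonded hydrogens (same residue)."""
    out: dict[int, list[int]] = {}
    by_res: dict[tuple, list[int]] = {}
    for i, a in enumerate(s.atoms):
        by_res.setdefault((a.chain, a.resid, a.icode), []).append(i)
    for members in by_res.values():
        heavies = [i for i in members if not s.atoms[i].is_hydrogen]
        hydros = [i for i in members if s.atoms[i].is_hydrogen]
        for h in hydros:
            if not heavies:
                continue
            d = [np.linalg.norm(s.atoms[h].coord - s.atoms[i].coord) for i in heavies]
            k = int(np.argmin(d))
            if d[k] <= max_bond:
                out.setdefault(heavies[k], []).append(h)
    # amide H of residue i may precede N in some files; residue-local search
    # already covers backbone N-H, which is all the classifier needs
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def hbond_detect(
    s: Structure,
    donors: AtomSelection | None = None,
    acceptors: AtomSelection | None = None,
    d_HA_max: float = 2.5,
    d_DA_max: float = 3.5,
    angle_min: float = 120.0,
    mode: Literal["auto", "geometric", "heavy-atom-only"] = "auto",
) -> list[HBond]:
    """Detect hydrogen bonds between donor and acceptor heavy atoms.

    With hydrogens present (and ``mode`` auto/geometric) a bond requires
    d(H···A) ≤ ``d_HA_max`` and angle D-H···A ≥ ``angle_min``; otherwise
    the heavy-atom fallback d(D···A) ≤ ``d_DA_max`` applies.  Donor and
    acceptor default to the standard protein dictionaries.
    """

    def default_sel(table: dict[str, set[str]]) -> AtomSelection:
        idx = [
            i
            for i, a in enumerate(s.atoms)
            if a.name in table.get(a.resname, set()) | table["*"]
            and not a.is_hydrogen
        ]
        return AtomSelection(tuple(idx))

    donors = donors if donors is not None else default_sel(PROTEIN_DONORS)
    acceptors = acceptors if acceptors is not None else default_sel(PROTEIN_ACCEPTORS)
    hyd = _attached_hydrogens(s) if mode != "heavy-atom-only" else {}

    bonds: list[HBond] = []
    acc_xyz = s.coords[list(acceptors.indices)]
    for di in donors.indices:
        d_atom = s.atoms[di]
        dist = np.linalg.norm(acc_xyz - d_atom.coord, axis=1)
        for k, ai in enumerate(acceptors.indices):
            if ai == di:
                continue
            a_atom = s.atoms[ai]
            if (a_atom.chain, a_atom.resid, a_atom.icode) == (
                d_atom.chain,
                d_atom.resid,
                d_atom.icode,
            ) and {d_atom.name, a_atom.name} <= {"N", "O", "OXT"}:
                continue  # intra-residue backbone N..O is a covalent neighborhood
            d_DA = float(dist[k])
            if d_DA > max(d_DA_max, d_HA_max + 1.2):
                continue
            hs = hyd.get(di, [])
            use_geometric = mode == "geometric" or (mode == "auto" and bool(hs))
            if use_geometric and hs:
                for hi in hs:
                    h_atom = s.atoms[hi]
                    d_HA = float(np.linalg.norm(a_atom.coord - h_atom.coord))
                    ang = _angle(d_atom.coord, h_atom.coord, a_atom.coord)
                    if d_HA <= d_HA_max and ang >= angle_min:
                        bonds.append(
                            HBond(d_atom, a_atom, h_atom, d_DA, d_HA, ang, "geometric")
                        )
                        break
            else:
                if d_DA <= d_DA_max:
                    bonds.append(
                        HBond(d_atom, a_atom, None, d_DA, None, None, "heavy-atom-only")
                    )
    return bonds


def classify_helix(
    s: Structure,
    chain: str,
    resid_range: tuple[int, int] | None = None,
    d_HA_max: float = 2.5,
    d_DA_max: float = 3.5,
    angle_min: float = 120.0,
) -> HelixAssignment:
    """Label each residue by its carbonyl's acceptor pattern:
    O(i)→N(i+3) ⇒ 3₁₀, O(i)→N(i+4) ⇒ α, O(i)→N(i+5) ⇒ π, with priority
    α > π > 3₁₀ when several patterns coexist (all recorded).
    Segments are maximal runs of at least 3 equal labels."""
    res_atoms: dict[int, dict[str, int]] = {}
    for i, a in enumerate(s.atoms):
        if a.chain != chain:
            continue
        if resid_range is not None and not resid_range[0] <= a.resid <= resid_range[1]:
            continue
        res_atoms.setdefault(a.resid, {})[a.name] = i
    resids = sorted(res_atoms)
    hyd = _attached_hydrogens(s)

    def bonded(i_res: int, j_res: int) -> bool:
        """Carbonyl O of i_res accepting from amide N of j_res?"""
        oi = res_atoms.get(i_res, {}).get("O")
        nj = res_atoms.get(j_res, {}).get("N")
        if oi is None or nj is None:
            return False
        o_xyz = s.atoms[oi].coord
        n_atom = s.atoms[nj]
        hs = hyd.get(nj, [])
        if hs:
            for hi in hs:
                h = s.atoms[hi]
                d_HA = float(np.linalg.norm(o_xyz - h.coord))
                ang = _angle(n_atom.coord, h.coord, o_xyz)
                if d_HA <= d_HA_max and ang >= angle_min:
                    return True
            return False
        return float(np.linalg.norm(o_xyz - n_atom.coord)) <= d_DA_max

    labels: list[str] = []
    alternates: dict[int, list[str]] = {}
    priority = ["alpha", "pi", "310"]
    offset = {"310": 3, "alpha": 4, "pi": 5}
    for r in resids:
        present = {"N", "CA", "C", "O"} <= set(res_atoms[r])
        if not present:
            warnings.warn(
                f"residue {r} of chain {chain} lacks backbone atoms; labeled none",
                RuntimeWarning,
                stacklevel=2,
            )
            labels.append("none")
            continue
        found = [lab for lab in priority if bonded(r, r + offset[lab])]
        if not found:
            labels.append("none")
        else:
            labels.append(found[0])
            if len(found) > 1:
                alternates[r] = found
    segments: list[tuple[str, int, int]] = []
    i = 0
    while i < len(resids):
        j = i
        while j + 1 < len(resids) and labels[j + 1] == labels[i] and resids[j + 1] == resids[j] + 1:
            j += 1
        if labels[i] != "none" and j - i + 1 >= 3:
            segments.append((labels[i], resids[i], resids[j]))
        i = j + 1
    return HelixAssignment(
        resids=resids,
        labels=labels,
        segments=segments,
        alternates=alternates or None,
    )


def _axis_points(ca: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window Cα centroids approximating the local helix axis."""
    n = ca.shape[0]
    if n < window + 2:
        raise ValueError(f"need at least {window + 2} Cα atoms, got {n}")
    return np.array([ca[i : i + window].mean(axis=0) for i in range(n - window + 1)])


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Best-fit line direction through points, oriented along the sequence."""
    centered = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    d = Vt[0]
    if d @ (points[-1] - points[0]) < 0:
        d = -d
    return d


def helix_axis_and_kink(
    s: Structure,
    chain: str,
    range1: tuple[int, int],
    range2: tuple[int, int],
    window: int = 4,
) -> tuple[np.ndarray, float, float]:
    """Local helix axis polyline plus the kink angle between the two
    residue ranges and the mean per-residue turning angle (curvature).

    Returns ``(axis_points, kink_deg, curvature_deg_per_residue)``.
    """

    def ca_of(r: tuple[int, int]) -> np.ndarray:
        pts = [
            a.coord
            for a in s.atoms
            if a.chain == chain and a.name == "CA" and r[0] <= a.resid <= r[1]
        ]
        return np.array(pts)

    ca1, ca2 = ca_of(range1), ca_of(range2)
    ax1, ax2 = _axis_points(ca1, window), _axis_points(ca2, window)
    d1, d2 = _fit_direction(ax1), _fit_direction(ax2)
    kink = math.degrees(math.acos(max(-1.0, min(1.0, float(d1 @ d2)))))

    full = np.vstack([ax1, ax2])
    seg = np.diff(full, axis=0)
    turning = []
    for u, v in zip(seg[:-1], seg[1:]):
        cosang = float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        turning.append(math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))
    curvature = float(np.mean(turning)) if turning else 0.0
    return full, float(kink), curvature
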