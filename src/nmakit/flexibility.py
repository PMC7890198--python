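"""Mode-derived atomic fluctuations, B-factor interconversion, difference
profiles, chelating-group averages and per-mode correlation maps.

The fluctuation of atom i from a set of modes is

    f_i = sqrt( (k_B T / m_i) Σ_m a_im² / ω_m² )

with a_im the mass-weighted mode components and the sum over the chosen
nontrivial modes.  In the package's internal units (kcal/mol, Å, amu) the
eigenvalue λ_m = ω_m² can be used directly and f comes out in Å.  The
default temperature of 1300 K is a display-scaling convention — harmonic
all-atom fluctuations are systematically undervalued relative to
crystallographic B-factors, and this temperature brings them onto the
same scale; it is NOT a physical temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping
import math
import warnings

import numpy as np
import pandas as pd

from .constants import KB_KCAL_PER_MOL_K
from .modes import ModeSet
from .structure import AtomSelection, Structure

__all__ = [
    "FluctuationProfile",
    "CorrelationMap",
    "mode_fluctuations",
    "bfactor_to_fluct",
    "fluct_to_bfactor",
    "bfactor_fluctuations",
    "difference_profile",
    "group_fluctuations",
    "mode_correlation_map",
    "CALCIUM_SITE_GROUPS",
]

#: Oxygen groups chelating the two Ca²⁺ ions of a P-type ATPase transport
#: site: carboxyl O of E309/E771/D800/E908, hydroxyl O of T799, sidechain
#: amide O of N768/N796, backbone carbonyl O of V304/A305/I307.
CALCIUM_SITE_GROUPS: dict[str, list[tuple[int, str]]] = {
    "E309 carboxyl": [(309, "OE1"), (309, "OE2")],
    "E771 carboxyl": [(771, "OE1"), (771, "OE2")],
    "D800 carboxyl": [(800, "OD1"), (800, "OD2")],
    "E908 carboxyl": [(908, "OE1"), (908, "OE2")],
    "T799 hydroxyl": [(799, "OG1")],
    "N768 amide": [(768, "OD1")],
    "N796 amide": [(796, "OD1")],
    "V304 carbonyl": [(304, "O")],
    "A305 carbonyl": [(305, "O")],
    "I307 carbonyl": [(307, "O")],
}


@dataclass
class FluctuationProfile:
    """Per-atom fluctuations f_i in Å with provenance."""

    values: np.ndarray  # (n,) Å
    aggregation: Literal["atom", "residue-CA", "group"] = "atom"
    provenance: str = ""
    atom_map: AtomSelection | None = None
    labels: list | None = None  # residue/group labels when aggregated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("fluctuations must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels if self.labels is not None else list(range(len(self)))
        return pd.DataFrame({"label": labels, "f_A": self.values})


@dataclass
class CorrelationMap:
    """Per-mode Cα×Cα orientational correlation matrix in [−1, 1]."""

    matrix: np.ndarray
    mode_index: int
    mask: np.ndarray | None = None  # True where undefined

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.shape[0] != C.shape[1]:
            raise ValueError("correlation matrix must be square")
        valid = ~(self.mask if self.mask is not None else np.zeros(C.shape[0], bool))
        sub = C[np.ix_(valid, valid)]
        if sub.size:
            if np.abs(sub - sub.T).max() > 1e-9:
                raise ValueError("correlation matrix must be symmetric")
            if np.abs(np.diag(sub) - 1.0).max() > 1e-9 or np.abs(sub).max() > 1.0 + 1e-9:
                raise ValueError("correlations must have unit diagonal and |C| ≤ 1")
        self.matrix = C


def mode_fluctuations(
    ms: ModeSet,
    T: float = 1300.0,
    mode_range: Iterable[int] | None = None,
) -> FluctuationProfile:
    """Thermal fluctuation amplitude per atom from a mode sum.

    ``mode_range`` defaults to every nontrivial mode in the set; a zero
    eigenvalue inside the range raises (the formula divides by ω²).
    """
    modes = list(mode_range) if mode_range is not None else list(ms.nontrivial_range())
    msd = np.zeros(ms.n_atoms)
    for m in modes:
        lam = float(ms.eigenvalues[m - 1])
        if lam <= 0.0:
            raise ZeroDivisionError(
                f"mode {m} has non-positive eigenvalue {lam:g}; "
                "exclude trivial/imaginary modes from the fluctuation sum"
            )
        a2 = np.sum(ms.mode(m).reshape(-1, 3) ** 2, axis=1)
        msd += a2 / lam
    msd *= KB_KCAL_PER_MOL_K * T / ms.masses
    return FluctuationProfile(
        values=np.sqrt(msd),
        aggregation="atom",
        provenance=f"modes(T={T:g} K, modes {modes[0]}..{modes[-1]})",
        atom_map=ms.atom_map,
    )


def bfactor_to_fluct(B):
    """f = (1/π)·sqrt(3B/8): isotropic displacement amplitude (Å) from a
    crystallographic B-factor (Å²)."""
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("B-factors must be non-negative")
    out = np.sqrt(3.0 * B / 8.0) / math.pi
    return float(out) if out.ndim == 0 else out


def fluct_to_bfactor(f):
    """Inverse of :func:`bfactor_to_fluct`: B = 8π²f²/3."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("fluctuations must be non-negative")
    out = 8.0 * math.pi**2 * f**2 / 3.0
    return float(out) if out.ndim == 0 else out


def bfactor_fluctuations(s: Structure, sel: AtomSelection) -> FluctuationProfile:
    """Fluctuation profile taken from the crystal B-factor column."""
    B = s.bfactors[list(sel.indices)]
    return FluctuationProfile(
        values=bfactor_to_fluct(B),
        aggregation="atom",
        provenance="bfactor",
        atom_map=sel,
    )


def difference_profile(
    fA: FluctuationProfile,
    fB: FluctuationProfile,
    mapping: Mapping[int, int] | None = None,
    threshold: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Δf = fA − fB per mapped position and the indices where
    |Δf| exceeds ``threshold`` (0.2 Å by default, the scale at which
    localized flexibility changes become meaningful against profile noise).

    ``mapping`` maps positions of fA onto positions of fB (identity when
    both profiles are aligned already).
    """
    if mapping is None:
        if len(fA) != len(fB):
            raise ValueError("profiles differ in length and no mapping given")
        delta = fA.values - fB.values
    else:
        idxA = np.array(sorted(mapping), dtype=int)
        idxB = np.array([mapping[i] for i in idxA], dtype=int)
        delta = fA.values[idxA] - fB.values[idxB]
    flagged = np.nonzero(np.abs(delta) > threshold)[0]
    return delta, flagged


def group_fluctuations(
    f: FluctuationProfile,
    s: Structure,
    groups: Mapping[str, list[tuple[int, str]]] | None = None,
    chain: str | None = None,
) -> dict[str, float]:
    """Arithmetic mean fluctuation of named atom groups.

    ``groups`` maps a label to (resid, atom-name) pairs; the shipped
    :data:`CALCIUM_SITE_GROUPS` table covers the transport-site chelating
    oxygens of a P-type Ca²⁺ pump.
    """
    groups = groups if groups is not None else CALCIUM_SITE_GROUPS
    sel = f.atom_map or AtomSelection(tuple(range(len(s.atoms))))
    lookup: dict[tuple[str, int, str], int] = {}
    for row, i in enumerate(sel.indices):
        a = s.atoms[i]
        lookup[(a.chain, a.resid, a.name)] = row
    out: dict[str, float] = {}
    for label, members in groups.items():
        rows = []
        for resid, name in members:
            hits = [
                r
                for (ch, ri, nm), r in lookup.items()
                if ri == resid and nm == name and (chain is None or ch == chain)
            ]
            if not hits:
                raise KeyError(f"group {label!r}: atom {name} of residue {resid} not found")
            rows.extend(hits)
        out[label] = float(np.mean(f.values[rows]))
    return out


def mode_correlation_map(
    ms: ModeSet, m: int, sel: AtomSelection | None = None
) -> CorrelationMap:
    """C_ij = cos angle between atoms i and j's 3-component displacement
    sub-vectors in mode ``m``; +1 is concerted motion, −1 opposed.

    Atoms with a zero sub-vector are masked (row/column undefined) with a
    warning rather than erroring.
    """
    from .transition import mode_components

    comps = mode_components(ms, m, sel, cartesian=True).reshape(-1, 3)
    norms = np.linalg.norm(comps, axis=1)
    mask = norms == 0.0
    if np.any(mask):
        warnings.warn(
            f"{int(mask.sum())} atom(s) have zero displacement in mode {m}; "
            "their correlations are masked",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(mask, 1.0, norms)
    unit = comps / safe[:, None]
    C = unit @ unit.T
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    C[mask, :] = np.nan
    C[:, mask] = np.nan
    return CorrelationMap(matrix=C, mode_index=m, mask=mask)
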