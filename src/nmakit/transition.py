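"""Mode-overlap analysis of conformational transitions.

The central statistic is the overlap percentage
p = [v₁·v₂ / (‖v₁‖‖v₂‖)]² × 100 between a normal mode and the difference
coordinate vector ΔR between two superposed conformations, evaluated over
Cα atoms only so sidechain noise never dominates the direction.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .modes import ModeSet
from .structure import AtomSelection, DisplacementVector, PairingError

__all__ = [
    "OverlapResult",
    "overlap_percentage",
    "mode_components",
    "mode_difference_scan",
    "mode_cross_projection",
    "cumulative_overlap",
]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of one mode with a target vector."""

    mode_index: int  # 1-based
    frequency: float  # cm⁻¹
    p: float  # percent, in [0, 100]
    target_label: str = ""


def overlap_percentage(v1: np.ndarray, v2: np.ndarray) -> float:
    """Squared normalized dot product × 100; symmetric and sign-invariant."""
    v1 = np.asarray(v1, dtype=float).reshape(-1)
    v2 = np.asarray(v2, dtype=float).reshape(-1)
    if v1.shape != v2.shape:
        raise PairingError(f"vector lengths differ ({v1.size} vs {v2.size})")
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        raise ZeroDivisionError("overlap undefined for a zero-norm vector")
    c = float(v1 @ v2) / (n1 * n2)
    return c * c * 100.0


def mode_components(
    ms: ModeSet,
    m: int,
    sel: AtomSelection | None = None,
    cartesian: bool = True,
) -> np.ndarray:
    """Flattened components of 1-based mode ``m`` restricted to ``sel``.

    ``sel`` indexes the same structure as ``ms.atom_map``; with
    ``cartesian=True`` (default) the mode is de-mass-weighted before
    restriction, matching projections onto coordinate differences.
    """
    full = ms.cartesian_mode(m) if cartesian else ms.mode(m).reshape(-1, 3)
    if sel is None:
        return full.reshape(-1)
    map_idx = (
        ms.atom_map.indices
        if ms.atom_map is not None
        else tuple(range(ms.n_atoms))
    )
    pos = {atom_i: row for row, atom_i in enumerate(map_idx)}
    try:
        rows = [pos[i] for i in sel.indices]
    except KeyError as exc:
        raise PairingError(
            f"selection atom {exc.args[0]} is not covered by the mode set"
        ) from exc
    return full[rows].reshape(-1)


def mode_difference_scan(
    ms: ModeSet,
    dv: DisplacementVector,
    sel: AtomSelection | None = None,
    mode_range: range | None = None,
    cartesian: bool = True,
    target_label: str = "ΔR",
) -> list[OverlapResult]:
    """Overlap of each mode in ``mode_range`` (default: all nontrivial
    modes) with the difference vector, over the selection the vector was
    built on."""
    sel = sel if sel is not None else dv.selection
    if len(sel) != len(dv.selection):
        raise PairingError("selection does not match the displacement vector")
    target = dv.flat
    if mode_range is None:
        mode_range = ms.nontrivial_range()
    out = []
    for m in mode_range:
        v = mode_components(ms, m, sel, cartesian=cartesian)
        out.append(
            OverlapResult(
                mode_index=m,
                frequency=float(ms.frequencies[m - 1]),
                p=overlap_percentage(v, target),
                target_label=target_label,
            )
        )
    return out


def argmax_overlap(results: list[OverlapResult]) -> OverlapResult:
    if not results:
        raise ValueError("empty overlap scan")
    return max(results, key=lambda r: r.p)


def mode_cross_projection(
    msA: ModeSet,
    m: int,
    msB: ModeSet,
    mode_range: range | None = None,
    sel: AtomSelection | None = None,
    cartesian: bool = True,
) -> list[OverlapResult]:
    """Project one mode of system A onto every mode of system B over a
    shared atom correspondence; the highest p identifies B's motion most
    similar to A's mode ``m``."""
    vA = mode_components(msA, m, sel, cartesian=cartesian)
    if mode_range is None:
        mode_range = msB.nontrivial_range()
    out = []
    for n in mode_range:
        vB = mode_components(msB, n, sel, cartesian=cartesian)
        out.append(
            OverlapResult(
                mode_index=n,
                frequency=float(msB.frequencies[n - 1]),
                p=overlap_percentage(vA, vB),
                target_label=f"mode {m} of reference system",
            )
        )
    return out


def cumulative_overlap(
    ms: ModeSet,
    dv: DisplacementVector,
    mode_subset,
    sel: AtomSelection | None = None,
    cartesian: bool = True,
) -> float:
    """Sum of per-mode overlaps over a subset of modes.

    Over a complete orthonormal basis of the projection space the sum is
    exactly 100 (Parseval); restricted all-atom modes are generally not
    orthogonal on the subspace, so sums above 100 are capped with a
    warning.
    """
    subset = list(mode_subset)
    if not subset:
        return 0.0
    total = sum(
        r.p
        for r in mode_difference_scan(
            ms, dv, sel=sel, mode_range=subset, cartesian=cartesian
        )
    )
    if total > 100.0 + 1e-6:
        warnings.warn(
            f"cumulative overlap {total:.2f}% exceeds 100%: restricted modes "
            "are not orthogonal on this subspace; reporting 100%",
            RuntimeWarning,
            stacklevel=2,
        )
        return 100.0
    return float(total)
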