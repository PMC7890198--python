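"""Molecular structures in PDB format: parsing, selection, superposition,
difference vectors and coordinate-level editing.

The in-memory model is deliberately flat — an ordered list of :class:`Atom`
records — because the atom order defines the 3N coordinate layout shared by
every downstream matrix (Hessians, mode sets, displacement vectors).
Parsing and writing go through :mod:`gemmi`; everything above the file
format is owned by this module.
"""

from __future__ import annotations

import math
import os
import re
import urllib.request
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "AtomSelection",
    "DisplacementVector",
    "StructureError",
    "PairingError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "fetch_pdb",
    "select",
    "kabsch_superpose",
    "rmsd",
    "difference_vector",
    "transplant_ligand",
    "solvent_shell",
    "radius_of_gyration",
    "pair_by_residue",
    "WATER_RESNAMES",
]

#: Residue names recognised as water across common force-field dialects.
WATER_RESNAMES = {"HOH", "TIP3", "TIP", "WAT", "SOL", "H2O"}

_ION_RESNAMES = {"MG", "NA", "K", "CL", "CA", "ZN", "MN", "SOD", "POT", "CLA"}


class StructureError(ValueError):
    """Malformed input or empty result at the structure level."""


class PairingError(ValueError):
    """Two structures/selections could not be put in 1:1 correspondence."""


class SelectionError(ValueError):
    """Malformed selection expression."""


@dataclass
class Atom:
    """One atom record in PDB column convention."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    altloc: str
    coord: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    bfactor: float = 0.0
    mass: float = 0.0  # amu
    icode: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")
        if self.bfactor < 0:
            raise StructureError(f"negative B-factor for atom {self.serial}")

    @property
    def is_water(self) -> bool:
        return self.resname.strip() in WATER_RESNAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def key(self) -> tuple:
        return (self.chain, self.resid, self.icode, self.name)


@dataclass
class Structure:
    """Ordered collection of atoms; order defines the 3N layout."""

    atoms: list[Atom]
    title: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order, Å."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coord = row.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([a.bfactor for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, coord=a.coord.copy()) for a in self.atoms],
            title=self.title,
            source=self.source,
        )

    def subset(self, sel: "AtomSelection") -> "Structure":
        return Structure(
            atoms=[replace(self.atoms[i], coord=self.atoms[i].coord.copy()) for i in sel.indices],
            title=self.title,
            source=self.source,
        )

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, resid, resname) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resid, a.resname), None)
        return list(seen)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered positions into a Structure's atom list."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SelectionError("selection indices must be strictly increasing")
        if idx and idx[0] < 0:
            raise SelectionError("negative selection index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def empty(self) -> bool:
        return len(self.indices) == 0


@dataclass
class DisplacementVector:
    """Per-atom displacement over a named selection, after superposition."""

    selection: AtomSelection
    components: np.ndarray  # (n_sel, 3) Å
    frame: str = ""

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (len(self.selection), 3):
            raise StructureError("one 3-vector per selected atom required")

    @property
    def flat(self) -> np.ndarray:
        return self.components.reshape(-1)


# --------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# --------------------------------------------------------------------------

def _element_of(gatom: gemmi.Atom, name: str) -> str:
    el = gatom.element.name
    if el and el != "X":
        return el
    # PDB v3.3 fallback: strip digits, use the leading letter(s)
    stripped = re.sub(r"[0-9'\"]", "", name).strip()
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Mg", "Na", "Zn", "Fe", "Mn"):
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def read_pdb(
    path: str,
    chains: Iterable[str] | None = None,
    model: int | None = None,
    altloc_policy: Literal["keep-highest-occupancy", "keep-first"] = "keep-highest-occupancy",
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Atom order follows the file.  Masses are assigned from standard atomic
    weights.  Alternate locations are resolved per ``altloc_policy``
    (ties under keep-highest-occupancy go to altloc 'A', then alphabetical).
    """
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message passthrough
        raise StructureError(f"unparseable PDB file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path!r}")
    gmodel = st[model - 1] if model is not None else st[0]
    chain_set = set(chains) if chains is not None else None

    atoms: list[Atom] = []
    for gchain in gmodel:
        if chain_set is not None and gchain.name not in chain_set:
            continue
        for gres in gchain:
            # group atoms by name to resolve altlocs
            by_name: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for ga in gres:
                if ga.name not in by_name:
                    order.append(ga.name)
                by_name.setdefault(ga.name, []).append(ga)
            for name in order:
                group = by_name[name]
                if len(group) == 1:
                    ga = group[0]
                elif altloc_policy == "keep-first":
                    ga = group[0]
                else:
                    ga = sorted(
                        group, key=lambda g: (-g.occ, g.altloc or "A")
                    )[0]
                el = _element_of(ga, name)
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=name.strip(),
                        element=el,
                        resname=gres.name.strip(),
                        resid=gres.seqid.num,
                        chain=gchain.name,
                        altloc=(ga.altloc or ""),
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        bfactor=max(ga.b_iso, 0.0),
                        mass=gemmi.Element(el).weight,
                        icode=(gres.seqid.icode or "").strip(),
                        het=gres.het_flag == "H",
                    )
                )
    if not atoms:
        raise StructureError(
            f"empty structure after chain filter {sorted(chain_set) if chain_set else None} in {path!r}"
        )
    return Structure(atoms=atoms, title=st.name or "", source=path)


def write_pdb(s: Structure, path: str) -> None:
    """Write a Structure back to standard PDB format (coords to 1e-3 Å)."""
    # group consecutively by (chain, residue); gemmi's add_* copy by value,
    # so each container must be complete before insertion
    res_groups: list[tuple[tuple, list[Atom]]] = []
    for a in s.atoms:
        key = (a.chain, a.resid, a.icode, a.resname)
        if not res_groups or res_groups[-1][0] != key:
            res_groups.append((key, []))
        res_groups[-1][1].append(a)

    st = gemmi.Structure()
    st.name = s.title or "nmakit"
    gmodel = gemmi.Model("1")
    current_chain: str | None = None
    pending: list[gemmi.Residue] = []

    def flush_chain() -> None:
        if current_chain is None:
            return
        gchain = gemmi.Chain(current_chain)
        for gres in pending:
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)

    for (chain, resid, icode, resname), members in res_groups:
        if chain != current_chain:
            flush_chain()
            current_chain = chain
            pending = []
        gres = gemmi.Residue()
        gres.name = resname
        gres.seqid = gemmi.SeqId(resid, icode or " ")
        gres.het_flag = "H" if members[0].het else "A"
        for a in members:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            ga.b_iso = a.bfactor
            ga.altloc = a.altloc if a.altloc else "\0"
            ga.serial = a.serial
            gres.add_atom(ga)
        pending.append(gres)
    flush_chain()
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(path)


def fetch_pdb(pdb_id: str, cache_dir: str | None = None, timeout: float = 10.0) -> str:
    """Download a public PDB entry (with a local cache); returns the file path.

    Raises ``OSError`` when the entry is not cached and the network is
    unreachable.
    """
    pdb_id = pdb_id.lower()
    cache_dir = cache_dir or os.path.join(
        os.environ.get("XDG_CACHE_HOME", os.path.expanduser("~/.cache")), "nmakit"
    )
    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(cache_dir, f"{pdb_id}.pdb")
    if os.path.exists(path) and os.path.getsize(path) > 0:
        return path
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    with open(path, "wb") as fh:
        fh.write(data)
    return path


# --------------------------------------------------------------------------
# Selection expressions
# --------------------------------------------------------------------------
#
# Grammar (documented for config files):
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := unary ("and" unary)*
#   unary    := "not" unary | "(" expr ")" | term
#   term     := "chain" ID+ | "resid" RANGE+ | "name" ID+ | "element" ID+
#             | "resname" ID+ | "heavy" | "protein" | "water" | "ion" | "all"
#   RANGE    := INT | INT "-" INT  (author numbering, inclusive)

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL", "MSE",
}


class _SelParser:
    def __init__(self, expr: str):
        self.tokens = _TOKEN_RE.findall(expr)
        if not self.tokens:
            raise SelectionError("empty selection expression")
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(f"trailing token {self.peek()!r}")
        return node

    def parse_or(self):
        nodes = [self.parse_and()]
        while self.peek() == "or":
            self.next()
            nodes.append(self.parse_and())
        return nodes[0] if len(nodes) == 1 else ("or", nodes)

    def parse_and(self):
        nodes = [self.parse_unary()]
        while self.peek() == "and":
            self.next()
            nodes.append(self.parse_unary())
        return nodes[0] if len(nodes) == 1 else ("and", nodes)

    def parse_unary(self):
        tok = self.peek()
        if tok == "not":
            self.next()
            return ("not", self.parse_unary())
        if tok == "(":
            self.next()
            node = self.parse_or()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return node
        return self.parse_term()

    def parse_term(self):
        kw = self.next().lower()
        if kw in ("heavy", "protein", "water", "ion", "all", "hydrogen"):
            return (kw,)
        if kw not in ("chain", "resid", "name", "element", "resname"):
            raise SelectionError(f"unknown selection keyword {kw!r}")
        args: list[str] = []
        stop = {"and", "or", "not", "(", ")"}
        while self.peek() is not None and self.peek() not in stop:
            args.append(self.next())
        if not args:
            raise SelectionError(f"keyword {kw!r} needs at least one argument")
        if kw == "resid":
            ranges: list[tuple[int, int]] = []
            for a in args:
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", a)
                if not m:
                    raise SelectionError(f"bad resid range {a!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                ranges.append((lo, hi))
            return ("resid", ranges)
        return (kw, [a.upper() for a in args])


def _eval_sel(node, atom: Atom) -> bool:
    op = node[0]
    if op == "or":
        return any(_eval_sel(n, atom) for n in node[1])
    if op == "and":
        return all(_eval_sel(n, atom) for n in node[1])
    if op == "not":
        return not _eval_sel(node[1], atom)
    if op == "all":
        return True
    if op == "heavy":
        return not atom.is_hydrogen
    if op == "hydrogen":
        return atom.is_hydrogen
    if op == "water":
        return atom.is_water
    if op == "ion":
        return atom.resname.strip() in _ION_RESNAMES
    if op == "protein":
        return atom.resname.strip() in _AMINO3
    if op == "chain":
        return atom.chain.upper() in node[1]
    if op == "name":
        return atom.name.upper() in node[1]
    if op == "element":
        return atom.element.upper() in node[1]
    if op == "resname":
        return atom.resname.upper() in node[1]
    if op == "resid":
        return any(lo <= atom.resid <= hi for lo, hi in node[1])
    raise SelectionError(f"unknown node {op!r}")  # pragma: no cover


def select(s: Structure, expr: str, label: str | None = None) -> AtomSelection:
    """Evaluate a selection expression; empty selections are allowed."""
    tree = _SelParser(expr).parse()
    idx = tuple(i for i, a in enumerate(s.atoms) if _eval_sel(tree, a))
    return AtomSelection(indices=idx, label=label if label is not None else expr)


# --------------------------------------------------------------------------
# Superposition & comparison
# --------------------------------------------------------------------------

def _check_pairs(selA: AtomSelection, selB: AtomSelection) -> None:
    if len(selA) != len(selB):
        raise PairingError(
            f"paired selections differ in size ({len(selA)} vs {len(selB)})"
        )
    if len(selA) < 3:
        raise PairingError("at least 3 paired atoms are required")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of two matched point sets.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``reference``; ``R`` is a proper rotation (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise PairingError("matched (n,3) coordinate arrays required")
    if P.shape[0] < 3:
        raise PairingError("at least 3 paired atoms are required")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cP, Q - cQ
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise PairingError("degenerate (collinear) geometry in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - cP @ R.T
    fitted = P @ R.T + t
    value = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, value


def rmsd(
    A: Structure,
    B: Structure,
    selA: AtomSelection,
    selB: AtomSelection,
    superpose: bool = True,
) -> float:
    """RMSD (Å) over paired selections, optionally after optimal superposition."""
    _check_pairs(selA, selB)
    PA = A.coords[list(selA.indices)]
    PB = B.coords[list(selB.indices)]
    if superpose:
        _, _, value = kabsch_superpose(PB, PA)
        return value
    return float(np.sqrt(np.mean(np.sum((PA - PB) ** 2, axis=1))))


def difference_vector(
    A: Structure,
    B: Structure,
    selA: AtomSelection,
    selB: AtomSelection,
    frame: str = "A",
) -> DisplacementVector:
    """ΔR = R_B − R_A per paired atom, in A's frame.

    B is superposed onto A over the same paired selection before the
    difference is taken, so rigid-body offsets never contribute.
    """
    _check_pairs(selA, selB)
    PA = A.coords[list(selA.indices)]
    PB = B.coords[list(selB.indices)]
    R, t, _ = kabsch_superpose(PB, PA)
    fitted = PB @ R.T + t
    return DisplacementVector(selection=selA, components=fitted - PA, frame=frame)


def pair_by_residue(
    A: Structure,
    B: Structure,
    atom_name: str = "CA",
    chain_map: dict[str, str] | None = None,
) -> tuple[AtomSelection, AtomSelection]:
    """Match atoms named ``atom_name`` across two structures by
    (chain, resid, icode), over the intersection of shared residues.

    ``chain_map`` maps A's chain ids to B's (identity by default).
    """
    chain_map = chain_map or {}

    def index(s: Structure, use_map: bool) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for i, a in enumerate(s.atoms):
            if a.name.upper() != atom_name.upper() or a.is_water:
                continue
            ch = chain_map.get(a.chain, a.chain) if use_map else a.chain
            key = (ch, a.resid, a.icode)
            out.setdefault(key, i)
        return out

    mapA = index(A, use_map=True)
    mapB = index(B, use_map=False)
    pairs = sorted((mapA[k], mapB[k]) for k in mapA if k in mapB)
    if len(pairs) < 3:
        raise PairingError(
            f"only {len(pairs)} shared {atom_name} residues between structures"
        )
    idxB = [p[1] for p in pairs]
    if idxB != sorted(idxB):
        raise PairingError(
            "shared residues appear in different order in the two structures; "
            "provide explicit paired selections instead"
        )
    selA = AtomSelection(tuple(p[0] for p in pairs), label=f"{atom_name} shared")
    selB = AtomSelection(tuple(idxB), label=f"{atom_name} shared")
    return selA, selB


# --------------------------------------------------------------------------
# Editing operations
# --------------------------------------------------------------------------

def transplant_ligand(
    target: Structure,
    donor: Structure,
    ligand_sel: AtomSelection,
    contact_cutoff: float = 5.0,
    target_ligand_sel: AtomSelection | None = None,
    fit_atoms: Literal["CA", "heavy"] = "CA",
) -> Structure:
    """Copy a ligand from a donor structure into the target by local
    superposition of the ligand's contact shell.

    The shell is every target residue having a heavy atom within
    ``contact_cutoff`` Å of the target's own ligand; the donor is superposed
    onto the target over the shell's Cα (or all heavy) atoms, then the donor
    ligand coordinates replace the target ligand.
    """
    if ligand_sel.empty:
        raise SelectionError("no ligand atoms selected in donor")
    if target_ligand_sel is None:
        # default: same residue names as the donor ligand
        lig_res = {donor.atoms[i].resname for i in ligand_sel.indices}
        target_ligand_sel = AtomSelection(
            tuple(i for i, a in enumerate(target.atoms) if a.resname in lig_res),
            label="target ligand",
        )
    if target_ligand_sel.empty:
        raise SelectionError("no ligand in target to define the contact shell")

    lig_xyz = target.coords[list(target_ligand_sel.indices)]
    lig_idx = set(target_ligand_sel.indices)
    shell_res: set[tuple[str, int, str]] = set()
    for i, a in enumerate(target.atoms):
        if i in lig_idx or a.is_hydrogen or a.is_water:
            continue
        if np.min(np.linalg.norm(lig_xyz - a.coord, axis=1)) <= contact_cutoff:
            shell_res.add((a.chain, a.resid, a.icode))
    if not shell_res:
        raise StructureError(f"empty contact shell at cutoff {contact_cutoff} Å")

    def shell_atoms(s: Structure) -> dict[tuple, np.ndarray]:
        out = {}
        for a in s.atoms:
            if (a.chain, a.resid, a.icode) not in shell_res:
                continue
            if fit_atoms == "CA" and a.name != "CA":
                continue
            if fit_atoms == "heavy" and a.is_hydrogen:
                continue
            out[(a.chain, a.resid, a.icode, a.name)] = a.coord
        return out

    ta = shell_atoms(target)
    da = shell_atoms(donor)
    shared = [k for k in ta if k in da]
    if len(shared) < 3:
        raise PairingError("fewer than 3 shared shell atoms between target and donor")
    R, t, _ = kabsch_superpose(
        np.array([da[k] for k in shared]), np.array([ta[k] for k in shared])
    )

    new_atoms: list[Atom] = [
        replace(a, coord=a.coord.copy())
        for i, a in enumerate(target.atoms)
        if i not in lig_idx
    ]
    for i in ligand_sel.indices:
        a = donor.atoms[i]
        new_atoms.append(replace(a, coord=a.coord @ R.T + t))
    return Structure(atoms=new_atoms, title=target.title, source=target.source)


def solvent_shell(
    s: Structure,
    solute_sel: AtomSelection,
    cutoff: float = 2.8,
    include_ions: bool = True,
) -> AtomSelection:
    """Whole water molecules (and optionally ions) with any atom within
    ``cutoff`` Å of a solute heavy atom.  Molecules are kept or dropped
    atomically, never split.
    """
    if solute_sel.empty:
        raise SelectionError("empty solute selection")
    solute = np.array(
        [
            s.atoms[i].coord
            for i in solute_sel.indices
            if not s.atoms[i].is_hydrogen
        ]
    )
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(s.atoms):
        if a.is_water or (include_ions and a.resname.strip() in _ION_RESNAMES):
            groups.setdefault((a.chain, a.resid, a.icode, a.resname), []).append(i)
    kept: list[int] = []
    for members in groups.values():
        xyz = np.array([s.atoms[i].coord for i in members])
        d2 = np.min(
            np.sum((xyz[:, None, :] - solute[None, :, :]) ** 2, axis=2)
        )
        if d2 <= cutoff**2:
            kept.extend(members)
    return AtomSelection(tuple(sorted(kept)), label=f"solvent shell {cutoff} Å")


def radius_of_gyration(
    s: Structure, sel: AtomSelection, mass_weighted: bool = True
) -> float:
    """Second-moment radius (Å) about the (mass-weighted) centroid."""
    if sel.empty:
        raise SelectionError("empty selection for radius of gyration")
    xyz = s.coords[list(sel.indices)]
    if mass_weighted:
        w = s.masses[list(sel.indices)]
        if np.any(w <= 0):
            raise StructureError("non-positive masses in mass-weighted Rg")
    else:
        w = np.ones(len(sel))
    center = np.average(xyz, axis=0, weights=w)
    return float(
        math.sqrt(np.average(np.sum((xyz - center) ** 2, axis=1), weights=w))
    )
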