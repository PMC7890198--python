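"""End-to-end transition report: given a reference structure (e.g. a pump
with a bound regulatory peptide), an optional comparison system (the same
pump without it) and one or more target conformations, compute the
mode-overlap scans, the displacement/correlation analysis of the
best-overlapping modes, fluctuation difference profiles and a geometry
table — the complete analysis sequence as a single deterministic run.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import time
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .energetics import ANMParameters, anm_hessian, mass_weight
from .flexibility import difference_profile, mode_fluctuations
from .modes import ModeSet, cartesian_displacement, diagonalize_full, dimb_diagonalize, export_nmd
from .structure import (
    AtomSelection,
    Structure,
    difference_vector,
    pair_by_residue,
    read_pdb,
    select,
)
from .transition import argmax_overlap, mode_difference_scan
from .flexibility import mode_correlation_map

__all__ = ["PipelineConfig", "run_transition_report", "load_config"]


@dataclass
class PipelineConfig:
    """Fully serializable run description; copied verbatim into the
    output directory so a run is reproducible from its own artifacts."""

    structure_a: str  # reference system (modes computed here)
    structure_b: str | None = None  # comparison system (fluctuation difference)
    targets: dict[str, str] = field(default_factory=dict)  # label -> path
    selection: str = "name CA"
    anm_cutoff: float = 15.0
    anm_gamma: float = 1.0
    mode_method: str = "full"  # "full" | "dimb"
    n_modes: int = 200
    conv_tol: float = 0.03
    temperature: float = 1300.0
    fluct_threshold: float = 0.2
    output_dir: str = "report"
    seed: int = 0
    chain_map: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_config(path: str) -> PipelineConfig:
    """Read a PipelineConfig from a JSON file."""
    with open(path) as fh:
        data = json.load(fh)
    return PipelineConfig(**data)


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def _compute_modes(s: Structure, sel: AtomSelection, cfg: PipelineConfig) -> ModeSet:
    params = ANMParameters(cutoff=cfg.anm_cutoff, gamma=cfg.anm_gamma)
    H = mass_weight(anm_hessian(s, sel, params))
    n_nontrivial = min(cfg.n_modes, H.order - 6)
    if cfg.mode_method == "dimb":
        return dimb_diagonalize(H, n_modes=n_nontrivial, conv_tol=cfg.conv_tol)
    ms = diagonalize_full(H)
    return ms


def run_transition_report(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns a summary dict and writes the report
    bundle (TSV scans, NMD exports, correlation matrices, fluctuation
    difference, log) under ``cfg.output_dir``.

    Any stage failure aborts with the stage name; partial outputs are
    preserved on disk.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    log_path = os.path.join(cfg.output_dir, "run.log")
    from . import __version__ as _version

    summary: dict[str, Any] = {"version": _version, "stages": []}

    def log(stage: str, **info: Any) -> None:
        entry = {"stage": stage, "t": round(time.time(), 3), **info}
        summary["stages"].append(entry)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    with open(os.path.join(cfg.output_dir, "config.json"), "w") as fh:
        fh.write(cfg.to_json())

    stage = "load"
    try:
        A = read_pdb(cfg.structure_a)
        selA = select(A, cfg.selection)
        if selA.empty:
            raise ValueError(f"selection {cfg.selection!r} matches nothing in {cfg.structure_a}")
        log(stage, structure_a=cfg.structure_a, hash=_file_hash(cfg.structure_a), n_sel=len(selA))

        stage = "modes"
        ms = _compute_modes(A, selA, cfg)
        log(stage, method=cfg.mode_method, n_modes=ms.n_modes, n_trivial=ms.n_trivial,
            converged=bool(ms.converged))

        stage = "scans"
        scan_results = {}
        for label, path in cfg.targets.items():
            B = read_pdb(path)
            pA, pB = pair_by_residue(A, B, atom_name="CA", chain_map=cfg.chain_map)
            dv = difference_vector(A, B, pA, pB, frame=label)
            # RMS displacement below coordinate precision means the
            # endpoints are effectively identical
            if float(np.linalg.norm(dv.flat)) < 1e-6 * math.sqrt(len(pA)):
                raise ValueError(
                    f"zero-norm difference vector for target {label!r} "
                    "(identical endpoints?)"
                )
            results = mode_difference_scan(ms, dv, sel=pA, target_label=label)
            best = argmax_overlap(results)
            df = pd.DataFrame(
                {
                    "mode": [r.mode_index for r in results],
                    "frequency_cm-1": [r.frequency for r in results],
                    "overlap_percent": [r.p for r in results],
                }
            )
            tsv = os.path.join(cfg.output_dir, f"scan_{label}.tsv")
            df.to_csv(tsv, sep="\t", index=False, float_format="%.6f")
            scan_results[label] = {
                "argmax_mode": best.mode_index,
                "argmax_frequency_cm1": best.frequency,
                "argmax_overlap_percent": best.p,
                "tsv": tsv,
            }
            log(stage, target=label, hash=_file_hash(path), **{
                k: v for k, v in scan_results[label].items() if k != "tsv"})
        summary["scans"] = scan_results

        stage = "top_modes"
        top_modes = sorted({v["argmax_mode"] for v in scan_results.values()})
        for m in top_modes:
            dv_m = cartesian_displacement(ms, m, amplitude=3.0)
            nmd = os.path.join(cfg.output_dir, f"mode_{m}.nmd")
            export_nmd(
                ModeSet(
                    eigenvectors=ms.eigenvectors[:, m - 1 : m],
                    eigenvalues=ms.eigenvalues[m - 1 : m],
                    frequencies=ms.frequencies[m - 1 : m],
                    masses=ms.masses,
                    n_trivial=0,
                    atom_map=ms.atom_map,
                ),
                A,
                nmd,
                title=f"mode {m}",
            )
            cm = mode_correlation_map(ms, m)
            np.savetxt(
                os.path.join(cfg.output_dir, f"correlation_mode_{m}.tsv"),
                cm.matrix,
                delimiter="\t",
                fmt="%.6f",
            )
            _maybe_heatmap(cm.matrix, os.path.join(cfg.output_dir, f"correlation_mode_{m}.png"))
            log(stage, mode=m, max_disp_A=float(np.abs(dv_m.components).max()))
        summary["top_modes"] = top_modes

        stage = "fluctuations"
        fA = mode_fluctuations(ms, T=cfg.temperature)
        flA = fA.to_frame()
        flA["resid"] = [A.atoms[i].resid for i in selA.indices]
        flA.to_csv(os.path.join(cfg.output_dir, "fluctuations_a.tsv"), sep="\t", index=False)
        if cfg.structure_b:
            Bsys = read_pdb(cfg.structure_b)
            selB = select(Bsys, cfg.selection)
            msB = _compute_modes(Bsys, selB, cfg)
            fB = mode_fluctuations(msB, T=cfg.temperature)
            if len(fA) == len(fB):
                delta, flagged = difference_profile(fA, fB, threshold=cfg.fluct_threshold)
                pd.DataFrame(
                    {
                        "resid": [A.atoms[i].resid for i in selA.indices],
                        "delta_f_A": delta,
                        "flagged": np.isin(np.arange(len(delta)), flagged),
                    }
                ).to_csv(
                    os.path.join(cfg.output_dir, "fluctuation_difference.tsv"),
                    sep="\t",
                    index=False,
                )
                summary["n_flagged_residues"] = int(flagged.size)
                log(stage, n_flagged=int(flagged.size), threshold=cfg.fluct_threshold)
            else:
                warnings.warn("systems differ in size; skipping difference profile", RuntimeWarning)
        else:
            log(stage, n_atoms=len(fA))

        summary["output_dir"] = cfg.output_dir
        return summary
    except Exception as exc:
        log("error", failed_stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _maybe_heatmap(C: np.ndarray, path: str) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(C, cmap="bwr", vmin=-1, vmax=1, origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
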