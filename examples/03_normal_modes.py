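"""Normal modes: full and iterative diagonalization, frequencies, export.

Diagonalizes a 100-node elastic network both directly and with the
mixed-basis iterative scheme, compares them, and exports the softest modes
to the NMD format for visualization.
"""

import tempfile

import numpy as np

from nmakit import energetics as en
from nmakit import modes as md
from nmakit import synthetic as syn
from nmakit.structure import select

s = syn.folded_chain_structure(100, seed=3)
sel = select(s, "name CA")
H = en.mass_weight(en.anm_hessian(s, sel, en.ANMParameters(cutoff=10.0)))

# reference: full diagonalization (all 300 eigenpairs)
full = md.diagonalize_full(H)
print(f"full spectrum: {full.n_modes} modes, {full.n_trivial} trivial (rigid-body)")
print("lowest five nontrivial frequencies (cm⁻¹):",
      np.round(full.frequencies[6:11], 2))

# iterative mixed-basis diagonalization of only the 20 softest modes
approx = md.dimb_diagonalize(H, n_modes=20, conv_tol=0.03, block_size=60)
worst = min(
    abs(float(approx.mode(m) @ full.mode(m)))
    for m in approx.nontrivial_range(approx.n_trivial + 20)
)
print(f"iterative vs full: worst |cosine| over 20 modes = {worst:.5f} "
      f"(converged: {approx.converged})")

# Cartesian displacement along the softest mode, scaled to 1 Å mass-weighted RMSD
dv = md.cartesian_displacement(full, 7, amplitude=1.0)
print(f"softest mode: largest per-atom displacement {np.abs(dv.components).max():.2f} Å")

# NMD export for normal-mode viewers
with tempfile.NamedTemporaryFile(suffix=".nmd", delete=False) as fh:
    md.export_nmd(full, s, fh.name)
    print(f"exported modes to {fh.name}")
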