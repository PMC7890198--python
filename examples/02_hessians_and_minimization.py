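"""Elastic-network Hessians, finite-difference checks and minimization.

Shows the ANM Hessian of a compact Cα toy, verifies it against finite
differences of the network energy, and relaxes a perturbed harmonic chain
with the two-stage minimizer.
"""

import numpy as np

from nmakit import energetics as en
from nmakit import synthetic as syn
from nmakit.structure import select

# ANM Hessian of a 40-bead compact chain
s = syn.folded_chain_structure(40, seed=7)
sel = select(s, "name CA")
params = en.ANMParameters(cutoff=10.0, gamma=1.0)
H = en.anm_hessian(s, sel, params)
print(f"ANM Hessian: order {H.order}, symmetric, translation-invariant")

# cross-check against central finite differences of the network energy
xyz = s.coords[list(sel.indices)]
pot = en.anm_potential(xyz, params)
H_fd = en.numerical_hessian(pot, xyz)
print(f"analytic vs finite-difference max deviation: {np.abs(H.array - H_fd.array).max():.1e}")

# minimize a perturbed harmonic chain: steepest descent, then conjugate gradient
pot_c, coords, _ = syn.harmonic_chain(20, k=1.0)
rng = np.random.default_rng(0)
x0 = coords.ravel() + rng.normal(scale=0.1, size=coords.size)
x_min, trace = en.minimize(pot_c, x0, sd_steps=200)
print(
    f"minimized: E {pot_c.energy(x0):.4f} -> {pot_c.energy(x_min):.2e} kcal/mol, "
    f"GRMS {en.grms(pot_c.gradient(x_min)):.1e} kcal/mol/Å in {len(trace.energies)} steps"
)
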