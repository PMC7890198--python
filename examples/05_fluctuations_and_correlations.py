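"""Thermal fluctuations, B-factors and per-mode correlation maps.

Computes mode-sum fluctuation profiles, converts to/from crystallographic
B-factors, and builds the orientational cross-correlation map of a soft mode.
"""

import numpy as np

from nmakit import energetics as en
from nmakit import flexibility as fx
from nmakit import modes as md
from nmakit import synthetic as syn
from nmakit.structure import select

s = syn.folded_chain_structure(100, seed=3)
sel = select(s, "name CA")
H = en.mass_weight(en.anm_hessian(s, sel, en.ANMParameters(cutoff=10.0)))
ms = md.diagonalize_full(H)

# fluctuation amplitude per bead from the mode sum (f ∝ √T)
f300 = fx.mode_fluctuations(ms, T=300.0)
print(f"fluctuations at 300 K: mean {f300.values.mean():.3f} Å, "
      f"max {f300.values.max():.3f} Å at bead {int(np.argmax(f300.values)) + 1}")

# equivalent crystallographic B-factors, and the exact round trip
B = fx.fluct_to_bfactor(f300.values)
back = fx.bfactor_to_fluct(B)
print(f"B-factor round trip max error: {np.abs(back - f300.values).max():.1e} Å")

# difference profile between two related networks, flagging |Δf| > 0.2 Å
s2 = syn.perturbed_copy(s, 0.4, seed=9)
H2 = en.mass_weight(en.anm_hessian(s2, sel, en.ANMParameters(cutoff=10.0)))
f2 = fx.mode_fluctuations(md.diagonalize_full(H2), T=300.0)
delta, flagged = fx.difference_profile(f300, f2, threshold=0.2)
print(f"fluctuation difference: {flagged.size} of {len(delta)} beads flagged")

# per-mode correlation map: cosine between per-atom displacement directions
cm = fx.mode_correlation_map(ms, 7)
frac_concerted = float(np.mean(cm.matrix > 0.5))
print(f"mode 7 correlation map: {frac_concerted:.0%} of pairs move concertedly (C > 0.5)")
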