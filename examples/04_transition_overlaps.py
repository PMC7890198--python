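"""Which normal mode points toward a conformational change?

Uses the two-domain hinge toy: the open→closed difference vector is scanned
against the open form's ANM modes; the hinge mode shows up as the argmax
with a high overlap percentage.
"""

import numpy as np

from nmakit import energetics as en
from nmakit import modes as md
from nmakit import synthetic as syn
from nmakit import transition as tr
from nmakit.structure import difference_vector, select

open_s, closed_s = syn.hinge_pair(seed=0)
sel = select(open_s, "name CA")

H = en.mass_weight(en.anm_hessian(open_s, sel, en.ANMParameters(cutoff=12.0)))
ms = md.diagonalize_full(H)

# ΔR between the conformations (superposed, so no rigid-body contribution)
dv = difference_vector(open_s, closed_s, sel, sel)
print(f"open→closed motion: RMS ΔR = {np.sqrt(np.mean(dv.flat**2)):.2f} Å")

# overlap p = (cosine)² × 100 of each nontrivial mode with ΔR
results = tr.mode_difference_scan(ms, dv, sel=sel)
best = tr.argmax_overlap(results)
rank = best.mode_index - ms.n_trivial
print(
    f"best mode: #{best.mode_index} (nontrivial rank {rank}), "
    f"{best.frequency:.2f} cm⁻¹, overlap {best.p:.1f}%"
)

# how much of the motion do the ten softest modes capture together?
cum = tr.cumulative_overlap(ms, dv, ms.nontrivial_range(ms.n_trivial + 10), sel=sel)
print(f"cumulative overlap of the 10 softest modes: {cum:.1f}%")
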