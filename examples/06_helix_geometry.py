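"""Hydrogen bonds, helix classification and kink angles.

Classifies ideal α/3₁₀/π helices from their backbone hydrogen-bond ladder
and recovers a constructed 30° kink from the Cα axis geometry.
"""

from nmakit import geometry as ge
from nmakit import synthetic as syn
from nmakit.structure import select

# backbone hydrogen bonds of an α-helix (geometric criterion, H present)
helix = syn.ideal_helix(14, helix_type="alpha", build_H=True)
bonds = ge.hbond_detect(helix)
print(f"α-helix: {len(bonds)} backbone hydrogen bonds "
      f"({bonds[0].criterion} criterion)")

# per-residue helix labels from the O(i)→N(i+3/4/5) acceptor pattern
for kind in ("alpha", "310", "pi"):
    s = syn.ideal_helix(14, helix_type=kind, build_H=True)
    out = ge.classify_helix(s, "A")
    segs = ", ".join(f"{lbl} {a}-{b}" for lbl, a, b in out.segments) or "none"
    print(f"ideal {kind:>5} helix → segments: {segs}")

# kink angle between the two halves of a bent helix
bent = syn.bent_helix(24, bend_deg=30.0)
_, kink, curvature = ge.helix_axis_and_kink(bent, "A", (1, 11), (14, 24))
print(f"constructed 30° bend → recovered kink {kink:.1f}°, "
      f"curvature {curvature:.1f}°/residue")

# minimum distance between two residue groups (with the realizing atom pair)
a = select(helix, "resid 2")
b = select(helix, "resid 9")
d, (atom_a, atom_b) = ge.min_group_distance(helix, a, b)
print(f"closest approach residues 2↔9: {d:.2f} Å ({atom_a.name}···{atom_b.name})")
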