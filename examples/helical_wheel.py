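"""Project a peptide onto a helical wheel and inspect its faces.

The wheel advances 100 degrees per residue; 18 residues close five turns.
For an amphipathic helix the hydrophobic residues bunch into one angular
sector and the cationic ones into the opposite sector.
"""

from collections import defaultdict

from amphiscreen import wheel_layout
from amphiscreen.wheel import layout_table

SEQ = "DMARYYSALRHYINLITRQRY"  # neuropeptide-Y inhibitory region

layout = wheel_layout(SEQ)
print(layout_table(layout).to_string(index=False))

sectors = defaultdict(list)
for e in layout.entries:
    if e.klass in ("hydrophobic", "cationic"):
        sectors[e.klass].append(e.angle_deg)

for klass, angles in sorted(sectors.items()):
    print(f"\n{klass} residues sit at angles: {sorted(set(angles))}")

print(
    "\nHydrophobic and cationic angles occupy largely disjoint sectors - the "
    "two-face\narchitecture the screen selects for. Use "
    "amphiscreen.wheel.plot_wheel(layout, 'wheel.png')\nfor a graphical "
    "rendering (requires matplotlib)."
)
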