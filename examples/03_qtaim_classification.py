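"""Annotate a bond-critical-point table and classify every interaction.

Re-derives the local kinetic energy density G = (1/4 lap - V)/2, the local
energy density H = V + G, the empirical interaction energy
E = (-172.5 V + 0.33) kcal/mol (reported in kJ/mol), and the
Hayashi/Jeffrey classifications from the tabulated (rho, lap, V) of the
portal hydrogen bonds in the CB[7] complex series.
"""

from hostguest import annotate_table, interaction_inventory
from hostguest.refdata import bcp_hbond_table

annotated = annotate_table(bcp_hbond_table())
cols = ["complex_id", "conformer", "bond", "d", "H", "E", "GC", "EC", "HC", "itype"]
print(annotated[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print("interaction inventory:")
print(interaction_inventory(annotated).to_string(index=False))
# Every portal N-H...O contact is an ionic hydrogen bond; all but one are
# pure closed-shell (pCS, H > 0: electrostatic). The short 1.88 A bond of
# the bromophenyl complex has H < 0 (rCS): incipient covalent character.
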