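"""Nanobubble detection and compartment-resolved condensed volumes.

Plants a 1.2 nm argon droplet in the bulk solvent and a small droplet in
the interlayer gap, recovers both by single-linkage clustering at 1.5 sigma,
and reports per-compartment probe volumes normalized by the bulk condensed
fraction — the dimensionless table used to compare where each gas species
condenses.
"""
import vesiclegas as vg
from vesiclegas.compartments import CompartmentModel

scenario = vg.Scenario(
    box=20.0, n_frames=1, n_gas=24, species="argon",
    bubbles=[vg.BubblePlan("bulk", 1.2, "argon"),
             vg.BubblePlan("gap", 0.45, "argon")],
    seed=5)
frames, truth = vg.generate(scenario)
frame = frames[0]

model = CompartmentModel.from_frame(frame)
clusters = vg.cluster_gas(frame, "argon")
print(f"{len(clusters)} clusters; sizes of the largest three: "
      f"{[len(c) for c in clusters[:3]]} "
      "(the 24 dispersed atoms stay single, below the droplet filter)")

bubbles, table = vg.condensed_volumes(frame, clusters, model, "argon",
                                      min_size=2)
for b in bubbles.bubbles:
    print(f"  droplet in {b.compartment:5s}: {len(b.member_indices):3d} atoms, "
          f"probe volume {b.volume_A3:8.1f} A^3")
for t in truth.bubbles:
    print(f"  planted in {t.compartment:5s}: {t.n_atoms:3d} atoms, "
          f"expected envelope {t.inflated_volume_A3:8.1f} A^3")

print("\nper-compartment condensed volumes (A^3) and bulk-normalized row:")
print(table.round(3).to_string())
print("here the bulk droplet dominates; a gas whose normalized gap entry "
      "grows far above 1 is condensing preferentially between the "
      "monolayers (the interlayer-bubble signature)")
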