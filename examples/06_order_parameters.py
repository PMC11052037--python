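"""Prochiral Pro-S / Pro-R order parameters per leaflet.

United-atom chains carry no hydrogens, so the two methylene H positions are
reconstructed from the carbon skeleton and distinguished by chirality.
A synthetic vesicle with all chains tilted 30 degrees from the radial
direction shows how the director convention matters: the radial (curvature
aware) director sees the planted order, while the laboratory z axis
averages it away over the sphere — which is why order parameters measured
on a vesicle in the lab frame look flattened.
"""
import numpy as np

import vesiclegas as vg

scenario = vg.Scenario(n_frames=2, n_gas=10, chain_tilt=30.0, seed=3)
frames, truth = vg.generate(scenario)

s_true = truth.order_S_true["proS"][0]
print(f"planted: tilt 30 deg -> S = P2(cos 30) x P2(cos 90) = {s_true:.4f} "
      "for every sp3 carbon\n")

for mode in ("radial", "lab_z"):
    for leaflet in ("outer", "inner"):
        prof = vg.order_profile(frames, leaflet, "sn1", director_mode=mode)
        print(f"{mode:7s} {leaflet:5s} Sn1  Pro-S: "
              + " ".join(f"{s:+.4f}" for s in prof.S_proS))
print("\ncarbons reported: C2..C{} (the carbonyl C1 and the terminal methyl "
      "have no reconstructable methylene pair)".format(
          scenario.vesicle.template.n_chain - 1))
print("radial-mode values match the planted order; lab-frame values sit "
      "near zero by spherical averaging")
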