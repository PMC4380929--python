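"""Single-cell Fucci-style analysis: phases, events and dose response.

Generates two-channel tracks (15-min sampling, 60 h), derives quadrant
thresholds from an unstimulated reference, calls G1/S transition events
with the 4+4 run rule, and recovers the responder-fraction EC50 from the
pooled 42-54 h snapshot window across an HGF dose sweep.
"""

import numpy as np

import hepg1s as h

# reference condition: quiescent cells define the thresholds
ref = h.generate_tracks(
    h.TrackGeneratorSpec(n_cells=60, dose=0.0,
                         responder_hill=h.HillSpec(amp=0.0), seed=7)
)
thr = h.derive_thresholds(ref)
print(f"thresholds from unstimulated reference: RFP >= {thr.rfp:.1f}, "
      f"YFP >= {thr.yfp:.1f}  ({thr.derivation})")

for dose in (4.0, 100.0):
    tracks = h.generate_tracks(h.TrackGeneratorSpec(n_cells=20, dose=dose, seed=int(dose)))
    curve = h.cumulative_transition_curve(tracks, thr)
    n = curve["cells_transitioned"].iloc[-1]
    fr = h.snapshot_fractions(tracks, thr)
    print(f"\nHGF {dose:g} ng/ml, 20 tracked cells:")
    print(f"  cells with >= 1 G1/S transition: {n}/20")
    print(f"  42-54 h snapshot: "
          + ", ".join(f"{p} {v:.1f}%" for p, v in fr.items()))

# dose sweep: S/G2/M snapshot fraction vs dose -> cycling-fraction EC50
doses = np.unique(np.round(np.geomspace(0.5, 250, 12), 2))
fracs = []
for i, d in enumerate(doses):
    tracks = h.generate_tracks(
        h.TrackGeneratorSpec(n_cells=100, dose=float(d), seed=100 + i)
    )
    fracs.append(h.snapshot_fractions(tracks, thr)["S/G2/M"])
fit = h.fit_hill4(doses, np.array(fracs))
print(f"\ncycling-fraction dose response: EC50 {fit.k:.1f} ng/ml "
      f"(generator truth 16), Hill slope {fit.n:.2f}")
print("(an increase in HGF recruits more responding cells rather than "
      "accelerating entry)")
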