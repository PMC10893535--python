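"""Design the fluorometric verification probe set and classify simulated
cleavage curves.

Starting from consensus UACAUA with weakly conserved positions 1, 4 and 6,
the design emits the consensus probe plus every single-base substitution at
each weak position: ten chimeric probes (RNA insert between two 5-dA arms,
5' 6-FAM, 3' BHQ-1).  Only the cognate insert is cleaved in the simulated
assay, so only its fluorescence rises above the no-enzyme control.
"""

import numpy as np

import cleavemap as cm
from cleavemap.motifcall import Motif

motif = Motif(
    consensus="UACAUA",
    core_span=(-1, 4),
    info_content=np.full(11, 2.0),
    low_consistency_positions=(1, 4, 6),
    cut_before=2,
)
probes = cm.design_probes(motif)
print(f"{len(probes)} probes designed:")
for p in probes:
    print(f"  {p.name:<11} {p.full_sequence}  [{p.label_5p} ... {p.label_3p}]")

# triplicate curves: cognate probe cleaved at k = 0.2 / min, others inert
curves, controls = [], []
for i, p in enumerate(probes):
    k = 0.2 if p.insert == "UACAUA" else 0.0
    for rep in (1, 2, 3):
        curves.append(cm.simulate_fret(p, k, noise_sd=0.18, seed=10 * i + rep, replicate=rep))
        controls.append(cm.simulate_fret(p, 0.0, noise_sd=0.18, seed=1000 + 10 * i + rep, replicate=rep))

print("\nverdicts (fold change vs no-enzyme control; k fit per minute):")
for v in cm.classify_curves(curves, controls):
    k = f"{v.k_estimate:.3f}" if v.k_estimate is not None else "NA"
    print(f"  {v.probe_name:<11} {'cleaved' if v.cleaved else 'not_cleaved':<12} fold={v.fold_change:8.3g}  k={k}")
print("\nOnly the consensus probe shows a fluorescence increase: the enzyme")
print("requires the full UACAUA sequence.")
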