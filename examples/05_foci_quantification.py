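"""Quantify marker-chromocenter colocalization in synthetic nuclei.

Renders two-channel nuclear scenes — DAPI with bright chromocenters, a
marker channel with foci — at a high and a low colocalization fraction,
runs the full quantification chain (max projection, Otsu nuclei, top-hat
speckle enhancement, robust-background foci, parent-child relation), and
compares the per-nucleus colocalized counts between the two conditions.
"""

import numpy as np

from majorsat import foci, synthdata
from majorsat.synthdata import ImageSceneSpec

counts = {}
for label, p_coloc in (("high", 0.9), ("low", 0.2)):
    per_nucleus = []
    for i in range(4):  # 4 scenes x 5 nuclei per condition
        spec = ImageSceneSpec(p_coloc=p_coloc, rng_seed=400 + i, snr=10.0)
        dapi, marker, truth = synthdata.gen_nuclear_images(spec)
        result = foci.analyze_scene(dapi, marker)
        per_nucleus.extend(result["per_nucleus"]["n_colocalized"])
        if i == 0:
            n = result["per_nucleus"]
            print(f"{label} colocalization, scene 0: "
                  f"{len(result['nuclei'])} nuclei, per-nucleus colocalized "
                  f"counts {list(n['n_colocalized'])}")
    counts[label] = np.array(per_nucleus)

comparison = foci.compare_groups(counts["high"], counts["low"],
                                 labels=("high", "low"))
print("\n" + str(comparison))
print("\nThe Mann-Whitney test separates the two colocalization regimes; "
      "medians and IQRs summarise the per-nucleus count distributions.")
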