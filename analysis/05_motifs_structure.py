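"""Promoter -10/-35 motifs with spacer lengths, the conserved 3'-end motif,
folding free energies, and the TEP subcategory split.

Re-runs the motif/structure stage via the pipeline on results/dataset and
reports what the discovered elements look like.
"""

from collections import Counter

import numpy as np
import pandas as pd

from strep_regulome.pipeline import RunConfig, run_all

cfg = RunConfig(dataset_dir="results/dataset", outdir="results/pipeline", seed=11)
res = run_all(cfg)

print("promoter -10 consensus:", res.promoter["pwm10"].consensus,
      " -35 consensus:", res.promoter["pwm35"].consensus)
spacers = pd.Series(list(res.promoter["spacers"].values()))
print("spacer length mode:", int(spacers.mode()[0]),
      "distribution:", dict(spacers.value_counts().sort_index()))

print("3'-end motif consensus:", res.tep_pwm.consensus,
      f"({len(res.tep_pwm.sites)} of {len(res.tep_records)} TEP windows carry it)")
subs = Counter(r.subcategory for r in res.tep_records if r.subcategory)
print("TEP subcategories:", dict(subs))
dgs = np.array([r.dG for r in res.tep_records if r.dG is not None])
print(f"fold energy of -40..+1 windows: median {np.median(dgs):.1f} kcal/mol; "
      f"{np.mean(dgs < -25) * 100:.0f}% below the -25 kcal/mol split")
imat = res.interaction
iu = np.triu_indices_from(imat, k=3)
hot = np.argsort(imat[iu])[::-1][:3]
print("strongest base-pair interaction frequencies (offsets in the -100..0 "
      "window):", [(int(iu[0][h] - 100), int(iu[1][h] - 100),
                    round(float(imat[iu][h]), 2)) for h in hot])
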