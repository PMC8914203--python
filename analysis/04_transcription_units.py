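"""Assemble transcription units from the boundary calls, cluster them into
TUCs, label terminal vs non-terminal TEPs, and summarize read-through and
premature-termination intensity.

Reads the pipeline outputs written by 03_call_boundaries.py.
"""

import json
from collections import Counter

import numpy as np
import pandas as pd

manifest = json.loads(open("results/pipeline/manifest.json").read())
print("TU stage record counts:", manifest["stages"]["tu"])

tu_lines = [l.split("\t") for l in open("results/pipeline/tu.gff3")
            if not l.startswith("#")]
cats = Counter(dict(kv.split("=") for kv in f[8].strip().split(";"))["category"]
               for f in tu_lines)
print("TU categories:", dict(cats))

tuc = pd.read_csv("results/pipeline/tuc.tsv", sep="\t",
                  dtype={"terminal_teps": str, "nonterminal_teps": str})
n_terminal = tuc["terminal_teps"].fillna("").str.split(",").map(
    lambda v: sum(1 for x in v if x)).sum()
n_nonterm = tuc["nonterminal_teps"].fillna("").str.split(",").map(
    lambda v: sum(1 for x in v if x)).sum()
print(f"{len(tuc)} TUCs; {n_terminal} terminal and {n_nonterm} non-terminal TEPs")

rt = pd.read_csv("results/pipeline/readthrough.tsv", sep="\t")
rt = rt[np.isfinite(rt["readthrough"])]
print(f"read-through fraction over {len(rt)} TEPs: median "
      f"{rt['readthrough'].median():.3f} "
      f"(IQR {rt['readthrough'].quantile(0.25):.3f}"
      f"-{rt['readthrough'].quantile(0.75):.3f})")
rt.to_csv("results/readthrough_summary.tsv", sep="\t", index=False)
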