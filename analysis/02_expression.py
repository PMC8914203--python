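"""Differential expression across the E->T and T->S transitions, nine-group
classification, and translation efficiency, from the gene-level count table.

Reads results/dataset/counts.tsv; writes deg_table.tsv and prints the group
composition and TE summary.
"""

import pandas as pd

from strep_regulome.expression import expression_table

counts = pd.read_csv("results/dataset/counts.tsv", sep="\t")
table = expression_table(counts)
table.reset_index(names="gene").to_csv("results/deg_table.tsv", sep="\t", index=False)

n = len(table)
deg = table[table["group"] != "IX"]
print(f"{n} genes; {len(deg)} DEGs ({100 * len(deg) / n:.1f}%)")
print("group sizes:\n", table["group"].value_counts().sort_index().to_string())
buffered = table[table["te_lfc_et"] < -1]
print(f"{len(buffered)} genes show ET translational buffering "
      f"(log2 TE_FC < -1); median log2 TE_FC "
      f"{buffered['te_lfc_et'].median():.2f}")
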