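"""Ribosome pausing: per-codon A-site scores across growth phases, and the
codon usage / downstream structure of the top-scoring sites.

Re-runs the pausing stage via the pipeline on results/dataset.
"""

from strep_regulome.pipeline import RunConfig, run_all

cfg = RunConfig(dataset_dir="results/dataset", outdir="results/pipeline", seed=11)
res = run_all(cfg)

for phase in "ETS":
    stats = res.codon_stats[phase].dropna(subset=["mean_score"])
    top = stats.sort_values("mean_score", ascending=False).head(3)
    print(f"{phase} phase: top A-site codons "
          + ", ".join(f"{c} ({row.mean_score:.1f}, n={int(row.n)})"
                      for c, row in top.iterrows()))

ts = res.top_sites["T"]
print(f"top-{ts['n']} pausing sites (T phase): downstream +40 nt "
      f"dG {ts['top_dg_mean']:.1f} kcal/mol vs controls "
      f"{[round(v, 1) for v in ts['control_dg_means']]} "
      f"(rank-sum p {['%.1e' % p for p in ts['ranksum_p']]})")
print(f"GC of the same windows: {100 * ts['top_gc_mean']:.1f}% vs "
      f"{[round(100 * v, 1) for v in ts['control_gc_means']]}% (controls)")
rel = ts["rel_freq"].sort_values(ascending=False)
print("codons most enriched among top sites:",
      {c: round(v, 3) for c, v in rel.head(3).items()})
print(f"codon-frequency chi-square p = {ts['chi2_p']:.2e}")
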