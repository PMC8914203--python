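"""Call TSSs from the dRNA-seq TAP+/- tracks and TEPs from Term-seq, then
compare both call sets with the planted truth.

Runs the full pipeline in dataset mode (results/dataset) so the boundary
calls use exactly the thresholds of the published workflow: 1.5x TAP ratio,
100-bp clustering, 10/25-bp sub-cluster SD, count >= 4, Z > 6, 5-NN.
"""

from collections import Counter

from strep_regulome.pipeline import RunConfig, run_all
from strep_regulome.simulate import TruthSet

cfg = RunConfig(dataset_dir="results/dataset", outdir="results/pipeline", seed=11)
res = run_all(cfg)
truth = TruthSet.from_json("results/dataset/truth.json")


def near(calls, pos, strand, tol=2):
    return any(abs(p - pos) <= tol and s == strand for p, s in calls)


tss_calls = {(r.position, r.strand) for r in res.tss_records}
planted = {(t.position, t.strand) for t in truth.tss_list}
decoys = {(d.position, d.strand) for d in truth.decoy_list}
recall = sum(near(tss_calls, p, s) for p, s in planted) / len(planted)
dec = sum(near(tss_calls, p, s) for p, s in decoys) / len(decoys)
print(f"TSS: {len(tss_calls)} called; recall {recall:.3f} vs {len(planted)} "
      f"planted; decoy acceptance {dec:.3f}")
print("TSS categories:", dict(Counter(r.category for r in res.tss_records)))
print("leader classes:", dict(Counter(r.leader_class for r in res.tss_records
                                      if r.category == 'primary')))

tep_calls = {(r.position, r.strand) for r in res.tep_records}
planted_tep = {(t.position, t.strand) for t in truth.tep_list}
prec = sum(near(planted_tep, p, s) for p, s in tep_calls) / len(tep_calls)
rec = sum(near(tep_calls, p, s) for p, s in planted_tep) / len(planted_tep)
print(f"TEP: {len(tep_calls)} called; precision {prec:.3f}, recall {rec:.3f}")
print("TEP categories:", dict(Counter(r.category for r in res.tep_records)))
print("outputs -> results/pipeline/tss.gff3, tep.gff3")
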