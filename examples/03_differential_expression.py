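"""Two-group NB differential expression with |log2FC| >= 1 and p < 0.05.

Simulates mRNA counts with known fold changes, runs the NB Wald test
(median-of-ratios size factors, moment dispersion, t reference) and
compares calls against the planted truth.
"""
from cernet import generate_reference, plant_regulation, simulate_counts
from cernet.expression import de_summary, de_test

ref = generate_reference(seed=1)
truth = plant_regulation(ref, n_triples=8, seed=2)
_, _, cm_mrna = simulate_counts(truth, ref, seed=3)

res = de_test(cm_mrna)
print(res.head(6).round(3).to_string())
summary = de_summary(res)
print(f"\ncalled: {summary['n_up']} up, {summary['n_down']} down "
      f"of {len(res)} genes")

truly_de = {f for f in truth.true_de if f.startswith("gene")}
called_de = set(res.index[res["regulated"] != "ns"])
tp = len(truly_de & called_de)
print(f"planted DE genes recovered: {tp}/{len(truly_de)}; "
      f"false calls: {len(called_de - truly_de)}")
print("log2fc is group G over group C; 'up' means higher in the grazing-like"
      "\ngroup at the inclusive fold-change and strict p-value thresholds.")
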