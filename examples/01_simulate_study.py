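"""Simulate a two-group muscle transcriptome study with planted ceRNA structure.

Builds a toy genome with gene models, mature miRNAs and circRNAs, plants
eight circRNA-miRNA-mRNA sponge triples (binding sites embedded in the
sequence, opposing fold changes, correlated counts), and prints what was
planted.  Everything downstream of this generator is scoreable against the
returned ground truth.
"""
from cernet import generate_reference, plant_regulation, simulate_counts

ref = generate_reference(n_genes=30, n_mirnas=15, n_circ=12, seed=1)
truth = plant_regulation(ref, n_triples=8, seed=2)
cm_circ, cm_mir, cm_mrna = simulate_counts(truth, ref, seed=3)

print(f"genome: {len(ref.genome.chroms)} chromosomes, "
      f"{sum(len(s) for s in ref.genome.chroms.values())} bp")
print(f"{len(ref.genes)} genes, {len(ref.mirnas)} miRNAs, "
      f"{len(ref.circs)} circRNAs ({len(truth.triples)} planted triples)")
print(f"count matrices: circ {cm_circ.counts.shape}, "
      f"miRNA {cm_mir.counts.shape}, mRNA {cm_mrna.counts.shape}")
print("\nplanted triples (circRNA, miRNA, mRNA) and true log2FC (G vs C):")
for c, m, g in truth.triples:
    print(f"  {c} ({truth.true_log2fc[c]:+.0f})  {m} "
          f"({truth.true_log2fc[m]:+.0f})  {g} ({truth.true_log2fc[g]:+.0f})")
print("\nEach triple's circRNA and mRNA move together between groups while")
print("the shared miRNA moves opposite - the sponge signature the network")
print("stage is designed to detect.")
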