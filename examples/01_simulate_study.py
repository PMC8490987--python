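"""Generate a synthetic compartmentalized 2x2 study and inspect its truth.

The generator plants compartment-enrichment and treatment effects, coupled
protein effects, miRNA-family site enrichment in process-downregulated
genes, a consensus motif in their 3'UTRs, and a GO term — everything the
downstream stages are asked to recover.
"""

import compscale as cs

cfg = cs.SynthConfig(n_genes=1000, seed=1)
ann, truth, counts, design, intensities, pdesign = cs.simulate_study(cfg)

print(f"genes: {len(counts)}, RNA samples: {counts.shape[1]}, "
      f"proteins detected: {intensities.shape[0]}")
print(f"missing intensity cells: {intensities.isna().to_numpy().mean():.2%}")
print(truth.effects["treatment_label"].value_counts().to_string())
print("planted active miRNA family:", truth.active_families)
print("planted motif consensus:", truth.planted_consensus,
      f"({len(truth.motif_positive_genes)} motif-positive genes)")

manifest = cs.write_fixture("scratch/example_fixture", ann, truth, counts,
                            design, intensities, pdesign)
print("fixture files:", ", ".join(manifest["files"]))
# Each label group above is a recovery target: e.g. 'down_processes' genes
# carry a -1.5 log2 treatment effect in the process compartment only.
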