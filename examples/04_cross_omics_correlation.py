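"""Correlate RNA and protein log2 fold changes of the treatment response.

With a planted RNA/protein effect correlation of 0.8 the Spearman rho of
jointly significant features should land near that value.
"""

import compscale as cs

cfg = cs.SynthConfig(n_genes=1000, seed=1, n_replicates_rna=4,
                     rna_protein_effect_correlation=0.8)
ann, truth, counts, design, intensities, pdesign = cs.simulate_study(cfg)

rna, _, _ = cs.run_de(counts, design)
_, prot = cs.run_protein_de(intensities, pdesign, seed=1)

pairs = cs.pair_changes(rna["ptx_in_processes"], prot["ptx_in_processes"])
sig = pairs[pairs["sig_rna"] & pairs["sig_prot"]]
rho, p = cs.spearman(sig["logFC_rna"], sig["logFC_prot"])
r, _ = cs.pearson(sig["logFC_rna"], sig["logFC_prot"])
print(f"{len(pairs)} shared features, {len(sig)} significant in both")
print(f"Spearman rho = {rho:.3f} (p = {p:.2e}), Pearson r = {r:.3f}")
# rho ~ 0.8 reflects the planted coupling between the two omics layers.
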