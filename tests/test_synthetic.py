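"""The generator's planted structure must be recoverable by direct counting."""

import numpy as np
import pandas as pd
import pytest

import compscale as cs
from compscale.io import read_counts, read_table, read_truth, read_utr_fasta
from compscale.simulate import make_utr_sequences


def _site_rate(annotations, truth, label):
    genes = set(truth.genes_with_label(label)) if label != "null" else \
        set(truth.effects.index[truth.effects["treatment_label"] == "null"])
    fam = truth.active_families[0]
    sites = annotations.sites
    sub = sites[(sites["family"] == fam) & (sites["gene"].isin(genes))]
    return sub["site_count"].sum() / len(genes)


def test_determinism_under_fixed_seed(small_config):
    a1, t1 = cs.generate_universe(small_config)
    a2, t2 = cs.generate_universe(small_config)
    pd.testing.assert_frame_equal(t1.effects, t2.effects)
    pd.testing.assert_frame_equal(a1.sites, a2.sites)
    pd.testing.assert_frame_equal(a1.go_annotations, a2.go_annotations)
    c1, _ = cs.simulate_rna_counts(a1, t1, small_config)
    c2, _ = cs.simulate_rna_counts(a2, t2, small_config)
    pd.testing.assert_frame_equal(c1, c2)


def test_invalid_fraction_group_rejected():
    with pytest.raises(cs.ConfigError):
        cs.SynthConfig(frac_ptx_down_processes=0.5, frac_ptx_down_somata=0.3,
                       frac_ptx_up_processes=0.2,
                       frac_ptx_up_somata=0.2).validate()


def test_no_site_enrichment_when_multiplier_is_one():
    cfg = cs.SynthConfig(n_genes=5000, seed=2, active_site_enrichment=1.0,
                         frac_ptx_down_processes=0.1)
    ann, truth = cs.generate_universe(cfg)
    r_down = _site_rate(ann, truth, "down_processes")
    r_null = _site_rate(ann, truth, "null")
    # binomial/Poisson sampling error on ~500-gene set at rate 0.3
    se = np.sqrt(cfg.site_rate / 500 + cfg.site_rate / 3000)
    assert abs(r_down - r_null) < 4 * se


def test_site_enrichment_ratio_recovers_multiplier():
    cfg = cs.SynthConfig(n_genes=5000, seed=3, active_site_enrichment=4.0,
                         frac_ptx_down_processes=0.1)
    ann, truth = cs.generate_universe(cfg)
    ratio = _site_rate(ann, truth, "down_processes") / _site_rate(ann, truth, "null")
    assert 0.8 * 4.0 <= ratio <= 1.2 * 4.0


def test_site_enrichment_monotone_in_multiplier():
    ratios = []
    for mult in (1.0, 2.0, 4.0):
        cfg = cs.SynthConfig(n_genes=4000, seed=4, active_site_enrichment=mult,
                             frac_ptx_down_processes=0.1)
        ann, truth = cs.generate_universe(cfg)
        ratios.append(_site_rate(ann, truth, "down_processes")
                      / _site_rate(ann, truth, "null"))
    assert ratios[0] < ratios[1] < ratios[2]


def test_poisson_limit_variance_equals_mean():
    cfg = cs.SynthConfig(n_genes=2000, seed=5, dispersion=0.0,
                         frac_compartment_enriched=0,
                         frac_ptx_down_processes=0, frac_ptx_down_somata=0,
                         frac_ptx_up_processes=0, frac_ptx_up_somata=0,
                         lib_size_range=(2_000_000, 2_000_000))
    ann, truth = cs.generate_universe(cfg)
    counts, design = cs.simulate_rna_counts(ann, truth, cfg)
    y = counts.to_numpy(float)
    mean = y.mean(axis=1)
    var = y.var(axis=1, ddof=1)
    # index of dispersion ~ 1 on average in the Poisson limit
    ratio = var[mean > 20] / mean[mean > 20]
    assert abs(ratio.mean() - 1.0) < 3 * ratio.std() / np.sqrt(ratio.size)


def test_nb_mean_variance_relation():
    phi = 0.1
    cfg = cs.SynthConfig(n_genes=2000, seed=6, dispersion=phi,
                         n_replicates_rna=25,
                         frac_compartment_enriched=0,
                         frac_ptx_down_processes=0, frac_ptx_down_somata=0,
                         frac_ptx_up_processes=0, frac_ptx_up_somata=0,
                         lib_size_range=(2_000_000, 2_000_000))
    ann, truth = cs.generate_universe(cfg)
    counts, design = cs.simulate_rna_counts(ann, truth, cfg)
    som = design.loc[(design.compartment == "somata")
                     & (design.treatment == "mock"), "sample"]
    y = counts[som.tolist()].to_numpy(float)
    mean = y.mean(axis=1)
    var = y.var(axis=1, ddof=1)
    keep = mean > 50
    excess = (var[keep] - mean[keep]) / mean[keep] ** 2  # estimates phi
    se = excess.std() / np.sqrt(excess.size)
    assert abs(excess.mean() - phi) < 3 * se


def test_planted_treatment_logfc_recovered_at_high_replication():
    cfg = cs.SynthConfig(n_genes=1500, seed=7, n_replicates_rna=50,
                         treatment_logfc=1.0)
    ann, truth = cs.generate_universe(cfg)
    counts, design = cs.simulate_rna_counts(ann, truth, cfg)
    cpm = counts / counts.sum(axis=0) * 1e6
    proc = design[design.compartment == "processes"]
    ptx = cpm[proc.loc[proc.treatment == "ptx", "sample"].tolist()].mean(axis=1)
    mock = cpm[proc.loc[proc.treatment == "mock", "sample"].tolist()].mean(axis=1)
    down = truth.genes_with_label("down_processes")
    observed = np.log2(ptx.loc[down] / mock.loc[down]).mean()
    assert abs(observed - (-1.0)) < 0.1


def test_null_design_has_equal_group_means():
    cfg = cs.SynthConfig(n_genes=800, seed=8, n_replicates_rna=10,
                         frac_compartment_enriched=0,
                         frac_ptx_down_processes=0, frac_ptx_down_somata=0,
                         frac_ptx_up_processes=0, frac_ptx_up_somata=0)
    ann, truth = cs.generate_universe(cfg)
    counts, design = cs.simulate_rna_counts(ann, truth, cfg)
    cpm = counts / counts.sum(axis=0) * 1e6
    means = {}
    for comp in ("somata", "processes"):
        for trt in ("mock", "ptx"):
            cols = design.loc[(design.compartment == comp)
                              & (design.treatment == trt), "sample"]
            means[(comp, trt)] = cpm[cols.tolist()].to_numpy().mean()
    vals = np.array(list(means.values()))
    assert vals.std() / vals.mean() < 0.01


def test_mnar_missingness_properties(small_config):
    cfg_none = cs.SynthConfig(**{**small_config.to_dict(),
                                 "missing_intensity_scale": 0.0})
    ann, truth = cs.generate_universe(cfg_none)
    intens, _ = cs.simulate_protein_intensities(ann, truth, cfg_none)
    assert not intens.isna().any().any()

    cfg_mnar = cs.SynthConfig(**{**small_config.to_dict(),
                                 "missing_intensity_scale": 0.4})
    ann, truth = cs.generate_universe(cfg_mnar)
    intens, _ = cs.simulate_protein_intensities(ann, truth, cfg_mnar)
    mask = truth.protein_missing_mask.to_numpy()
    complete = np.log2(truth.protein_complete.to_numpy())
    assert mask.sum() > 50
    assert complete[mask].mean() < complete[~mask].mean()


def test_perfect_correlation_copies_rna_effects():
    cfg = cs.SynthConfig(n_genes=300, seed=9, rna_protein_effect_correlation=1.0)
    ann, truth = cs.generate_universe(cfg)
    eff = truth.effects
    np.testing.assert_array_equal(eff["prot_logfc_somata"],
                                  eff["trt_logfc_somata"])
    np.testing.assert_array_equal(eff["prot_logfc_processes"],
                                  eff["trt_logfc_processes"])


def test_fixture_round_trip(fixture_dir, small_study, small_config):
    ann, truth, counts, design, intens, pdesign = small_study
    counts_rt = read_counts(fixture_dir / "counts.tsv")
    pd.testing.assert_frame_equal(counts_rt, counts, check_names=False)
    intens_rt = read_counts(fixture_dir / "intensities.tsv")
    pd.testing.assert_frame_equal(intens_rt, intens, check_names=False)
    sites_rt = read_table(fixture_dir / "mbs_sites.tsv")
    pd.testing.assert_frame_equal(sites_rt, ann.sites)
    motifs_rt = cs.read_meme(fixture_dir / "motifs.meme")
    assert [m.motif_id for m in motifs_rt] == [m.motif_id for m in ann.motifs]
    for a, b in zip(motifs_rt, ann.motifs):
        np.testing.assert_array_equal(a.matrix, b.matrix)

    seqs = read_utr_fasta(fixture_dir / "utr.fasta")
    truth_json = read_truth(fixture_dir / "truth.json")
    lengths = dict(zip(truth_json["effects"]["gene"],
                       truth_json["effects"]["utr_length"]))
    assert all(len(seq) == lengths[g] for g, seq in seqs.items())

    consensus = truth_json["planted_consensus"]
    for gene in truth_json["motif_positive_genes"]:
        assert consensus in seqs[gene]  # substring-search oracle
    # non-positive genes carry the 7-mer only at the chance rate
    # (~ length * prod of base probabilities, well under 20% of sequences)
    other = [g for g in seqs if g not in set(truth_json["motif_positive_genes"])]
    hits = sum(consensus in seqs[g] for g in other)
    assert hits < 0.2 * len(other)


def test_sequences_deterministic(small_config, small_study):
    ann, truth = small_study[0], small_study[1]
    s1 = make_utr_sequences(ann, truth, small_config)
    s2 = make_utr_sequences(ann, truth, small_config)
    assert s1 == s2
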