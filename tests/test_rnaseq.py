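"""RNA differential-expression stage: filtering, TMM, NB GLM, LRT, BH, sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import compscale as cs
from compscale.rnaseq import (
    CONTRASTS,
    bh_adjust,
    build_design_matrix,
    classify_sets,
    filter_expressed,
    fit_nb_glm,
    lrt_contrast,
    tmm_factors,
)
from compscale.simulate import _design_table


# ---------------------------------------------------------------------------
# filtering

def _counts(rows, design):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=design["sample"].tolist())


def test_filter_rule_is_strictly_greater(rna_design):
    counts = _counts([[21, 21, 0, 0, 0, 0, 0, 0],
                      [20, 20, 20, 20, 20, 20, 20, 20],
                      [100] * 8], rna_design)
    kept = filter_expressed(counts, min_count=20, min_samples=2)
    assert list(kept.index) == ["g0", "g2"]


def test_filter_empty_and_errors(rna_design):
    empty = _counts([], rna_design)
    assert filter_expressed(empty).empty
    counts = _counts([[30] * 8], rna_design)
    with pytest.raises(ValueError):
        filter_expressed(counts, min_samples=9)


def test_filter_per_compartment_scope(rna_design):
    # expressed only in the two somata_mock/ptx pairs
    counts = _counts([[50, 50, 50, 50, 0, 0, 0, 0]], rna_design)
    som = filter_expressed(counts, scope="per_compartment", design=rna_design,
                           compartment="somata")
    proc = filter_expressed(counts, scope="per_compartment", design=rna_design,
                            compartment="processes")
    assert len(som) == 1 and len(proc) == 0


def test_filter_idempotent_and_row_order_independent(null_counts):
    once = filter_expressed(null_counts)
    twice = filter_expressed(once)
    pd.testing.assert_frame_equal(once, twice)
    shuffled = null_counts.sample(frac=1, random_state=0)
    again = filter_expressed(shuffled).sort_index()
    pd.testing.assert_frame_equal(once.sort_index(), again)


# ---------------------------------------------------------------------------
# TMM

def test_tmm_identical_and_scaled_columns():
    rng = np.random.default_rng(0)
    col = rng.integers(10, 1000, size=50)
    counts = pd.DataFrame({"a": col, "b": col})
    np.testing.assert_allclose(tmm_factors(counts).to_numpy(), [1.0, 1.0],
                               atol=1e-12)
    counts3 = pd.DataFrame({"a": col, "b": 3 * col})
    np.testing.assert_allclose(tmm_factors(counts3).to_numpy(), [1.0, 1.0],
                               atol=1e-12)


def _tmm_oracle(counts, trim_m=0.30, trim_a=0.05):
    """Independent direct computation of the doubly-trimmed weighted mean."""
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    f75 = np.quantile(y / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        rows = [(np.log2((y[g, j] / lib[j]) / (y[g, ref] / lib[ref])),
                 0.5 * np.log2((y[g, j] / lib[j]) * (y[g, ref] / lib[ref])),
                 (lib[j] - y[g, j]) / (lib[j] * y[g, j])
                 + (lib[ref] - y[g, ref]) / (lib[ref] * y[g, ref]))
                for g in range(y.shape[0]) if y[g, j] > 0 and y[g, ref] > 0]
        m = np.array([r[0] for r in rows])
        a = np.array([r[1] for r in rows])
        w = np.array([r[2] for r in rows])
        n = len(rows)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = ((rm >= np.floor(n * trim_m) + 1) & (rm <= n - np.floor(n * trim_m))
                & (ra >= np.floor(n * trim_a) + 1) & (ra <= n - np.floor(n * trim_a)))
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    y = rng.integers(5, 2000, size=(100, 4))
    y[:5, 1] *= 20  # composition outliers in one sample
    counts = pd.DataFrame(y, columns=list("abcd"))
    np.testing.assert_allclose(tmm_factors(counts).to_numpy(),
                               _tmm_oracle(counts), atol=1e-10)


def test_tmm_geometric_mean_one_and_depth_invariance():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(1, 500, size=(80, 5)))
    f = tmm_factors(counts)
    assert abs(np.exp(np.mean(np.log(f))) - 1) < 1e-12
    # rescaling a sample's depth leaves M/A values unchanged; only the
    # inverse-variance weights shift, so factors move at most marginally
    scaled = counts.copy()
    scaled[2] = counts[2] * 7
    np.testing.assert_allclose(tmm_factors(scaled).to_numpy(), f.to_numpy(),
                               atol=0.05)


# ---------------------------------------------------------------------------
# dispersion

def test_dispersion_symmetry_identical_rows(rna_design):
    rng = np.random.default_rng(2)
    row = rng.integers(50, 300, size=8)
    counts = _counts([row, row, rng.integers(50, 300, size=8)], rna_design)
    est = cs.estimate_dispersion(counts, rna_design)
    assert est.per_gene.iloc[0] == est.per_gene.iloc[1]


def test_dispersion_rejects_zero_rows(rna_design):
    counts = _counts([[0] * 8, [10] * 8], rna_design)
    with pytest.raises(ValueError):
        cs.estimate_dispersion(counts, rna_design)


def test_dispersion_recovery():
    for true_phi, check in ((0.0, lambda c: c < 0.01),
                            (0.1, lambda c: 0.07 <= c <= 0.13)):
        cfg = cs.SynthConfig(n_genes=2000, seed=13, dispersion=true_phi,
                             frac_compartment_enriched=0,
                             frac_ptx_down_processes=0, frac_ptx_down_somata=0,
                             frac_ptx_up_processes=0, frac_ptx_up_somata=0)
        ann, truth = cs.generate_universe(cfg)
        counts, design = cs.simulate_rna_counts(ann, truth, cfg)
        est = cs.estimate_dispersion(counts, design)
        assert check(est.common), (true_phi, est.common)


# ---------------------------------------------------------------------------
# NB GLM and LRT

def test_saturated_fit_reproduces_group_means(rna_design):
    rng = np.random.default_rng(3)
    y = np.repeat(rng.integers(20, 400, size=(5, 4)), 2, axis=1)  # equal pairs
    counts = _counts(list(y), rna_design)
    # equalize library sizes with a balancing gene
    balance = counts.sum(axis=0).max() * 2 - counts.sum(axis=0)
    counts.loc["balance"] = balance.to_numpy()
    fit = fit_nb_glm(counts, rna_design, dispersion=0.0)
    X = build_design_matrix(rna_design).to_numpy()
    fitted = np.exp(fit.beta.to_numpy() @ X.T + fit.offset[None, :])
    np.testing.assert_allclose(fitted[:5], counts.to_numpy()[:5], rtol=1e-6)


def test_treatment_coefficient_closed_form(rna_design):
    # somata: mock mean 10, ptx mean 40 -> beta_ptx_somata = ln 4
    counts = _counts([[10, 10, 40, 40, 10, 10, 10, 10]], rna_design)
    counts.loc["balance"] = 1000 - counts.sum(axis=0).to_numpy()
    fit = fit_nb_glm(counts, rna_design, dispersion=0.0)
    assert abs(fit.beta.loc["g0", "ptx_somata"] - np.log(4.0)) < 1e-6


def test_glm_optimum_beats_perturbation_grid(rna_design):
    rng = np.random.default_rng(4)
    counts = _counts([rng.integers(5, 200, size=8) for _ in range(3)],
                     rna_design)
    phi = 0.1
    fit = fit_nb_glm(counts, rna_design, dispersion=phi)
    from compscale.rnaseq import _nb_loglik
    X = build_design_matrix(rna_design).to_numpy()
    y = counts.to_numpy(float)
    for g in range(3):
        best = fit.loglik[g]
        beta = fit.beta.to_numpy()[g]
        for d0 in np.linspace(-0.5, 0.5, 10):
            for d1 in np.linspace(-0.5, 0.5, 10):
                pert = beta + np.array([d0, d1, -d1, d0 / 2])
                mu = np.exp(pert @ X.T + fit.offset)[None, :]
                ll = _nb_loglik(y[g][None, :], mu, np.array([phi]))[0]
                assert ll <= best + 1e-8


def test_lrt_zero_effect_gives_zero_stat(rna_design):
    # identical counts across treatments within each compartment
    counts = _counts([[30, 30, 30, 30, 80, 80, 80, 80]], rna_design)
    counts.loc["balance"] = 500 - counts.sum(axis=0).to_numpy()
    fit = fit_nb_glm(counts, rna_design, dispersion=0.0)
    res = lrt_contrast(fit, "ptx_in_somata")
    assert res.loc[res.gene == "g0", "stat"].iloc[0] < 1e-6
    assert res.loc[res.gene == "g0", "p"].iloc[0] > 0.999


def test_lrt_unknown_contrast(rna_design, null_counts):
    fit = fit_nb_glm(null_counts, rna_design, dispersion=0.05)
    with pytest.raises(ValueError):
        lrt_contrast(fit, "nonsense")


def test_lrt_null_p_uniform(null_counts, rna_design):
    res, fit, disp = cs.run_de(null_counts, rna_design, min_count=0,
                               min_samples=1)
    p = res["ptx_in_processes"]["p"].to_numpy()
    assert stats.kstest(p, "uniform").pvalue > 0.01
    assert (res["ptx_in_processes"]["stat"] >= 0).all()


# ---------------------------------------------------------------------------
# BH adjustment

def test_bh_hand_examples():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 0.0])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


def test_bh_matches_statsmodels_oracle():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    p = rng.uniform(1e-6, 1, size=1000)
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0,
                          allow_nan=False), min_size=1, max_size=40))
def test_bh_bounds_and_monotonicity(pvals):
    p = np.asarray(pvals)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
    for alpha_lo, alpha_hi in ((0.01, 0.05), (0.05, 0.2)):
        assert (q < alpha_lo).sum() <= (q < alpha_hi).sum()


# ---------------------------------------------------------------------------
# set classification

def _de(genes, logfc, fdr, contrast="x"):
    return pd.DataFrame({"gene": genes, "logFC": logfc,
                         "logCPM": 5.0, "stat": 1.0, "p": fdr, "fdr": fdr,
                         "contrast": contrast})


def test_classify_rule_applications():
    genes = ["a", "b", "c"]
    som = _de(genes, [-0.8, 0.5, 1.0], [0.01, 0.5, 0.01])
    pro = _de(genes, [-1.2, -2.0, 2.0], [0.01, 0.04, 0.5])
    labels = classify_sets(som, pro).set_index("gene")["label"]
    assert labels["a"] == "common_down"      # both significant, both down
    assert labels["b"] == "processes_only_down"
    assert labels["c"] == "somata_only_up"


def test_classify_mismatched_universes():
    with pytest.raises(ValueError):
        classify_sets(_de(["a"], [1], [0.01]), _de(["b"], [1], [0.01]))


def test_classify_counts_match_brute_force(small_study):
    ann, truth, counts, design, *_ = small_study
    res, *_ = cs.run_de(counts, design)
    labels = classify_sets(res["ptx_in_somata"], res["ptx_in_processes"])
    som = res["ptx_in_somata"].set_index("gene")
    pro = res["ptx_in_processes"].set_index("gene")
    expected = {}
    for g in som.index:
        ss, sp = som.loc[g, "fdr"] < 0.05, pro.loc[g, "fdr"] < 0.05
        ds, dp = som.loc[g, "logFC"] < 0, pro.loc[g, "logFC"] < 0
        if ss and sp:
            lab = ("common_down" if ds and dp else
                   "common_up" if not ds and not dp else "discordant")
        elif ss:
            lab = "somata_only_down" if ds else "somata_only_up"
        elif sp:
            lab = "processes_only_down" if dp else "processes_only_up"
        else:
            lab = "ns"
        expected[lab] = expected.get(lab, 0) + 1
    observed = labels["label"].value_counts().to_dict()
    assert observed == expected


def test_compartment_enrichment_calls():
    de = _de(["a", "b", "c"], [1.5, 0.8, -1.5], [0.01, 0.01, 0.01],
             contrast="compartment_in_mock")
    labels = cs.classify_compartment(de).set_index("gene")["label"]
    assert labels["a"] == "process_enriched"
    assert labels["b"] == "ns"               # |logFC| <= 1
    assert labels["c"] == "somata_enriched"
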