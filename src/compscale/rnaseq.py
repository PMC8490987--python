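"""Negative-binomial differential expression for the 2x2 compartment study.

The stage mirrors a standard count-based workflow: expression filtering
(strictly more than ``min_count`` reads in at least ``min_samples`` samples),
TMM between-sample normalization, a per-gene NB GLM over
compartment * treatment with log library-size offsets, likelihood-ratio
contrasts for the treatment effect within each compartment (and the
compartment effect under mock), Benjamini-Hochberg adjustment, and the
classification of genes into exclusive/common regulated sets.

The design matrix uses treatment-within-compartment columns
(intercept, processes, ptx:somata, ptx:processes) — an equivalent
reparameterization of the intercept/compartment/treatment/interaction model
in which each named contrast is a single coefficient, so the reduced model
of every likelihood-ratio test is a plain column drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

LN2 = np.log(2.0)

CONTRASTS = {
    # contrast name -> (design column, samples forming the two compared groups)
    "ptx_in_somata": ("ptx_somata", ("somata", "treatment")),
    "ptx_in_processes": ("ptx_processes", ("processes", "treatment")),
    "compartment_in_mock": ("processes", ("mock", "compartment")),
}

DESIGN_COLUMNS = ["intercept", "processes", "ptx_somata", "ptx_processes"]


def build_design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Treatment-within-compartment design matrix for the 2x2 study."""
    comp = (design["compartment"].to_numpy() == "processes").astype(float)
    ptx = (design["treatment"].str.lower().isin(["ptx"])).to_numpy().astype(float)
    X = pd.DataFrame({
        "intercept": 1.0,
        "processes": comp,
        "ptx_somata": ptx * (1.0 - comp),
        "ptx_processes": ptx * comp,
    }, index=design["sample"].tolist())
    return X


def filter_expressed(
    counts: pd.DataFrame,
    min_count: int = 20,
    min_samples: int = 2,
    scope: str = "global",
    design: pd.DataFrame | None = None,
    compartment: str | None = None,
) -> pd.DataFrame:
    """Keep genes with count strictly greater than ``min_count`` in at least
    ``min_samples`` samples.

    With ``scope="per_compartment"`` the rule is applied within the named
    compartment's samples only, defining that compartment's background gene
    list for the enrichment analyses.
    """
    if counts.empty:
        return counts
    if scope == "global":
        sub = counts
    elif scope == "per_compartment":
        if design is None or compartment is None:
            raise ValueError("per_compartment scope needs design and compartment")
        samples = design.loc[design["compartment"] == compartment, "sample"]
        sub = counts[samples.tolist()]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if min_samples > sub.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds available samples ({sub.shape[1]})")
    keep = (sub > min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the column whose 75th CPM percentile is closest
    to the mean 75th percentile.  For every sample the factor is
    2^(weighted mean of M-values) after trimming ``trim_m`` of genes from
    each M tail and ``trim_a`` from each A tail, with inverse asymptotic
    binomial variances as weights; factors are rescaled to geometric mean 1.
    """
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    cpm_ = y / lib[None, :]
    f75 = np.quantile(cpm_, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))  # ties -> lowest index

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yk, nk = y[:, j], lib[j]
        pos = (yk > 0) & (yr > 0)
        if not pos.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed genes "
                "with the reference")
        m = np.log2((yk[pos] / nk) / (yr[pos] / nr))
        a = 0.5 * np.log2((yk[pos] / nk) * (yr[pos] / nr))
        w = (nk - yk[pos]) / (nk * yk[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        n = m.size
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n - int(np.floor(n * trim_m))
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n - int(np.floor(n * trim_a))
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
               (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and np.sum(1.0 / w[keep]) > 0:
            factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) /
                                 np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns).to_numpy()
    return counts / lib * 1e6


# ---------------------------------------------------------------------------
# NB GLM machinery (batched IRLS across genes)

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (Poisson limit for phi ~ 0); phi is (G,)."""
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(y.shape[0])
    tiny = phi < 1e-10
    if tiny.any():
        yt, mt = y[tiny], mu[tiny]
        out[tiny] = np.sum(yt * np.log(mt) - mt - gammaln(yt + 1.0), axis=1)
    big = ~tiny
    if big.any():
        yb, mb = y[big], mu[big]
        r = (1.0 / phi[big])[:, None]
        out[big] = np.sum(
            gammaln(yb + r) - gammaln(r) - gammaln(yb + 1.0)
            + r * np.log(r / (r + mb)) + yb * np.log(mb / (r + mb)), axis=1)
    return out


def _irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
    max_iter: int = 50, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for the NB log-link GLM with fixed dispersion.

    Returns (beta (G,P), mu (G,S), converged (G,)).
    """
    G, S = y.shape
    P = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    pinv = np.linalg.pinv(X)
    beta = (np.log(y + 0.5) - offset[None, :]) @ pinv.T
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(P) * 1e-10
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        XtWX = np.einsum("gs,sp,sq->gpq", W, X, X) + eye[None, :, :]
        XtWz = np.einsum("gs,sp,gs->gp", W, X, z)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged = delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    return beta, np.exp(eta), converged


def _cox_reid_apl(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    G = y.shape[0]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    beta, mu, _ = _irls(y, X, offset, phi, max_iter=30, tol=1e-6)
    ll = _nb_loglik(y, mu, phi)
    W = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("gs,sp,sq->gpq", W, X, X) + np.eye(X.shape[1])[None] * 1e-10
    sign, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet


@dataclass
class DispersionEstimate:
    common: float
    per_gene: pd.Series
    prior_df: float


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_df: float = 10.0,
    grid_points: int = 25,
) -> DispersionEstimate:
    """Common + shrunk gene-wise NB dispersions via Cox-Reid APL.

    The common dispersion maximizes the APL summed over genes
    (golden-section search on log10 phi in [-6, 1]).  Gene-wise values
    maximize the weighted objective APL_g(phi) + (prior_df / d_g) *
    mean-APL(phi) on a log-spaced grid, shrinking each gene toward the
    common curve with a prior weight equivalent to ``prior_df`` extra
    residual degrees of freedom.
    """
    y = counts.to_numpy(dtype=float)
    if np.any(y.sum(axis=1) == 0):
        raise ValueError("all-zero gene rows must be filtered before "
                         "dispersion estimation")
    X = build_design_matrix(design).to_numpy()
    lib = y.sum(axis=0)
    f = (factors.reindex(counts.columns).to_numpy()
         if factors is not None else np.ones(y.shape[1]))
    offset = np.log(lib * f)

    def total_apl(log10_phi: float) -> float:
        return float(_cox_reid_apl(y, X, offset, 10.0 ** log10_phi).sum())

    # golden-section maximization on log10 phi
    lo, hi = -6.0, 1.0
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc, fd = total_apl(c), total_apl(d)
    for _ in range(40):
        if fc > fd:
            hi, d, fd = d, c, fc
            c = hi - gr * (hi - lo)
            fc = total_apl(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + gr * (hi - lo)
            fd = total_apl(d)
        if hi - lo < 1e-4:
            break
    common = float(10.0 ** ((lo + hi) / 2.0))

    grid = np.logspace(-6, 1, grid_points)
    apl = np.stack([_cox_reid_apl(y, X, offset, g) for g in grid], axis=1)  # (G, K)
    d_resid = max(y.shape[1] - X.shape[1], 1)
    objective = apl + (prior_df / d_resid) * apl.mean(axis=0)[None, :]
    best = objective.argmax(axis=1)
    per_gene = grid[best]
    return DispersionEstimate(
        common=common,
        per_gene=pd.Series(per_gene, index=counts.index, name="dispersion"),
        prior_df=prior_df)


@dataclass
class NBFit:
    """Fitted per-gene NB GLMs plus everything needed to refit reduced models."""

    counts: pd.DataFrame
    design: pd.DataFrame
    X: pd.DataFrame
    offset: np.ndarray
    phi: np.ndarray
    beta: pd.DataFrame          # natural-log scale, DESIGN_COLUMNS
    mu: np.ndarray
    converged: np.ndarray
    loglik: np.ndarray
    factors: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


def fit_nb_glm(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    dispersion: float | pd.Series | np.ndarray = 0.0,
) -> NBFit:
    """Per-gene IRLS fit of the NB GLM with log(lib_size * factor) offsets."""
    X = build_design_matrix(design)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    y = counts[design["sample"].tolist()].to_numpy(dtype=float)
    lib = y.sum(axis=0)
    f = (factors.reindex(design["sample"]).to_numpy()
         if factors is not None else np.ones(y.shape[1]))
    offset = np.log(lib * f)
    if isinstance(dispersion, pd.Series):
        phi = dispersion.reindex(counts.index).to_numpy()
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float),
                              (y.shape[0],)).copy()
    beta, mu, converged = _irls(y, X.to_numpy(), offset, phi)
    ll = _nb_loglik(y, mu, phi)
    return NBFit(counts=counts, design=design, X=X, offset=offset, phi=phi,
                 beta=pd.DataFrame(beta, index=counts.index, columns=X.columns),
                 mu=mu, converged=converged, loglik=ll, factors=factors)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def _report_logfc(fit: NBFit, column: str, contrast: str) -> np.ndarray:
    """log2 fold change for reporting: the GLM coefficient, with a
    0.125-count prior fallback for genes with an all-zero group."""
    logfc = fit.beta[column].to_numpy() / LN2
    comp_or_trt, varying = CONTRASTS[contrast][1]
    design = fit.design
    if varying == "treatment":
        sub = design[design["compartment"] == comp_or_trt]
        g1 = sub.loc[sub["treatment"] == "ptx", "sample"].tolist()
        g0 = sub.loc[sub["treatment"] == "mock", "sample"].tolist()
    else:
        sub = design[design["treatment"] == comp_or_trt]
        g1 = sub.loc[sub["compartment"] == "processes", "sample"].tolist()
        g0 = sub.loc[sub["compartment"] == "somata", "sample"].tolist()
    y1 = fit.counts[g1].to_numpy(dtype=float)
    y0 = fit.counts[g0].to_numpy(dtype=float)
    zero_group = (y1.sum(axis=1) == 0) | (y0.sum(axis=1) == 0)
    if zero_group.any():
        norm = cpm(fit.counts, fit.factors)
        m1 = norm[g1].to_numpy().mean(axis=1) + 0.125
        m0 = norm[g0].to_numpy().mean(axis=1) + 0.125
        logfc = np.where(zero_group, np.log2(m1 / m0), logfc)
    return logfc


def lrt_contrast(fit: NBFit, contrast: str) -> pd.DataFrame:
    """Likelihood-ratio test for one named contrast.

    The reduced model drops the contrast's design column; the statistic is
    2 * (ll_full - ll_reduced) against chi-square with 1 df.  Reported logFC
    is log2 (the GLM is fit in natural log); logCPM is the mean log2 CPM
    after TMM.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; "
                         f"choose from {sorted(CONTRASTS)}")
    column = CONTRASTS[contrast][0]
    X = fit.X.to_numpy()
    keep = [i for i, c in enumerate(fit.X.columns) if c != column]
    y = fit.counts[fit.design["sample"].tolist()].to_numpy(dtype=float)
    _, mu_red, _ = _irls(y, X[:, keep], fit.offset, fit.phi)
    ll_red = _nb_loglik(y, mu_red, fit.phi)
    stat = np.maximum(2.0 * (fit.loglik - ll_red), 0.0)
    p = np.clip(stats.chi2.sf(stat, df=1), np.finfo(float).tiny, 1.0)
    norm = cpm(fit.counts, fit.factors)
    logcpm = np.log2(norm.mean(axis=1).to_numpy() + 0.5)
    out = pd.DataFrame({
        "gene": fit.genes,
        "logFC": _report_logfc(fit, column, contrast),
        "logCPM": logcpm,
        "stat": stat,
        "p": p,
        "fdr": bh_adjust(p),
    })
    out["contrast"] = contrast
    return out


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_count: int = 20,
    min_samples: int = 2,
    prior_df: float = 10.0,
    contrasts: tuple[str, ...] = tuple(CONTRASTS),
) -> tuple[dict[str, pd.DataFrame], NBFit, DispersionEstimate]:
    """Filter -> TMM -> dispersion -> GLM -> LRT for the named contrasts."""
    filtered = filter_expressed(counts, min_count=min_count,
                                min_samples=min_samples)
    factors = tmm_factors(filtered)
    disp = estimate_dispersion(filtered, design, factors, prior_df=prior_df)
    fit = fit_nb_glm(filtered, design, factors, disp.per_gene)
    results = {c: lrt_contrast(fit, c) for c in contrasts}
    return results, fit, disp


def classify_sets(
    somata: pd.DataFrame,
    processes: pd.DataFrame,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Partition genes by their treatment response across compartments.

    Labels: somata_only_down/up, processes_only_down/up, common_down/up,
    discordant (significant both, opposite signs), ns.
    """
    som = somata.set_index("gene")
    pro = processes.set_index("gene")
    if set(som.index) != set(pro.index):
        raise ValueError("contrasts computed on different gene universes")
    pro = pro.reindex(som.index)
    sig_s = som["fdr"].to_numpy() < q_thresh
    sig_p = pro["fdr"].to_numpy() < q_thresh
    down_s = som["logFC"].to_numpy() < 0
    down_p = pro["logFC"].to_numpy() < 0
    labels = np.where(
        sig_s & sig_p,
        np.where(down_s == down_p,
                 np.where(down_s, "common_down", "common_up"), "discordant"),
        np.where(sig_s, np.where(down_s, "somata_only_down", "somata_only_up"),
                 np.where(sig_p,
                          np.where(down_p, "processes_only_down",
                                   "processes_only_up"), "ns")))
    return pd.DataFrame({"gene": som.index, "label": labels})


def classify_compartment(
    compartment_de: pd.DataFrame,
    q_thresh: float = 0.05,
    logfc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Compartment-enrichment calls: q < ``q_thresh`` and |logFC| > ``logfc_thresh``.

    Positive logFC means higher in processes.
    """
    sig = (compartment_de["fdr"].to_numpy() < q_thresh) & \
          (np.abs(compartment_de["logFC"].to_numpy()) > logfc_thresh)
    label = np.where(sig & (compartment_de["logFC"].to_numpy() > 0),
                     "process_enriched",
                     np.where(sig, "somata_enriched", "ns"))
    return pd.DataFrame({"gene": compartment_de["gene"], "label": label})
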