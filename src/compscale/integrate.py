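"""Cross-omics and cross-compartment correlation of matched logFC vectors."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p from the t approximation t = rho * sqrt((n - 2) / (1 - rho^2)) on
    n - 2 df, two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation; p from a t-distribution with n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pair_changes(
    rna: pd.DataFrame,
    prot: pd.DataFrame,
    mapping: pd.Series | dict | None = None,
    gene_subset: set[str] | None = None,
    rna_sig: float = 0.05,
    prot_sig: float = 0.5,
) -> pd.DataFrame:
    """Inner-join RNA and protein logFC tables on gene.

    ``mapping`` translates protein ids to gene symbols first (identity when
    absent).  ``gene_subset`` optionally restricts to a curated gene list
    (e.g. synaptic genes).  Significance flags use the study thresholds
    (RNA fdr < 0.05, protein fdr < 0.5) by default.
    """
    r = rna[["gene", "logFC", "fdr"]].rename(
        columns={"logFC": "logFC_rna", "fdr": "fdr_rna"})
    p = prot.copy()
    id_col = "protein" if "protein" in p.columns else "gene"
    if mapping is not None:
        p["gene"] = p[id_col].map(pd.Series(mapping)).fillna(p[id_col])
    elif id_col == "protein":
        p["gene"] = p["protein"]
    p = p[["gene", "logFC", "fdr"]].rename(
        columns={"logFC": "logFC_prot", "fdr": "fdr_prot"})
    merged = r.merge(p, on="gene", how="inner")
    if merged.empty:
        raise ValueError("RNA and protein tables share no features")
    if gene_subset is not None:
        merged = merged[merged["gene"].isin(gene_subset)]
        if merged.empty:
            raise ValueError("no shared features in the requested gene subset")
    merged["sig_rna"] = merged["fdr_rna"] < rna_sig
    merged["sig_prot"] = merged["fdr_prot"] < prot_sig
    bad = ~np.isfinite(merged["logFC_rna"]) | ~np.isfinite(merged["logFC_prot"])
    return merged.loc[~bad].reset_index(drop=True)


def correlation_table(pairs_by_name: dict[str, pd.DataFrame],
                      method: str = "spearman") -> pd.DataFrame:
    """One correlation row per named paired-changes table."""
    func = spearman if method == "spearman" else pearson
    rows = []
    for name, pairs in pairs_by_name.items():
        rho, p = func(pairs["logFC_rna"], pairs["logFC_prot"])
        rows.append({"comparison": name, "n": len(pairs), "method": method,
                     "rho_or_r": rho, "p": p})
    return pd.DataFrame(rows)
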