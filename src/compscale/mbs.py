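"""miRNA-binding-site (MBS) enrichment in regulated gene sets.

Conserved family site counts (a TargetScan-like table) are summed over a
gene set of interest and its compartment-specific expressed background, and
each family is tested with an upper-tail hypergeometric test *on the number
of binding sites*: of the N site tokens in the background (all expressed
families), K belong to the family, and the set of interest carries n tokens
of which x belong to the family.  Families are called enriched at p < 0.05
and log2 fold enrichment > 0.5.

The up-vs-down site-ratio analysis compares, per family, per-gene-normalized
site densities between down- and upregulated genes; positive values mean
more sites in downregulated transcripts.  Ratio distributions of the two
compartments are compared with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .rnaseq import bh_adjust


def filter_expressed_families(expression: pd.DataFrame) -> set[str]:
    """Families with at least one member miRNA expressed strictly above the
    median of all detected miRNAs."""
    if expression.empty:
        raise ValueError("empty miRNA expression table")
    median = expression["expression"].median()
    passing = expression.loc[expression["expression"] > median, "family"]
    return set(passing.unique())


def _family_gene_counts(sites: pd.DataFrame, families: set[str]) -> pd.DataFrame:
    sub = sites[sites["family"].isin(families)]
    return sub.pivot_table(index="gene", columns="family", values="site_count",
                           aggfunc="sum", fill_value=0)


def site_hypergeom(
    set_genes: set[str],
    background_genes: set[str],
    sites: pd.DataFrame,
    family: str,
    families: set[str] | None = None,
    pseudocount: float = 0.5,
) -> dict:
    """Hypergeometric enrichment of one family's sites in a gene set.

    x = family sites over the set; n = sites of all (expressed) families
    over the set; K, N = the same over the background.  p = P[X >= x] for
    X ~ Hypergeom(N, K, n); log2FE uses a Haldane-Anscombe-style
    ``pseudocount`` to stay finite.
    """
    set_genes = set(set_genes)
    background_genes = set(background_genes)
    if not set_genes <= background_genes:
        raise ValueError("gene set must be contained in the background")
    if families is None:
        families = set(sites["family"].unique())
    if family not in families:
        raise ValueError(f"family {family!r} not in the family universe")
    sub = sites[sites["family"].isin(families)]
    in_set = sub["gene"].isin(set_genes)
    in_bg = sub["gene"].isin(background_genes)
    is_fam = sub["family"] == family
    x = int(sub.loc[in_set & is_fam, "site_count"].sum())
    n = int(sub.loc[in_set, "site_count"].sum())
    K = int(sub.loc[in_bg & is_fam, "site_count"].sum())
    N = int(sub.loc[in_bg, "site_count"].sum())
    if N == 0:
        raise ValueError("background contains no sites")
    p = float(stats.hypergeom.sf(x - 1, N, K, n)) if n > 0 else 1.0
    log2fe = float(np.log2(((x + pseudocount) / (n + pseudocount)) /
                           ((K + pseudocount) / (N + pseudocount))))
    return {"family": family, "x": x, "n": n, "K": K, "N": N,
            "log2FE": log2fe, "p": min(p, 1.0)}


def run_family_scan(
    down_sets: dict[str, set[str]],
    backgrounds: dict[str, set[str]],
    sites: pd.DataFrame,
    families: set[str],
    p_thresh: float = 0.05,
    fe_thresh: float = 0.5,
) -> pd.DataFrame:
    """Per-(family, compartment) enrichment records with significance flags.

    ``down_sets`` maps compartment -> exclusively downregulated genes;
    ``backgrounds`` maps compartment -> expressed genes.  A family is
    flagged when p < ``p_thresh`` and log2FE > ``fe_thresh``.
    """
    if not families:
        raise ValueError("empty family list")
    rows = []
    for compartment, gene_set in down_sets.items():
        background = backgrounds[compartment]
        for family in sorted(families):
            rec = site_hypergeom(gene_set, background, sites, family,
                                 families=families)
            rec["compartment"] = compartment
            rows.append(rec)
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for compartment in down_sets:
        mask = out["compartment"] == compartment
        out.loc[mask, "fdr"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["flagged"] = (out["p"] < p_thresh) & (out["log2FE"] > fe_thresh)
    return out.reset_index(drop=True)


def updown_site_ratio(
    up_set: set[str],
    down_set: set[str],
    sites: pd.DataFrame,
    family: str,
    pseudocount: float = 0.5,
) -> float:
    """Per-gene-normalized log2 site-density ratio, down over up.

    ratio = log2(((sites_down + pc) / |down|) / ((sites_up + pc) / |up|));
    positive values mean the family's sites are more frequent in
    downregulated genes.
    """
    if not up_set or not down_set:
        raise ValueError("both gene sets must be non-empty")
    fam = sites[sites["family"] == family]
    s_down = float(fam.loc[fam["gene"].isin(down_set), "site_count"].sum())
    s_up = float(fam.loc[fam["gene"].isin(up_set), "site_count"].sum())
    return float(np.log2(((s_down + pseudocount) / len(down_set)) /
                         ((s_up + pseudocount) / len(up_set))))


def ratio_table(
    up_sets: dict[str, set[str]],
    down_sets: dict[str, set[str]],
    sites: pd.DataFrame,
    families: set[str],
    min_total_sites: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-family down/up ratios per compartment.

    Families whose total sites over the union of both sets fall below
    ``min_total_sites`` in a compartment are excluded there (the study's
    family-selection rule is reproduced as a minimum-evidence filter).
    """
    rows = []
    for compartment in down_sets:
        up, down = up_sets[compartment], down_sets[compartment]
        both = up | down
        totals = sites[sites["gene"].isin(both)].groupby("family")[
            "site_count"].sum()
        for family in sorted(families):
            if totals.get(family, 0) < min_total_sites:
                continue
            rows.append({
                "family": family, "compartment": compartment,
                "ratio": updown_site_ratio(up, down, sites, family,
                                           pseudocount=pseudocount)})
    return pd.DataFrame(rows)


def compare_compartments(
    ratios_somata, ratios_processes,
) -> dict:
    """Two-sided Mann-Whitney U on per-family ratios of the two compartments.

    Exact enumeration for small tie-free samples (scipy's 'auto' rule),
    midrank-corrected normal approximation otherwise.
    """
    a = np.asarray(ratios_somata, dtype=float)
    b = np.asarray(ratios_processes, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both ratio groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "mean_somata": float(a.mean()),
        "mean_processes": float(b.mean()),
        "n_somata": int(a.size),
        "n_processes": int(b.size),
    }
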