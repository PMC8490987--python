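"""End-to-end orchestration of the compartment-scaling analysis.

``run_all`` composes the stages — expression filtering, TMM, NB GLM with
likelihood-ratio contrasts, BH adjustment, set classification, proteomics
moderated statistics, RNA/protein correlation, 3'UTR length and motif
enrichment, miRNA-binding-site enrichment, and GO enrichment — on a fixture
directory, writing tidy result tables, a JSON run manifest (config hash,
seeds, per-stage row counts) and a plain-text log recording every decision
that resolves an ambiguity (background definitions, ratio orientation).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import go as go_mod
from . import integrate, io, mbs, proteomics, rnaseq, utr
from .config import RunConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> Path:
    """Run every enabled stage; returns the output directory."""
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {"config": config.analysis_dict(),
                      "config_hash": config.config_hash(),
                      "seed": config.seed, "stages": {}}

    def log(msg: str) -> None:
        log_lines.append(msg)

    # ---- RNA differential expression -------------------------------------
    stage = "rnaseq_de"
    try:
        counts = io.read_counts(indir / "counts.tsv")
        design = io.read_design(indir / "design.tsv")
        results, fit, disp = rnaseq.run_de(
            counts, design, min_count=config.filter_min_count,
            min_samples=config.filter_min_samples,
            prior_df=config.dispersion_prior_df)
        for name, table in results.items():
            table = table.copy()
            table["config_hash"] = manifest["config_hash"]
            io.write_tsv(table, outdir / f"de_{name}.tsv")
        sets = rnaseq.classify_sets(results["ptx_in_somata"],
                                    results["ptx_in_processes"],
                                    q_thresh=config.rna_q)
        comp_sets = rnaseq.classify_compartment(
            results["compartment_in_mock"], q_thresh=config.rna_q,
            logfc_thresh=config.rna_logfc_cut)
        sets = sets.merge(comp_sets.rename(columns={"label": "compartment_label"}),
                          on="gene")
        sets["config_hash"] = manifest["config_hash"]
        io.write_tsv(sets, outdir / "sets.tsv")
        backgrounds = {
            comp: set(rnaseq.filter_expressed(
                counts, config.filter_min_count, config.filter_min_samples,
                scope="per_compartment", design=design, compartment=comp).index)
            for comp in ("somata", "processes")}
        log("backgrounds: expressed = >" + str(config.filter_min_count)
            + " reads in >=" + str(config.filter_min_samples)
            + " samples of the compartment (the 'two conditions' wording is "
            "read as two samples)")
        manifest["stages"][stage] = {
            "genes_tested": int(len(fit.genes)),
            "common_dispersion": disp.common,
            "de_counts": {name: int((t["fdr"] < config.rna_q).sum())
                          for name, t in results.items()}}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    labels = sets.set_index("gene")["label"]
    down_sets = {
        "somata": set(labels.index[labels == "somata_only_down"]),
        "processes": set(labels.index[labels == "processes_only_down"])}
    up_sets = {
        "somata": set(labels.index[labels == "somata_only_up"]),
        "processes": set(labels.index[labels == "processes_only_up"])}
    # regulated sets confined to their compartment background
    down_sets = {c: s & backgrounds[c] for c, s in down_sets.items()}
    up_sets = {c: s & backgrounds[c] for c, s in up_sets.items()}

    # ---- proteomics ------------------------------------------------------
    prot_results = None
    if config.run_proteomics and (indir / "intensities.tsv").exists():
        stage = "proteome_de"
        try:
            intensities = io.read_intensities(indir / "intensities.tsv")
            pdesign_path = indir / "protein_design.tsv"
            pdesign = io.read_design(pdesign_path if pdesign_path.exists()
                                     else indir / "design.tsv")
            fit_p, prot_results = proteomics.run_protein_de(
                intensities, pdesign, q=config.minprob_q,
                width=config.minprob_width, seed=config.seed,
                fdr_thresh=config.protein_fdr)
            for name, table in prot_results.items():
                table = table.copy()
                table["config_hash"] = manifest["config_hash"]
                io.write_tsv(table, outdir / f"prot_de_{name}.tsv")
            with open(outdir / "fit_metadata.json", "w") as fh:
                json.dump({"d0": None if fit_p.d0 != fit_p.d0 else
                           ("inf" if fit_p.d0 == float("inf") else fit_p.d0),
                           "s02": fit_p.s02,
                           "imputation_seed": config.seed}, fh, indent=1)
            manifest["stages"][stage] = {
                "proteins_tested": int(len(intensities)),
                "de_counts": {name: int((t["fdr"] < config.protein_fdr).sum())
                              for name, t in prot_results.items()}}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        log("proteomics stage disabled or intensities.tsv absent; "
            "integration will be skipped")

    # ---- integration -----------------------------------------------------
    if config.run_integration and prot_results is not None:
        stage = "integration"
        try:
            synaptic = None
            if (indir / "synaptic_genes.txt").exists():
                synaptic = io.read_gene_list(indir / "synaptic_genes.txt")
            pairs = {}
            for comp, rna_name in (("somata", "ptx_in_somata"),
                                   ("processes", "ptx_in_processes")):
                paired = integrate.pair_changes(
                    results[rna_name], prot_results[rna_name],
                    rna_sig=config.rna_q, prot_sig=config.protein_fdr)
                pairs[f"rna_vs_protein_{comp}"] = paired
                sig = paired[paired["sig_rna"] & paired["sig_prot"]]
                if len(sig) >= 4:
                    pairs[f"rna_vs_protein_{comp}_significant"] = sig
                if synaptic:
                    syn = paired[paired["gene"].isin(synaptic)]
                    if len(syn) >= 4:
                        pairs[f"rna_vs_protein_{comp}_synaptic"] = syn
            corr = pd.concat([
                integrate.correlation_table(pairs, method="spearman"),
                integrate.correlation_table(pairs, method="pearson"),
            ], ignore_index=True)
            corr["config_hash"] = manifest["config_hash"]
            io.write_tsv(corr, outdir / "correlations.tsv")
            manifest["stages"][stage] = {"comparisons": int(len(corr))}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    elif config.run_integration:
        log("integration skipped: no proteomics results")

    # ---- 3'UTR lengths and RBP motifs ------------------------------------
    utr_lengths = None
    if config.run_utr and (indir / "utr_lengths.tsv").exists():
        stage = "utr_lengths"
        try:
            iso = io.read_table(indir / "utr_lengths.tsv")
            longest = utr.select_longest_utr(iso)
            utr_lengths = longest.set_index("gene")["length"]
            rows = []
            for comp in ("somata", "processes"):
                down = [utr_lengths[g] for g in down_sets[comp]
                        if g in utr_lengths]
                upl = [utr_lengths[g] for g in up_sets[comp]
                       if g in utr_lengths]
                if len(down) >= 2 and len(upl) >= 2:
                    d, p = utr.ks_two_sample(down, upl)
                    rows.append({"comparison": f"down_vs_up_{comp}",
                                 "n_a": len(down), "n_b": len(upl),
                                 "D": d, "p": p})
            table = pd.DataFrame(rows)
            table["config_hash"] = manifest["config_hash"]
            io.write_tsv(table, outdir / "utr_lengths_test.tsv")
            manifest["stages"][stage] = {"comparisons": int(len(table))}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if config.run_motifs and (indir / "utr.fasta").exists() \
            and (indir / "motifs.meme").exists():
        stage = "rbp_motifs"
        try:
            seqs = io.read_utr_fasta(indir / "utr.fasta")
            motifs = utr.read_meme(indir / "motifs.meme")
            frames = []
            for comp in ("somata", "processes"):
                bg = {g: seqs[g] for g in backgrounds[comp] if g in seqs}
                for direction, gene_sets in (("down", down_sets),
                                             ("up", up_sets)):
                    pos = {g: seqs[g] for g in gene_sets[comp] if g in seqs}
                    if not pos:
                        continue
                    enr = utr.ame_fisher_enrichment(pos, bg, motifs)
                    enr.insert(0, "set", f"{direction}_{comp}")
                    frames.append(enr)
            table = pd.concat(frames, ignore_index=True)
            table["config_hash"] = manifest["config_hash"]
            io.write_tsv(table, outdir / "rbp_enrichment.tsv")
            manifest["stages"][stage] = {"records": int(len(table))}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- miRNA-binding sites ---------------------------------------------
    if config.run_mbs and (indir / "mbs_sites.tsv").exists():
        stage = "mbs_enrichment"
        try:
            sites = io.read_table(indir / "mbs_sites.tsv")
            expr = io.read_table(indir / "mirna_expression.tsv")
            families = mbs.filter_expressed_families(expr)
            log("miRNA families restricted to those with a member expressed "
                "strictly above the median of all detected miRNAs")
            scan = mbs.run_family_scan(down_sets, backgrounds, sites, families,
                                       p_thresh=config.mbs_p,
                                       fe_thresh=config.mbs_log2fe)
            scan["config_hash"] = manifest["config_hash"]
            io.write_tsv(scan, outdir / "mbs_enrichment.tsv")
            ratios = mbs.ratio_table(up_sets, down_sets, sites, families,
                                     min_total_sites=config.mbs_min_total_sites)
            log("site ratios oriented positive = more sites in downregulated "
                "genes; per-gene-normalized site densities")
            ratios["config_hash"] = manifest["config_hash"]
            io.write_tsv(ratios, outdir / "mbs_ratio.tsv")
            comparison = {}
            rs = ratios.loc[ratios["compartment"] == "somata", "ratio"]
            rp = ratios.loc[ratios["compartment"] == "processes", "ratio"]
            if len(rs) and len(rp):
                comparison = mbs.compare_compartments(rs, rp)
            with open(outdir / "mbs_compartment_test.json", "w") as fh:
                json.dump(comparison, fh, indent=1)
            manifest["stages"][stage] = {
                "families_tested": int(len(families)),
                "flagged": int(scan["flagged"].sum())}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- GO enrichment ----------------------------------------------------
    if config.run_go and (indir / "go_dag.tsv").exists():
        stage = "go_enrichment"
        try:
            dag = go_mod.GoDag.from_table(io.read_table(indir / "go_dag.tsv"))
            annotations = io.read_table(indir / "go_annotations.tsv")
            caps = {"CC": config.go_max_annotated_cc,
                    "BP": config.go_max_annotated_bp, "MF": None}
            frames = []
            for comp in ("somata", "processes"):
                for direction, gene_sets in (("down", down_sets),
                                             ("up", up_sets)):
                    gene_set = gene_sets[comp] & backgrounds[comp]
                    if not gene_set:
                        continue
                    for ns, cap in caps.items():
                        enr = go_mod.term_enrichment(
                            gene_set, backgrounds[comp], dag, annotations,
                            namespace=ns, max_annotated=cap)
                        if not enr.empty:
                            enr.insert(0, "set", f"{direction}_{comp}")
                            frames.append(enr)
            table = (pd.concat(frames, ignore_index=True)
                     if frames else pd.DataFrame())
            if not table.empty:
                table["config_hash"] = manifest["config_hash"]
            io.write_tsv(table, outdir / "go_enrichment.tsv")
            top = (table.groupby("set", sort=True)
                   .apply(lambda d: go_mod.top_terms(d, k=config.go_top_k),
                          include_groups=False)
                   .reset_index(level=0).reset_index(drop=True)
                   if not table.empty else table)
            io.write_tsv(top, outdir / "top_terms.tsv")
            manifest["stages"][stage] = {"records": int(len(table))}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
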