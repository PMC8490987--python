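"""Synthetic compartmentalized multi-omics study with known planted structure.

Generates a complete 2 (compartment) x 2 (treatment) study: negative-binomial
RNA counts, log-normal protein intensities with intensity-dependent (MNAR)
missingness, 3'UTR lengths and sequences with planted motif occurrences, a
miRNA-family binding-site table with activity concentrated in
process-downregulated genes, and a toy GO DAG — together with the ground
truth needed to score recovery of every downstream analysis stage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SynthConfig
from .utr import MotifModel, write_meme

COMPARTMENTS = ("somata", "processes")
TREATMENTS = ("mock", "ptx")

UTR_BACKGROUND = np.array([0.3, 0.2, 0.2, 0.3])  # A C G T


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child generator derived from the global seed and a stage name."""
    child = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, child])


@dataclass
class GroundTruth:
    """Planted effects and memberships — the recovery target for all tests.

    ``effects`` is indexed by gene with the planted log2 compartment
    enrichment, per-compartment treatment logFC (RNA and protein), the true
    3'UTR length and the motif-positive flag.
    """

    effects: pd.DataFrame
    active_families: list[str]
    planted_motif_id: str
    planted_consensus: str
    motif_positive_genes: list[str]
    planted_go_term: str
    protein_detected: list[str] = field(default_factory=list)
    protein_complete: pd.DataFrame | None = None
    protein_missing_mask: pd.DataFrame | None = None

    def genes_with_label(self, label: str, column: str = "treatment_label") -> list[str]:
        return list(self.effects.index[self.effects[column] == label])


@dataclass
class GeneAnnotations:
    """All simulated annotation tables for one synthetic universe."""

    genes: pd.DataFrame            # gene, baseline_log2cpm, labels, utr_length
    utr_isoforms: pd.DataFrame     # gene, transcript, length
    sites: pd.DataFrame            # family, gene, site_count (non-zero rows)
    mirna_expression: pd.DataFrame  # mirna, family, expression
    go_annotations: pd.DataFrame   # gene, term
    go_dag: pd.DataFrame           # term, parent, namespace
    motifs: list[MotifModel]
    config: SynthConfig


def _sharp_pwm(consensus: str, rng: np.random.Generator,
               peak: float = 0.85) -> np.ndarray:
    w = len(consensus)
    mat = np.full((w, 4), (1.0 - peak) / 3.0)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = peak
    return mat


def _toy_go_dag(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ns in ("BP", "MF", "CC"):
        root = f"GO:{ns}:root"
        rows.append({"term": root, "parent": "", "namespace": ns})
        n_mid = max(2, config.go_terms_per_namespace // 4)
        mids = [f"GO:{ns}:mid{i:02d}" for i in range(n_mid)]
        for mid in mids:
            rows.append({"term": mid, "parent": root, "namespace": ns})
        n_leaf = config.go_terms_per_namespace - n_mid
        for i in range(n_leaf):
            parent = mids[int(rng.integers(0, n_mid))]
            rows.append({"term": f"GO:{ns}:leaf{i:02d}", "parent": parent,
                         "namespace": ns})
    return pd.DataFrame(rows)


def generate_universe(config: SynthConfig) -> tuple[GeneAnnotations, GroundTruth]:
    """Generate per-gene annotations and the planted ground truth.

    Compartment-enrichment and treatment memberships are drawn independently;
    treatment categories (down/up in exactly one compartment) are mutually
    exclusive, so the "exclusively downregulated" sets used by the
    binding-site analyses are planted directly.
    """
    config.validate()
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    n = config.n_genes

    rng = stage_rng(config.seed, "universe")
    baseline = rng.uniform(*config.baseline_log_mean_range, size=n)

    # compartment-enrichment labels (half somata-, half process-enriched)
    comp_label = np.array(["none"] * n, dtype=object)
    k_comp = int(round(config.frac_compartment_enriched * n))
    order = rng.permutation(n)
    comp_label[order[: k_comp // 2]] = "process_enriched"
    comp_label[order[k_comp // 2: k_comp]] = "somata_enriched"

    # mutually exclusive treatment categories
    trt_label = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    start = 0
    for name, frac in (
        ("down_processes", config.frac_ptx_down_processes),
        ("down_somata", config.frac_ptx_down_somata),
        ("up_processes", config.frac_ptx_up_processes),
        ("up_somata", config.frac_ptx_up_somata),
    ):
        k = int(round(frac * n))
        trt_label[order[start: start + k]] = name
        start += k

    comp_logfc = np.where(comp_label == "process_enriched", config.compartment_logfc,
                          np.where(comp_label == "somata_enriched",
                                   -config.compartment_logfc, 0.0))
    trt_som = np.where(trt_label == "down_somata", -config.treatment_logfc,
                       np.where(trt_label == "up_somata", config.treatment_logfc, 0.0))
    trt_proc = np.where(trt_label == "down_processes", -config.treatment_logfc,
                        np.where(trt_label == "up_processes", config.treatment_logfc, 0.0))

    # protein treatment effects coupled to the RNA effects
    rho = config.rna_protein_effect_correlation
    noise = np.sqrt(max(0.0, 1.0 - rho ** 2)) * config.protein_effect_noise_sd
    prot_som = rho * trt_som + noise * rng.standard_normal(n)
    prot_proc = rho * trt_proc + noise * rng.standard_normal(n)

    # 3'UTR lengths (log-normal, brain-like long tails)
    mu, sigma = config.utr_length_lognormal_params
    utr_len = np.maximum(
        np.round(rng.lognormal(mu, sigma, size=n)).astype(int), 5)

    # motifs: one planted consensus + decoys
    rng_m = stage_rng(config.seed, "motifs")
    consensi: list[str] = []
    while len(consensi) < config.n_decoy_motifs + 1:
        cand = "".join(rng_m.choice(list("ACGT"), size=config.motif_width,
                                    p=UTR_BACKGROUND))
        if cand not in consensi:
            consensi.append(cand)
    motifs = [MotifModel("planted_motif" if i == 0 else f"decoy{i:02d}",
                         _sharp_pwm(c, rng_m), background=UTR_BACKGROUND.copy())
              for i, c in enumerate(consensi)]
    planted = motifs[0]

    down_proc_idx = np.flatnonzero(trt_label == "down_processes")
    n_pos = int(round(config.motif_positive_fraction * down_proc_idx.size))
    pos_idx = rng_m.choice(down_proc_idx, size=n_pos, replace=False) \
        if n_pos else np.array([], dtype=int)
    motif_positive = np.zeros(n, dtype=bool)
    motif_positive[pos_idx] = True
    # a motif-positive UTR must be able to carry the consensus
    utr_len[pos_idx] = np.maximum(utr_len[pos_idx], config.motif_width + 10)

    # miRNA families, member miRNAs, expression, and the site table
    rng_f = stage_rng(config.seed, "families")
    families = [f"fam{i:03d}" for i in range(config.n_mirna_families)]
    active = sorted(rng_f.choice(families, size=config.n_active_families,
                                 replace=False).tolist())
    mir_rows = []
    for fam in families:
        for j in range(int(rng_f.integers(1, 4))):
            mir_rows.append({"mirna": f"miR-{fam[3:]}-{j}", "family": fam,
                             "expression": float(rng_f.lognormal(2.0, 1.0))})
    mirna_expression = pd.DataFrame(mir_rows)
    if len(mirna_expression) and active:
        top = mirna_expression["expression"].max() * 1.1
        for fam in active:  # guarantee active families pass the expressed filter
            first = mirna_expression.index[mirna_expression["family"] == fam][0]
            mirna_expression.loc[first, "expression"] = top

    rate = np.full((n, config.n_mirna_families), config.site_rate)
    fam_index = {f: k for k, f in enumerate(families)}
    for fam in active:
        rate[down_proc_idx, fam_index[fam]] *= config.active_site_enrichment
    counts = rng_f.poisson(rate)
    gi, fi = np.nonzero(counts)
    sites = pd.DataFrame({
        "family": [families[k] for k in fi],
        "gene": [genes[g] for g in gi],
        "site_count": counts[gi, fi],
    }).sort_values(["family", "gene"]).reset_index(drop=True)

    # GO DAG and annotations; one BP leaf enriched in process-down genes
    rng_g = stage_rng(config.seed, "go")
    go_dag = _toy_go_dag(config, rng_g)
    leaves = go_dag.loc[go_dag["term"].str.contains("leaf"), "term"].tolist()
    planted_go = next(t for t in leaves if ":BP:" in t)
    lo, hi = config.go_annotations_per_gene
    annot_rows = []
    for g_idx, gene in enumerate(genes):
        k = int(rng_g.integers(lo, hi + 1))
        for term in rng_g.choice(leaves, size=k, replace=False):
            annot_rows.append({"gene": gene, "term": term})
        p_extra = 0.5 if trt_label[g_idx] == "down_processes" else 0.05
        if rng_g.random() < p_extra:
            annot_rows.append({"gene": gene, "term": planted_go})
    go_annotations = pd.DataFrame(annot_rows).drop_duplicates().sort_values(
        ["gene", "term"]).reset_index(drop=True)

    # isoform table: the true (longest) transcript plus a shorter decoy for some genes
    iso_rows = []
    rng_u = stage_rng(config.seed, "isoforms")
    for g_idx, gene in enumerate(genes):
        iso_rows.append({"gene": gene, "transcript": f"{gene}.t1",
                         "length": int(utr_len[g_idx])})
        if rng_u.random() < 0.3 and utr_len[g_idx] > 30:
            iso_rows.append({"gene": gene, "transcript": f"{gene}.t2",
                             "length": int(rng_u.integers(21, utr_len[g_idx]))})
    utr_isoforms = pd.DataFrame(iso_rows)

    effects = pd.DataFrame({
        "baseline_log2cpm": baseline,
        "compartment_label": comp_label,
        "treatment_label": trt_label,
        "comp_logfc": comp_logfc,
        "trt_logfc_somata": trt_som,
        "trt_logfc_processes": trt_proc,
        "prot_logfc_somata": prot_som,
        "prot_logfc_processes": prot_proc,
        "utr_length": utr_len,
        "motif_positive": motif_positive,
    }, index=pd.Index(genes, name="gene"))

    genes_table = effects.reset_index()[
        ["gene", "baseline_log2cpm", "compartment_label", "treatment_label",
         "utr_length"]]
    annotations = GeneAnnotations(
        genes=genes_table, utr_isoforms=utr_isoforms, sites=sites,
        mirna_expression=mirna_expression, go_annotations=go_annotations,
        go_dag=go_dag, motifs=motifs, config=config)
    truth = GroundTruth(
        effects=effects, active_families=active,
        planted_motif_id=planted.motif_id, planted_consensus=planted.consensus,
        motif_positive_genes=[genes[i] for i in sorted(pos_idx.tolist())],
        planted_go_term=planted_go)
    return annotations, truth


def _design_table(n_replicates: int) -> pd.DataFrame:
    rows = []
    for comp in COMPARTMENTS:
        for trt in TREATMENTS:
            for rep in range(1, n_replicates + 1):
                rows.append({"sample": f"{comp}_{trt}_r{rep}",
                             "compartment": comp, "treatment": trt,
                             "replicate": rep})
    return pd.DataFrame(rows)


def expected_log2_abundance(truth: GroundTruth, design: pd.DataFrame) -> pd.DataFrame:
    """Planted per-gene log2 relative abundance for every sample."""
    eff = truth.effects
    cols = {}
    for _, row in design.iterrows():
        eta = eff["baseline_log2cpm"].to_numpy().copy()
        if row["compartment"] == "processes":
            eta = eta + eff["comp_logfc"].to_numpy()
            if row["treatment"] == "ptx":
                eta = eta + eff["trt_logfc_processes"].to_numpy()
        elif row["treatment"] == "ptx":
            eta = eta + eff["trt_logfc_somata"].to_numpy()
        cols[row["sample"]] = eta
    return pd.DataFrame(cols, index=eff.index)


def simulate_rna_counts(
    annotations: GeneAnnotations, truth: GroundTruth, config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for the 2x2 design.

    Per-sample gene fractions are the renormalized planted log2 abundances,
    so planted effects also induce composition shifts; counts are drawn as a
    gamma-Poisson mixture with dispersion phi (Poisson when phi = 0).
    """
    rng = stage_rng(config.seed, "rna_counts")
    design = _design_table(config.n_replicates_rna)
    lib_sizes = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1,
                             size=len(design))
    eta = expected_log2_abundance(truth, design).to_numpy()
    frac = np.exp2(eta)
    frac /= frac.sum(axis=0, keepdims=True)
    mu = frac * lib_sizes[None, :]
    phi = config.dispersion
    if phi <= 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=truth.effects.index.copy(),
                             columns=design["sample"].tolist())
    return counts_df, design


def simulate_protein_intensities(
    annotations: GeneAnnotations, truth: GroundTruth, config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal protein intensities with MNAR missingness.

    A random subset of genes is "detected" as proteins.  Log2 intensities are
    a protein baseline plus the planted compartment effect plus the coupled
    protein treatment effect plus replicate noise.  Each cell is masked with
    probability ``missing_intensity_scale * (1 - Phi((x - c_j) / 1))`` where
    ``c_j`` is the sample's 5th percentile of log2 intensity, so missingness
    concentrates in the lowest-intensity cells; at the default scale the
    vast majority of proteins have no missing value at all, matching the
    structure of deep label-free experiments.  The complete matrix and the
    mask are stored on ``truth`` for recovery tests.
    """
    from scipy.stats import norm

    rng = stage_rng(config.seed, "protein")
    design = _design_table(config.n_replicates_protein)
    genes = truth.effects.index.to_numpy()
    n_det = int(round(config.protein_detected_fraction * len(genes)))
    detected = np.sort(rng.choice(len(genes), size=n_det, replace=False))
    det_genes = genes[detected]
    eff = truth.effects.loc[det_genes]

    base = rng.normal(25.0, 2.0, size=n_det)
    cols = {}
    for j, (_, row) in enumerate(design.iterrows()):
        mean = base.copy()
        if row["compartment"] == "processes":
            mean = mean + eff["comp_logfc"].to_numpy()
            if row["treatment"] == "ptx":
                mean = mean + eff["prot_logfc_processes"].to_numpy()
        elif row["treatment"] == "ptx":
            mean = mean + eff["prot_logfc_somata"].to_numpy()
        cols[row["sample"]] = mean + rng.normal(0.0, config.protein_noise_sd,
                                                size=n_det)
    log2_mat = pd.DataFrame(cols, index=pd.Index(det_genes, name="protein"))

    raw = np.exp2(log2_mat)
    if config.missing_intensity_scale > 0:
        c = np.quantile(log2_mat.to_numpy(), 0.05, axis=0)
        p_miss = config.missing_intensity_scale * norm.sf(
            (log2_mat.to_numpy() - c[None, :]) / 1.0)
        mask = rng.random(p_miss.shape) < p_miss
    else:
        mask = np.zeros(log2_mat.shape, dtype=bool)
    intensities = raw.mask(mask)

    truth.protein_detected = list(det_genes)
    truth.protein_complete = raw
    truth.protein_missing_mask = pd.DataFrame(mask, index=raw.index,
                                              columns=raw.columns)
    return intensities, design


def make_utr_sequences(
    annotations: GeneAnnotations, truth: GroundTruth, config: SynthConfig,
) -> dict[str, str]:
    """i.i.d. background sequences with the planted consensus inserted into
    motif-positive genes (one exact occurrence at a random position)."""
    rng = stage_rng(config.seed, "utr_seq")
    consensus = truth.planted_consensus
    pos = set(truth.motif_positive_genes)
    bases = np.array(list("ACGT"))
    seqs = {}
    for gene, length in truth.effects["utr_length"].items():
        seq = rng.choice(bases, size=int(length), p=UTR_BACKGROUND)
        if gene in pos:
            start = int(rng.integers(0, int(length) - len(consensus) + 1))
            seq[start: start + len(consensus)] = list(consensus)
        seqs[gene] = "".join(seq)
    return seqs


def write_fixture(
    dir_path: str | Path,
    annotations: GeneAnnotations,
    truth: GroundTruth,
    counts: pd.DataFrame,
    rna_design: pd.DataFrame,
    intensities: pd.DataFrame,
    protein_design: pd.DataFrame,
    sequences: dict[str, str] | None = None,
) -> dict:
    """Write all study tables to ``dir_path`` and return a file manifest."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    config = annotations.config
    if sequences is None:
        sequences = make_utr_sequences(annotations, truth, config)

    counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    rna_design.to_csv(out / "design.tsv", sep="\t", index=False)
    intensities.to_csv(out / "intensities.tsv", sep="\t", index_label="protein")
    protein_design.to_csv(out / "protein_design.tsv", sep="\t", index=False)
    annotations.utr_isoforms.to_csv(out / "utr_lengths.tsv", sep="\t", index=False)
    annotations.sites.to_csv(out / "mbs_sites.tsv", sep="\t", index=False)
    annotations.mirna_expression.to_csv(out / "mirna_expression.tsv", sep="\t",
                                        index=False)
    annotations.go_annotations.to_csv(out / "go_annotations.tsv", sep="\t",
                                      index=False)
    annotations.go_dag.to_csv(out / "go_dag.tsv", sep="\t", index=False)
    write_meme(out / "motifs.meme", annotations.motifs, background=UTR_BACKGROUND)

    records = [SeqRecord(Seq(seq), id=f"{gene}|{gene}.t1", description="")
               for gene, seq in sequences.items()]
    seqio_write(records, str(out / "utr.fasta"), "fasta")

    # "synaptic genes" analogue: the planted down-regulated genes
    synaptic = sorted(set(truth.genes_with_label("down_processes"))
                      | set(truth.genes_with_label("down_somata")))
    (out / "synaptic_genes.txt").write_text("\n".join(synaptic) + "\n")

    truth_payload = {
        "config": config.to_dict(),
        "active_families": truth.active_families,
        "planted_motif_id": truth.planted_motif_id,
        "planted_consensus": truth.planted_consensus,
        "motif_positive_genes": truth.motif_positive_genes,
        "planted_go_term": truth.planted_go_term,
        "protein_detected": truth.protein_detected,
        "effects": truth.effects.reset_index().to_dict(orient="list"),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1)

    manifest = {"dir": str(out), "files": sorted(
        p.name for p in out.iterdir() if p.is_file())}
    return manifest


def simulate_study(config: SynthConfig):
    """Convenience wrapper: universe + RNA counts + protein intensities."""
    annotations, truth = generate_universe(config)
    counts, rna_design = simulate_rna_counts(annotations, truth, config)
    intensities, prot_design = simulate_protein_intensities(
        annotations, truth, config)
    return annotations, truth, counts, rna_design, intensities, prot_design
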