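"""Configuration objects for the synthetic study generator and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic compartmentalized 2x2 study.

    The generator emulates the structure of a compartment (somata / processes)
    by treatment (mock / PTX) design: negative-binomial RNA counts with
    library-size and composition variation, log-scale protein intensities with
    intensity-dependent (MNAR) missingness, planted compartment-enrichment and
    treatment effects, 3'UTR lengths/sequences with planted motif occurrences,
    a TargetScan-like miRNA-family site table with activity concentrated in
    process-downregulated genes, and a toy GO DAG.

    All proportions are in [0, 1]; the treatment-fraction group and the
    compartment fraction must each sum to at most 1.  A single integer
    ``seed`` fully determines every output; sub-generators derive child
    seeds deterministically by stage name.
    """

    n_genes: int = 4000
    n_replicates_rna: int = 2
    n_replicates_protein: int = 4

    # RNA abundance model
    baseline_log_mean_range: tuple[float, float] = (2.5, 9.5)  # log2 CPM
    dispersion: float = 0.05  # NB dispersion phi (BCV ~ 0.22)
    lib_size_range: tuple[int, int] = (1_500_000, 2_500_000)

    # planted effects (log2 scale)
    frac_compartment_enriched: float = 0.15  # split evenly somata/processes
    compartment_logfc: float = 2.0
    frac_ptx_down_processes: float = 0.05
    frac_ptx_down_somata: float = 0.05
    frac_ptx_up_processes: float = 0.04
    frac_ptx_up_somata: float = 0.04
    treatment_logfc: float = 1.5

    # proteome
    rna_protein_effect_correlation: float = 0.8
    protein_detected_fraction: float = 0.5
    protein_noise_sd: float = 0.3        # replicate SD, log2 scale
    protein_effect_noise_sd: float = 0.5  # decoupling SD when correlation < 1
    missing_intensity_scale: float = 0.05  # max MNAR missingness probability

    # miRNA-binding sites
    n_mirna_families: int = 30
    n_active_families: int = 1
    active_site_enrichment: float = 4.0  # site-rate multiplier in process-down genes
    site_rate: float = 0.3               # Poisson rate of sites per (gene, family)

    # 3'UTRs and motifs
    utr_length_lognormal_params: tuple[float, float] = (6.2, 0.8)  # ln scale
    motif_width: int = 7
    n_decoy_motifs: int = 20
    motif_positive_fraction: float = 0.8  # of process-down genes carry the consensus

    # GO
    go_terms_per_namespace: int = 20
    go_annotations_per_gene: tuple[int, int] = (1, 3)

    seed: int = 0

    def validate(self) -> "SynthConfig":
        fracs = {
            "frac_compartment_enriched": self.frac_compartment_enriched,
            "frac_ptx_down_processes": self.frac_ptx_down_processes,
            "frac_ptx_down_somata": self.frac_ptx_down_somata,
            "frac_ptx_up_processes": self.frac_ptx_up_processes,
            "frac_ptx_up_somata": self.frac_ptx_up_somata,
            "protein_detected_fraction": self.protein_detected_fraction,
            "missing_intensity_scale": self.missing_intensity_scale,
            "motif_positive_fraction": self.motif_positive_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        trt_sum = (
            self.frac_ptx_down_processes
            + self.frac_ptx_down_somata
            + self.frac_ptx_up_processes
            + self.frac_ptx_up_somata
        )
        if trt_sum > 1.0:
            raise ConfigError(f"treatment fractions sum to {trt_sum} > 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not -1.0 <= self.rna_protein_effect_correlation <= 1.0:
            raise ConfigError("rna_protein_effect_correlation outside [-1, 1]")
        if self.active_site_enrichment <= 0:
            raise ConfigError("active_site_enrichment must be > 0")
        if self.n_active_families > self.n_mirna_families:
            raise ConfigError("n_active_families exceeds n_mirna_families")
        if self.n_genes < 1 or self.n_replicates_rna < 1 or self.n_replicates_protein < 1:
            raise ConfigError("counts must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("baseline_log_mean_range", "lib_size_range",
                    "utr_length_lognormal_params", "go_annotations_per_gene"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d).validate()


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Thresholds default to the study's reported conventions: RNA calls at
    q < 0.05, compartment enrichment additionally at |logFC| > 1, protein
    calls at FDR < 0.5, miRNA-family flags at p < 0.05 and log2FE > 0.5,
    GO term-size caps of 1000 (CC) / 300 (BP) genes for the compartment
    analysis and 500 for proteomics.
    """

    input_dir: str = "."
    out_dir: str = "results"

    rna_q: float = 0.05
    rna_logfc_cut: float = 1.0       # used only for compartment-enrichment calls
    protein_fdr: float = 0.5
    mbs_p: float = 0.05
    mbs_log2fe: float = 0.5
    mbs_min_total_sites: int = 10
    go_max_annotated_cc: int = 1000
    go_max_annotated_bp: int = 300
    go_top_k: int = 5

    filter_min_count: int = 20
    filter_min_samples: int = 2
    dispersion_prior_df: float = 10.0
    minprob_q: float = 0.01
    minprob_width: float = 0.3

    run_proteomics: bool = True
    run_integration: bool = True
    run_utr: bool = True
    run_motifs: bool = True
    run_mbs: bool = True
    run_go: bool = True

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def analysis_dict(self) -> dict:
        """Config without filesystem paths (what the analysis depends on)."""
        d = self.to_dict()
        d.pop("input_dir", None)
        d.pop("out_dir", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
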