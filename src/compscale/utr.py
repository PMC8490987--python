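"""3'UTR selection, length-distribution comparison and RBP motif enrichment.

The length analysis compares cumulative 3'UTR length distributions of
regulated gene sets with a two-sample Kolmogorov-Smirnov test.  Motif
enrichment follows an AME-style procedure: each 3'UTR is scored against a
position weight matrix with the *average odds score* (mean over start
positions of the likelihood ratio of the window under the motif vs the
background), sequences are labelled motif-positive at a grid of candidate
score thresholds, and a one-sided Fisher's exact test compares the positive
set against the expressed background at each threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@dataclass
class MotifModel:
    """A position weight matrix over {A, C, G, T} with background frequencies."""

    motif_id: str
    matrix: np.ndarray          # (width, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be (width, 4)")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("motif probabilities outside [0, 1]")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as integer codes (A=0, C=1, G=2, T/U=3, N=4)."""
    seq = seq.upper()
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unexpected base {exc} in sequence") from exc


def avg_odds_score(sequence: str | np.ndarray, motif: MotifModel) -> float:
    """Average odds score of ``sequence`` under ``motif``.

    Mean over all start positions of prod_k p_motif(base, k) / p_bg(base).
    Positions containing N contribute an odds factor of 1 (background).
    The sequence is scanned on the given strand only.
    """
    codes = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    w = motif.width
    if codes.size < w:
        raise ValueError(
            f"sequence length {codes.size} shorter than motif width {w}")
    # odds lookup with a 5th column of ones for N
    odds = np.ones((w, 5))
    odds[:, :4] = (motif.matrix + motif.pseudocount) / motif.background
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    per_pos = odds[np.arange(w)[None, :], windows]
    return float(per_pos.prod(axis=1).mean())


def score_sequences(seqs: dict[str, str], motif: MotifModel) -> pd.Series:
    """Average odds scores for every sequence at least as long as the motif."""
    out = {}
    for name, seq in seqs.items():
        if len(seq) >= motif.width:
            out[name] = avg_odds_score(seq, motif)
    return pd.Series(out, dtype=float)


def select_longest_utr(annotations: pd.DataFrame, min_length: int = 20) -> pd.DataFrame:
    """Pick, per gene, the transcript with the longest 3'UTR.

    ``annotations`` needs columns gene, transcript, length (optionally
    sequence).  Records with length <= ``min_length`` are dropped (strictly
    "more than" ``min_length`` nucleotides).  Length ties are broken by the
    lexicographically smallest transcript id.
    """
    required = {"gene", "transcript", "length"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotations must have columns {sorted(required)}")
    df = annotations.sort_values(
        ["gene", "length", "transcript"], ascending=[True, False, True])
    longest = df.groupby("gene", sort=True).head(1)
    longest = longest[longest["length"] > min_length]
    return longest.reset_index(drop=True)


def ks_two_sample(lengths_a, lengths_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    D = sup |ECDF_a - ECDF_b|; p from the Kolmogorov distribution with
    effective sample size n_a * n_b / (n_a + n_b).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ame_fisher_enrichment(
    pos_seqs: dict[str, str],
    background_seqs: dict[str, str],
    motifs: list[MotifModel] | MotifModel,
    deciles: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
) -> pd.DataFrame:
    """AME-style motif enrichment of a positive sequence set vs a background.

    For each motif, sequences are scored with the average odds score.
    Candidate thresholds are the given quantiles of the background score
    distribution plus the positive-set median.  At each threshold a
    one-sided Fisher's exact test (enrichment) compares motif-positive
    fractions between the positive set and the background *excluding* the
    positive sequences; the minimum p across thresholds is Bonferroni
    corrected by the number of thresholds, then BH-adjusted across motifs.
    """
    from .rnaseq import bh_adjust

    if isinstance(motifs, MotifModel):
        motifs = [motifs]
    if not pos_seqs or not background_seqs:
        raise ValueError("positive and background sets must be non-empty")

    neg_ids = [k for k in background_seqs if k not in pos_seqs]
    rows = []
    for motif in motifs:
        pos_scores = score_sequences(pos_seqs, motif)
        bg_scores = score_sequences(background_seqs, motif)
        neg_scores = bg_scores.loc[[i for i in neg_ids if i in bg_scores.index]]
        if pos_scores.empty or bg_scores.empty:
            raise ValueError(f"no scorable sequences for motif {motif.motif_id}")
        thresholds = np.concatenate([
            np.quantile(bg_scores.to_numpy(), deciles),
            [float(np.median(pos_scores.to_numpy()))],
        ])
        best = None
        for t in thresholds:
            a = int((pos_scores > t).sum())
            b = int(len(pos_scores) - a)
            c = int((neg_scores > t).sum())
            d = int(len(neg_scores) - c)
            if c + d == 0:  # positive set equals the background
                odds, p = float("nan"), 1.0
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]],
                                             alternative="greater")
            if best is None or p < best["p_raw"]:
                best = {"threshold": float(t), "pos_hits": a, "pos_total": a + b,
                        "bg_hits": c, "bg_total": c + d,
                        "odds_ratio": float(odds), "p_raw": float(p)}
        p_adj = min(1.0, best["p_raw"] * len(thresholds))
        rows.append({"motif": motif.motif_id, **best, "p": p_adj})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "motif"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# MEME minimal format I/O (exact text round-trip)

def write_meme(path, motifs: list[MotifModel], background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format."""
    if background is None:
        background = motifs[0].background if motifs else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {} C {} G {} T {}\n".format(*(repr(float(x)) for x in background)))
        for m in motifs:
            fh.write(f"\nMOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_meme(path) -> list[MotifModel]:
    """Read a MEME minimal-format motif file.

    Parses the background-frequency line (uniform if absent) and every
    MOTIF block's letter-probability matrix at full printed precision.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    background = np.full(4, 0.25)
    motifs: list[MotifModel] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            fields = lines[i].split()
            freqs = {fields[j]: float(fields[j + 1])
                     for j in range(0, len(fields) - 1, 2)}
            background = np.array([freqs.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                i += 1
            header = lines[i].strip()
            match = re.search(r"w=\s*(\d+)", header)
            width = int(match.group(1))
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            motifs.append(MotifModel(motif_id, np.array(rows),
                                     background=background.copy()))
        i += 1
    return motifs
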