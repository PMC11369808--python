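"""PWM motif scanning with exact background p-values.

A PWM is an L x 4 matrix of log2-odds scores (columns A, C, G, T) relative
to a background base composition. Sequences are scanned on both strands with
a sliding log-odds sum; hit significance comes from the exact score
distribution of a random background L-mer, computed by dynamic programming
over an integer-rescaled score grid (exact for the rescaled scores, default
granularity 1e-3 bits).

The packaged default motif is the canonical 15-bp Oct4-Sox2 composite
element — the Sox HMG half-site (CTTTGTT) directly adjoining the POU
octamer (ATGCAAAT) — used to measure composite-motif incidence in peak
sequence sets. Any count matrix or IUPAC consensus can replace it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: canonical Oct4-Sox2 composite consensus (Sox HMG half-site + POU octamer)
OCT4_SOX2_CONSENSUS = "CTTTGTTATGCAAAT"


@dataclass
class PWM:
    """Log2-odds position weight matrix over A,C,G,T."""

    name: str
    matrix: np.ndarray  # L x 4, bits
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name + "_rc", self.matrix[::-1, ::-1], self.background[::-1])


def pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "pwm",
) -> PWM:
    """PWM from a base-count matrix: log2((count + pc)-normalized / background)."""
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("count matrix must be L x 4")
    if (counts < 0).any():
        raise ValueError("negative counts")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    col_sums = counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    if pseudocount == 0 and (counts.sum(axis=1) == 0).any():
        raise ValueError("zero count column with zero pseudocount")
    freqs = (counts + pseudocount) / col_sums
    with np.errstate(divide="ignore"):
        matrix = np.log2(freqs / bg)
    return PWM(name, matrix, bg)


def pwm_from_iupac(
    consensus: str,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    weight: float = 100.0,
    name: str | None = None,
) -> PWM:
    """PWM from an IUPAC consensus: each letter's base set shares ``weight``
    pseudo-observations uniformly, then the count rule applies (so an 'N'
    column scores 0 bits everywhere under a uniform background)."""
    consensus = consensus.upper()
    counts = np.zeros((len(consensus), 4))
    for i, letter in enumerate(consensus):
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r} at position {i}")
        allowed = IUPAC[letter]
        for b in allowed:
            counts[i, BASES.index(b)] = weight / len(allowed)
    return pwm_from_counts(counts, pseudocount, background, name or consensus)


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N -> 4; anything else is an error."""
    table = np.full(256, -1, np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("N")] = table[ord("n")] = 4
    codes = table[np.frombuffer(seq.encode(), np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)[:5]})
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return codes.astype(np.int64)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; N bases contribute 0 bits."""
    L = len(pwm)
    n_off = len(codes) - L + 1
    mat = np.hstack([pwm.matrix, np.zeros((L, 1))])  # 5th column: N -> 0
    scores = np.zeros(n_off)
    for i in range(L):
        scores += mat[i, codes[i : i + n_off]]
    return scores


def _window_scores_grid(pwm: PWM, codes: np.ndarray, granularity: float) -> np.ndarray:
    """Integer window scores on the DP grid (per-cell rounding, then sum),
    identical to the scoring the exact p-value distribution is built on."""
    L = len(pwm)
    n_off = len(codes) - L + 1
    int_mat = np.round(pwm.matrix / granularity).astype(np.int64)
    mat = np.hstack([int_mat, np.zeros((L, 1), np.int64)])
    scores = np.zeros(n_off, np.int64)
    for i in range(L):
        scores += mat[i, codes[i : i + n_off]]
    return scores


@dataclass
class ScoreDistribution:
    """Exact background score distribution on an integer grid.

    ``tail[k]`` = P(score >= (k + offset) * granularity) for a random
    background L-mer; exact for scores rounded to the grid.
    """

    granularity: float
    offset: int
    probs: np.ndarray
    tail: np.ndarray

    def pvalue(self, score: float) -> float:
        return self.pvalue_grid(int(round(score / self.granularity)))

    def pvalue_grid(self, grid_score: int) -> float:
        k = grid_score - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.tail):
            return 0.0
        return float(self.tail[k])

    def score_at_pvalue(self, p: float) -> float:
        """Smallest grid score s with P(score >= s) <= p."""
        k = int(np.searchsorted(-self.tail, -p, side="left"))
        return (k + self.offset) * self.granularity


def score_distribution(pwm: PWM, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact PWM score distribution under the background, by DP convolution
    of integer-rescaled per-column score distributions."""
    int_mat = np.round(pwm.matrix / granularity).astype(np.int64)
    lo = int(int_mat.min(axis=1).sum())
    hi = int(int_mat.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    probs[0] = 1.0  # relative to running minimum
    run_lo = 0
    for ints in int_mat:
        new_lo = run_lo + int(ints.min())
        new = np.zeros(hi - lo + 1)
        for b in range(4):
            shift = int(ints[b]) + run_lo - new_lo
            contrib = probs * pwm.background[b]
            new[shift : shift + len(probs)] += contrib[: len(new) - shift]
        probs = new
        run_lo = new_lo
    tail = np.cumsum(probs[::-1])[::-1]
    return ScoreDistribution(granularity, lo, probs, tail)


def scan_sequence(
    pwm: PWM,
    seq: str,
    score_threshold: float | None = None,
    pvalue_threshold: float | None = None,
    strands: str = "both",
    dist: ScoreDistribution | None = None,
    seq_id: str = "seq",
) -> pd.DataFrame:
    """Scan a sequence for PWM hits on one or both strands.

    Hits satisfy ``score >= score_threshold`` or ``p <= pvalue_threshold``
    (exactly one must be given). Offsets are 0-based positions of the
    leftmost matched base in the forward orientation of ``seq``.
    """
    if (score_threshold is None) == (pvalue_threshold is None):
        raise ValueError("give exactly one of score_threshold / pvalue_threshold")
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence shorter ({len(seq)}) than motif ({L})")
    if dist is None:
        dist = score_distribution(pwm)
    grid_cutoff = None
    if pvalue_threshold is not None:
        # compare on the DP grid so accepted hits have p <= threshold exactly
        score_threshold = dist.score_at_pvalue(pvalue_threshold)
        grid_cutoff = int(round(score_threshold / dist.granularity))

    codes = encode(seq)
    rows = []
    strand_list = {"both": "+-", "+": "+", "-": "-"}[strands]
    for strand in strand_list:
        p = pwm if strand == "+" else pwm.reverse_complement()
        scores = _window_scores(p, codes)
        if grid_cutoff is not None:
            grid_scores = _window_scores_grid(p, codes, dist.granularity)
            accepted = np.flatnonzero(grid_scores >= grid_cutoff)
            pvals = {int(o): dist.pvalue_grid(int(grid_scores[o])) for o in accepted}
        else:
            accepted = np.flatnonzero(scores >= score_threshold - 1e-12)
            pvals = {int(o): dist.pvalue(float(scores[o])) for o in accepted}
        for off in accepted:
            rows.append(
                dict(seq_id=seq_id, offset=int(off), strand=strand,
                     score=float(scores[off]), p=pvals[int(off)])
            )
    return pd.DataFrame(rows, columns=["seq_id", "offset", "strand", "score", "p"])


def motif_incidence(
    seqs: dict[str, str],
    pwm: PWM,
    pvalue_threshold: float = 1e-4,
    alpha: float = 0.05,
) -> dict:
    """Fraction of sequences with >= 1 motif hit, with a binomial (Wilson) CI."""
    if not seqs:
        raise ValueError("no sequences given")
    dist = score_distribution(pwm)
    n_hit = 0
    for sid, seq in seqs.items():
        hits = scan_sequence(pwm, seq, pvalue_threshold=pvalue_threshold, dist=dist, seq_id=sid)
        if len(hits):
            n_hit += 1
    frac = n_hit / len(seqs)
    lo, hi = proportion_confint(n_hit, len(seqs), alpha=alpha, method="wilson")
    return dict(n=len(seqs), n_with_hit=n_hit, fraction=frac,
                percent=100.0 * frac, ci_low=float(lo), ci_high=float(hi))


def hits_to_tss(
    hits: pd.DataFrame, peaks: pd.DataFrame, assoc: pd.DataFrame
) -> pd.DataFrame:
    """Map motif hits inside peaks to TSS-relative positions of the
    peak-associated gene.

    A hit at peak-internal offset ``o`` lies at genomic coordinate
    ``peak_start + o``; its TSS-relative position is ``coord − tss`` for a
    + strand gene and ``tss − coord`` for a − strand gene, so upstream is
    negative either way. Hits on unassociated peaks are dropped (count
    logged). ``assoc`` must carry ``peak_id, gene_id, tss, strand``.
    """
    genes = assoc[["peak_id", "gene_id", "tss", "strand"]].rename(
        columns={"strand": "gene_strand"}
    )
    merged = hits.merge(
        peaks[["peak_id", "start"]], left_on="seq_id", right_on="peak_id", how="left"
    ).merge(genes, on="peak_id", how="left")
    dropped = int(merged["gene_id"].isna().sum())
    if dropped:
        logger.info("dropped %d hits on unassociated peaks", dropped)
    merged = merged.dropna(subset=["gene_id"]).copy()
    coord = merged["start"] + merged["offset"]
    pos = np.where(merged["gene_strand"] == "-", merged["tss"] - coord, coord - merged["tss"])
    merged["tss_relative_position"] = pos.astype(np.int64)
    return merged[
        ["seq_id", "offset", "strand", "score", "p", "gene_id", "tss_relative_position"]
    ]


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence}."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
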