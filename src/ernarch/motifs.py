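"""Allele-level sequence effects at QTLs: TF motifs, Inr, and TATA-like.

Central tiQTLs are scored against TF position weight matrices (bits,
log2-odds against a background), comparing the higher- and lower-phenotype
alleles at the stronger allele's best match placement. diQTLs near an nTSS
are scored against the Initiator element (likelihood = e^score under a
natural-log PWM) and, 40-20 bp upstream, against a tiered TATA-like score
that tolerates A<->T inversions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PWMModel",
    "AlleleDelta",
    "VariantWindow",
    "read_meme",
    "scan_best_match",
    "score_at",
    "allele_delta_pwm",
    "inr_likelihood_delta",
    "tata_score",
    "tata_delta",
    "pwm_match_pvalue",
    "motif_disruption_enrichment",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STRONG_MATCH_BITS = 13.0  # bits; a "strong" PWM match
DISRUPTION_P = 0.01
DISRUPTION_MIN_BITS = 0.5
INR_DELTA_THRESHOLD = 5.0  # Inr likelihood difference filter
TATA_WINDOW = (-40, -20)  # strand-relative bp upstream of the nTSS


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMModel:
    """A TF binding motif as a log-odds scoring matrix.

    ``pfm`` is 4 x L (rows A, C, G, T; columns sum to 1). The log-odds
    matrix is log_base((pfm + pc*bg) / (1 + pc) / bg); base 2 gives scores
    in bits (TF motifs), base e feeds the Inr likelihood ``e^score``.
    """

    id: str
    pfm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError("pfm must have 4 rows (A, C, G, T)")
        if (self.pfm < 0).any():
            raise ValueError("pfm frequencies must be non-negative")
        col_sums = self.pfm.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-3):
            raise ValueError("pfm columns must sum to 1")
        self.pfm = self.pfm / col_sums
        adj = (self.pfm + self.pseudocount * self.background[:, None]) / (1 + self.pseudocount)
        self.logodds = np.log(adj / self.background[:, None]) / math.log(self.log_base)

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.logodds.argmax(axis=0))


@dataclass(frozen=True)
class AlleleDelta:
    """Score difference between high- and low-phenotype alleles for a motif."""

    qtl_id: str
    motif_id: str
    delta: float  # score_high - score_low
    score_high: float
    score_low: float
    position: int  # best-match offset of the stronger allele, forward coords
    strand: str


@dataclass(frozen=True)
class VariantWindow:
    """A biallelic variant in its sequence context.

    ``ref_window`` is the forward-strand sequence around the variant;
    ``offset`` is the 0-based position of the REF allele's first base in
    that window. ``high_is_alt`` says which allele carries the higher
    phenotype (stronger initiation for ti, stronger proximal-strand
    directionality for di).
    """

    qtl_id: str
    ref_window: str
    ref: str
    alt: str
    offset: int
    high_is_alt: bool = True

    def alt_window(self) -> str:
        w = self.ref_window
        if w[self.offset:self.offset + len(self.ref)].upper() != self.ref.upper():
            raise ValueError(
                f"{self.qtl_id}: window does not carry REF allele {self.ref!r} at {self.offset}")
        return w[:self.offset] + self.alt + w[self.offset + len(self.ref):]

    def windows_high_low(self) -> tuple[str, str]:
        ref_w, alt_w = self.ref_window, self.alt_window()
        return (alt_w, ref_w) if self.high_is_alt else (ref_w, alt_w)


def read_meme(path: str, pseudocount: float = 0.8, log_base: float = 2.0) -> list[PWMModel]:
    """Read position frequency matrices from a MEME (minimal) motif file."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        pfm = np.array([[m.counts[b][i] for i in range(m.length)] for b in _BASES], dtype=float)
        pfm = pfm / pfm.sum(axis=0)
        bg = np.array([m.background[b] for b in _BASES]) if m.background else np.full(4, 0.25)
        out.append(PWMModel(m.name or m.consensus, pfm, bg, pseudocount, log_base))
    return out


def score_at(sequence: str, pwm: PWMModel, position: int, strand: str = "+") -> float:
    """Log-odds score of the length-L word at ``position`` (forward coords).

    Returns -inf if the word contains non-ACGT bases or runs off the end.
    """
    L = pwm.length
    word = sequence[position:position + L].upper()
    if len(word) < L:
        return -math.inf
    if strand == "-":
        word = _revcomp(word)
    total = 0.0
    for j, base in enumerate(word):
        i = _BASE_INDEX.get(base)
        if i is None:
            return -math.inf
        total += pwm.logodds[i, j]
    return total


def scan_best_match(sequence: str, pwm: PWMModel,
                    both_strands: bool = True) -> tuple[float, int, str]:
    """Best log-odds match of a PWM over all placements (both strands).

    Placements containing ambiguous bases are skipped. Ties break to the
    forward strand, then to the leftmost position. Returns
    (-inf, -1, '+') when no placement is scorable.
    """
    seq = sequence.upper()
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < motif length {L}")
    best = (-math.inf, -1, "+")
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        for pos in range(len(seq) - L + 1):
            s = score_at(seq, pwm, pos, strand)
            if s > best[0]:
                best = (s, pos, strand)
    return best


def allele_delta_pwm(variant: VariantWindow, pwms: Sequence[PWMModel],
                     strong_threshold: float = STRONG_MATCH_BITS,
                     max_indel: int = 40) -> list[AlleleDelta]:
    """Per-motif score change between high- and low-phenotype alleles.

    For each PWM with a strong match (> ``strong_threshold``) in at least
    one allele, the stronger allele's best placement is fixed and both
    alleles are scored there; delta = score_high - score_low. Identical
    alleles give an empty list; indels longer than ``max_indel`` are
    skipped with a flag.
    """
    if variant.ref.upper() == variant.alt.upper():
        return []
    if max(len(variant.ref), len(variant.alt)) > max_indel:
        logger.warning("%s: indel longer than %d bp skipped", variant.qtl_id, max_indel)
        return []
    high_w, low_w = variant.windows_high_low()
    out: list[AlleleDelta] = []
    for pwm in pwms:
        s_high = scan_best_match(high_w, pwm)
        s_low = scan_best_match(low_w, pwm)
        if max(s_high[0], s_low[0]) <= strong_threshold:
            continue
        if s_high[0] >= s_low[0]:
            _, pos, strand = s_high
            score_high = s_high[0]
            score_low = score_at(low_w, pwm, pos, strand)
        else:
            _, pos, strand = s_low
            score_low = s_low[0]
            score_high = score_at(high_w, pwm, pos, strand)
        out.append(AlleleDelta(variant.qtl_id, pwm.id, score_high - score_low,
                               score_high, score_low, pos, strand))
    return out


def inr_likelihood_delta(tss_window_high: str, tss_window_low: str,
                         inr_pwm: PWMModel) -> float:
    """Initiator-likelihood difference between directionality alleles.

    Likelihood is the natural exponent of the best PWM score within the
    strand-oriented TSS window (the Inr overlaps the TSS on the nTSS
    strand, so only the forward orientation of the supplied window is
    scanned). delta = e^score_high - e^score_low; downstream analyses
    filter to |delta| > 5.
    """
    if min(len(tss_window_high), len(tss_window_low)) < inr_pwm.length:
        raise ValueError("TSS window shorter than the Inr motif")
    s_high, _, _ = scan_best_match(tss_window_high, inr_pwm, both_strands=False)
    s_low, _, _ = scan_best_match(tss_window_low, inr_pwm, both_strands=False)
    return math.exp(s_high) - math.exp(s_low)


def tata_score(four_mer: str) -> int:
    """Tiered TATA-like score of a 4-mer.

    4 for TATA itself; 2 for a single A<->T inversion (TTTA, TAAA, ...);
    1 for two inversions (e.g. TTAA); 0 for anything else, including any
    4-mer containing C or G (inversions are defined only within {A, T}).
    """
    if len(four_mer) != 4:
        raise ValueError(f"expected a 4-mer, got {four_mer!r}")
    s = four_mer.upper()
    if any(b not in "AT" for b in s):
        return 0
    mismatches = sum(a != b for a, b in zip(s, "TATA"))
    return {0: 4, 1: 2, 2: 1}.get(mismatches, 0)


def tata_delta(window_high: str, window_low: str) -> int:
    """TATA-like score change between directionality alleles.

    Each allele's score is the maximum tiered score over all 4-mer offsets
    in its (strand-relative, 40-20 bp upstream) window; delta = high - low.
    """
    if min(len(window_high), len(window_low)) < 4:
        raise ValueError("window shorter than 4 bp")

    def best(w: str) -> int:
        return max(tata_score(w[i:i + 4]) for i in range(len(w) - 3))

    return best(window_high) - best(window_low)


def pwm_match_pvalue(score: float, pwm: PWMModel, decimals: int = 9,
                     max_support: int = 500_000) -> float:
    """P(random background sequence of length L scores >= ``score``).

    Exact dynamic programming over the discretized score distribution:
    per-column log-odds are scaled to integers at ``decimals`` digits and
    convolved under the background base frequencies. If the support grows
    past ``max_support`` the discretization is automatically coarsened and
    the computation restarts. Ties at the threshold are counted as matches
    (within the discretization slack).
    """
    if score > pwm.max_score + 1e-9:
        return 0.0
    if score <= pwm.min_score + 1e-12:
        return 1.0
    L = pwm.length
    bg = pwm.background
    d = decimals
    while True:
        scale = 10.0**d
        cols = np.round(pwm.logodds * scale).astype(np.int64)
        dist: dict[int, float] = {0: 1.0}
        overflow = False
        for j in range(L):
            new: dict[int, float] = {}
            col = cols[:, j]
            for s, pr in dist.items():
                for b in range(4):
                    key = s + int(col[b])
                    new[key] = new.get(key, 0.0) + pr * bg[b]
            dist = new
            if len(dist) > max_support:
                overflow = True
                break
        if not overflow:
            break
        d -= 2
        if d < 1:
            raise RuntimeError("cannot discretize PWM score distribution")
    threshold = int(round(score * scale)) - L  # L integer units of rounding slack
    return float(sum(pr for s, pr in dist.items() if s >= threshold))


def motif_disruption_enrichment(qtl_variants: Sequence[VariantWindow],
                                background_variants: Sequence[VariantWindow],
                                pwms: Sequence[PWMModel],
                                p_thresh: float = DISRUPTION_P,
                                min_bits: float = DISRUPTION_MIN_BITS,
                                enrichment_fold: float = 1.2,
                                rng: np.random.Generator | None = None):
    """Per-motif disruption counts in QTLs vs background SNPs, with fold.

    A variant disrupts a motif when at least one allele has a significant
    match (match p < ``p_thresh``) and the alleles' best scores differ by
    at least ``min_bits``. Background SNPs should come from the same
    regions (+/-200 bp of tTRE midpoints). If the background is smaller
    than the QTL set it is resampled with replacement to match, with a
    warning. Motifs never matched in either set are skipped. Returns a
    DataFrame with per-motif counts, rates, fold and an ``enriched`` flag
    (fold > ``enrichment_fold``).
    """
    import pandas as pd

    if not qtl_variants:
        raise ValueError("empty QTL variant set")
    if len(background_variants) < len(qtl_variants):
        logger.warning("background (%d) smaller than QTL set (%d); resampling "
                       "with replacement", len(background_variants), len(qtl_variants))
        rng = np.random.default_rng() if rng is None else rng
        idx = rng.integers(0, len(background_variants), size=len(qtl_variants))
        background_variants = [background_variants[i] for i in idx]

    sig_score = {pwm.id: _score_threshold(pwm, p_thresh) for pwm in pwms}

    def disrupted_motifs(variants: Sequence[VariantWindow]) -> dict[str, int]:
        counts = {pwm.id: 0 for pwm in pwms}
        for v in variants:
            if v.ref.upper() == v.alt.upper():
                continue
            high_w, low_w = v.windows_high_low()
            for pwm in pwms:
                s1, _, _ = scan_best_match(high_w, pwm)
                s2, _, _ = scan_best_match(low_w, pwm)
                if max(s1, s2) >= sig_score[pwm.id] and abs(s1 - s2) >= min_bits:
                    counts[pwm.id] += 1
        return counts

    q_counts = disrupted_motifs(qtl_variants)
    b_counts = disrupted_motifs(background_variants)
    n_q, n_b = len(qtl_variants), len(background_variants)
    rows = []
    for pwm in pwms:
        qc, bc = q_counts[pwm.id], b_counts[pwm.id]
        if qc == 0 and bc == 0:
            continue
        q_rate, b_rate = qc / n_q, bc / n_b
        fold = q_rate / b_rate if b_rate > 0 else math.inf
        rows.append({"motif_id": pwm.id, "n_qtl": qc, "n_background": bc,
                     "qtl_rate": q_rate, "background_rate": b_rate,
                     "fold": fold, "enriched": fold > enrichment_fold})
    return pd.DataFrame(rows, columns=["motif_id", "n_qtl", "n_background",
                                       "qtl_rate", "background_rate", "fold", "enriched"])


def _score_threshold(pwm: PWMModel, p_thresh: float) -> float:
    """Smallest attainable score whose match p-value is below ``p_thresh``.

    Found by bisection on the monotone tail probability over the attainable
    score range.
    """
    lo, hi = pwm.min_score, pwm.max_score
    if pwm_match_pvalue(hi, pwm) >= p_thresh:
        return math.inf  # even a perfect match is not significant
    for _ in range(60):
        mid = (lo + hi) / 2
        if pwm_match_pvalue(mid, pwm) < p_thresh:
            hi = mid
        else:
            lo = mid
    return hi
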