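"""Calling transcribed regulatory elements from stranded 5'-count tracks.

A transcribed transcriptional regulatory element (tTRE) is a pair of
divergent nascent transcription start sites (nTSSs): a minus-strand
initiation peak lying upstream (left) of a plus-strand peak, within 300 bp.
Peaks are called on the aggregate signal summed across individuals, merged
within a same-strand window, then greedily paired by ascending gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotatedTSS, StrandedSignal

__all__ = [
    "NTSS",
    "TTRE",
    "call_ntss",
    "pair_bidirectional",
    "classify_by_annotation",
    "classify_by_stability",
    "evaluate_roc",
    "ttre_window_counts",
    "assign_dominant_strand",
    "filter_masked",
]

MAX_PAIR_GAP = 300  # bp between divergent nTSSs
PLUS_WINDOW = (1, 250)  # midpoint-relative offsets, inclusive
MINUS_WINDOW = (-250, 0)


@dataclass(frozen=True)
class NTSS:
    """One strand's initiation peak: summit base plus merged aggregate count."""

    contig: str
    position: int
    strand: str
    count: int


@dataclass
class TTRE:
    """A divergent nTSS pair; midpoint halves the inter-summit span."""

    contig: str
    minus_position: int
    plus_position: int
    id: str = ""
    klass: str = "unclassified"
    dominant_strand: str | None = None

    def __post_init__(self) -> None:
        if self.minus_position >= self.plus_position:
            raise ValueError("tTRE requires minus nTSS strictly left of plus nTSS")
        if self.width > MAX_PAIR_GAP:
            raise ValueError(f"tTRE width {self.width} exceeds {MAX_PAIR_GAP} bp")

    @property
    def midpoint(self) -> int:
        return (self.minus_position + self.plus_position) // 2

    @property
    def width(self) -> int:
        return self.plus_position - self.minus_position


def call_ntss(signal: StrandedSignal, min_count: int, merge_window: int = 60) -> list[NTSS]:
    """Call nascent TSS peaks per strand from an aggregate count track.

    Bases with count >= ``min_count`` are candidates; same-strand candidates
    chained within ``merge_window`` bp collapse to the maximum-count base
    (leftmost on ties), carrying the summed count of the cluster. Returned
    sorted by position within each strand.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out: list[NTSS] = []
    for strand in ("+", "-"):
        track = signal.strand(strand)
        cand = sorted(p for p, c in track.items() if c >= min_count)
        cluster: list[int] = []
        for pos in cand:
            if cluster and pos - cluster[-1] > merge_window:
                out.append(_summit(signal.contig, strand, cluster, track))
                cluster = []
            cluster.append(pos)
        if cluster:
            out.append(_summit(signal.contig, strand, cluster, track))
    out.sort(key=lambda n: (n.position, n.strand))
    return out


def _summit(contig: str, strand: str, cluster: list[int], track: dict[int, int]) -> NTSS:
    best = max(cluster, key=lambda p: (track[p], -p))
    return NTSS(contig, best, strand, sum(track[p] for p in cluster))


def pair_bidirectional(ntss_list: Sequence[NTSS], max_gap: int = MAX_PAIR_GAP) -> list[TTRE]:
    """Pair minus-strand nTSSs with plus-strand nTSSs strictly downstream.

    Only the divergent geometry (minus left of plus, gap <= ``max_gap``)
    forms an element. Pairing is greedy by ascending gap with leftmost
    tie-break, and each nTSS joins at most one element; unpaired nTSSs are
    discarded.
    """
    minus = [n for n in ntss_list if n.strand == "-"]
    plus = [n for n in ntss_list if n.strand == "+"]
    candidates = []
    for m in minus:
        for p in plus:
            gap = p.position - m.position
            if 0 < gap <= max_gap:
                candidates.append((gap, m.position, p.position, m, p))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_minus: set[int] = set()
    used_plus: set[int] = set()
    ttres: list[TTRE] = []
    for gap, _, _, m, p in candidates:
        if m.position in used_minus or p.position in used_plus:
            continue
        used_minus.add(m.position)
        used_plus.add(p.position)
        ttres.append(TTRE(m.contig, m.position, p.position))
    ttres.sort(key=lambda t: (t.contig, t.minus_position))
    for i, t in enumerate(ttres):
        t.id = f"ttre_{i:05d}"
    return ttres


def classify_by_annotation(ttres: Sequence[TTRE], annotated_tss: Sequence[AnnotatedTSS],
                           promoter_dist: int = 500, enhancer_dist: int = 2000) -> list[str]:
    """Label tTREs by distance from either nTSS to the nearest annotated TSS.

    Promoter if the minimum distance is <= ``promoter_dist``; distal enhancer
    if > ``enhancer_dist``; in between stays unclassified.
    """
    if not annotated_tss:
        raise ValueError("annotated TSS list is empty")
    by_contig: dict[str, np.ndarray] = {}
    for a in annotated_tss:
        by_contig.setdefault(a.contig, []).append(a.position)  # type: ignore[arg-type]
    by_contig = {c: np.sort(np.array(v)) for c, v in by_contig.items()}
    labels = []
    for t in ttres:
        positions = by_contig.get(t.contig)
        if positions is None:
            labels.append("enhancer")
            continue
        d = min(_nearest_distance(positions, t.minus_position),
                _nearest_distance(positions, t.plus_position))
        if d <= promoter_dist:
            labels.append("promoter")
        elif d > enhancer_dist:
            labels.append("enhancer")
        else:
            labels.append("unclassified")
    for t, lab in zip(ttres, labels):
        t.klass = lab
    return labels


def _nearest_distance(sorted_positions: np.ndarray, pos: int) -> int:
    i = np.searchsorted(sorted_positions, pos)
    best = np.inf
    if i < len(sorted_positions):
        best = min(best, abs(int(sorted_positions[i]) - pos))
    if i > 0:
        best = min(best, abs(int(sorted_positions[i - 1]) - pos))
    return int(best)


def classify_by_stability(ttres: Sequence[TTRE], stability_signal: StrandedSignal,
                          annotated_tss: Sequence[AnnotatedTSS], fdr: float = 0.1,
                          flank: int = 5, background_dist: int = 1000) -> list[str]:
    """Label tTREs promoter/enhancer by stable-RNA (CAGE-like) signal.

    Stable capped RNA marks promoters; eRNAs are degraded and leave little.
    Per-nTSS stability counts (summit +/- ``flank`` on the nTSS strand,
    depth-normalized) are compared with an empirical background built from
    nTSSs at least ``background_dist`` bp from any annotated TSS; the
    empirical p-value (#{background >= observed} + 1) / (B + 1) is controlled
    by Benjamini-Hochberg at ``fdr``. A tTRE with either nTSS significant is
    a promoter, otherwise an enhancer.
    """
    from .qtl import bh_fdr

    total = stability_signal.total()
    scale = 1e6 / total if total > 0 else 1.0
    by_contig: dict[str, list[int]] = {}
    for a in annotated_tss:
        by_contig.setdefault(a.contig, []).append(a.position)
    sorted_by_contig = {c: np.sort(np.array(v)) for c, v in by_contig.items()}

    ntss: list[tuple[int, int, str]] = []  # (ttre index, position, strand)
    for i, t in enumerate(ttres):
        ntss.append((i, t.minus_position, "-"))
        ntss.append((i, t.plus_position, "+"))

    def rpm(pos: int, strand: str) -> float:
        return scale * stability_signal.window_count(pos - flank, pos + flank + 1, strand)

    background = []
    for _, pos, strand in ntss:
        positions = sorted_by_contig.get(stability_signal.contig)
        d = _nearest_distance(positions, pos) if positions is not None and len(positions) else np.inf
        if d >= background_dist:
            background.append(rpm(pos, strand))
    if not background:
        raise ValueError("no background nTSSs >= background_dist from annotation")
    bg = np.sort(np.array(background))
    B = len(bg)

    pvals = np.empty(len(ntss))
    for j, (_, pos, strand) in enumerate(ntss):
        obs = rpm(pos, strand)
        n_ge = B - np.searchsorted(bg, obs, side="left")
        pvals[j] = (n_ge + 1) / (B + 1)
    qvals = bh_fdr(pvals)
    significant = qvals < fdr
    labels = ["enhancer"] * len(ttres)
    for (i, _, _), sig in zip(ntss, significant):
        if sig:
            labels[i] = "promoter"
    for t, lab in zip(ttres, labels):
        t.klass = lab
    return labels


def evaluate_roc(region_scores: Mapping[str, float], positive_regions: set[str],
                 background_regions: set[str]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of a region score against positive and background region sets.

    Sweeps the score threshold over the pooled regions; returns (FPR, TPR)
    curves and the trapezoid AUC. With tied scores the curve moves
    diagonally, so the AUC equals the Mann-Whitney U statistic divided by
    n_pos * n_bg.
    """
    if not positive_regions:
        raise ValueError("positive region set is empty")
    if not background_regions:
        raise ValueError("background region set is empty")
    if positive_regions & background_regions:
        raise ValueError("positive and background sets must be disjoint")
    pos_scores = np.array([region_scores[r] for r in sorted(positive_regions)])
    bg_scores = np.array([region_scores[r] for r in sorted(background_regions)])
    thresholds = np.unique(np.concatenate([pos_scores, bg_scores]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        tpr.append(float((pos_scores >= th).mean()))
        fpr.append(float((bg_scores >= th).mean()))
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return fpr_arr, tpr_arr, auc


def ttre_window_counts(ttres: Sequence[TTRE], signals: Mapping[str, StrandedSignal]
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual read counts in the fixed strand windows of each tTRE.

    The plus window covers midpoint-relative offsets [1, 250] and the minus
    window [-250, 0]; windows are class-independent. Returns (plus, minus)
    DataFrames indexed by tTRE id with one column per individual.
    """
    samples = list(signals)
    plus = np.zeros((len(ttres), len(samples)), dtype=float)
    minus = np.zeros_like(plus)
    for i, t in enumerate(ttres):
        mid = t.midpoint
        for j, s in enumerate(samples):
            sig = signals[s]
            plus[i, j] = sig.window_count(mid + PLUS_WINDOW[0], mid + PLUS_WINDOW[1] + 1, "+")
            minus[i, j] = sig.window_count(mid + MINUS_WINDOW[0], mid + MINUS_WINDOW[1] + 1, "-")
    idx = [t.id for t in ttres]
    return (pd.DataFrame(plus, index=idx, columns=samples),
            pd.DataFrame(minus, index=idx, columns=samples))


def assign_dominant_strand(ttres: Sequence[TTRE], plus_counts: pd.DataFrame,
                           minus_counts: pd.DataFrame) -> None:
    """Mark each tTRE's dominant strand (higher window count over individuals).

    Used to orient promoters dominant-strand-downstream in positional plots;
    plus wins ties.
    """
    p = plus_counts.sum(axis=1)
    m = minus_counts.sum(axis=1)
    for t in ttres:
        t.dominant_strand = "+" if p.loc[t.id] >= m.loc[t.id] else "-"


def filter_masked(ttres: Sequence[TTRE], mask: pd.DataFrame, margin: int = 0) -> list[TTRE]:
    """Drop tTREs whose span (plus margin) overlaps any mask interval."""
    if mask.empty:
        return list(ttres)
    kept = []
    for t in ttres:
        sub = mask[mask["contig"] == t.contig]
        lo, hi = t.minus_position - margin, t.plus_position + 1 + margin
        if not ((sub["start"] < hi) & (sub["end"] > lo)).any():
            kept.append(t)
    return kept
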