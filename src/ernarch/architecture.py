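"""Positional and regional analyses of the bipartite enhancer model.

Enhancers carry a central transcription-factor-binding footprint flanked by
two core initiation regions around the nascent TSSs. These analyses test
where QTLs sit relative to that geometry: density profiles around element
midpoints with a resampled-background confidence band, a five-way partition
of the +/-2 kb window (center / core / NCNC / out / far-out), Fisher
enrichment of region frequencies and set overlaps, quantile-quantile
comparison of expression-association p-values, and tTRE-gene co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import TTRE

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentProfile",
    "positional_enrichment",
    "classify_region",
    "assign_regions",
    "regional_frequency_test",
    "overlap_enrichment",
    "qq_compare",
    "ttre_gene_correlation",
]

PROFILE_WINDOW = 2_000  # bp either side of the midpoint
CENTER_HALFWIDTH = 25  # bp from midpoint: central TF-binding footprint
CORE_HALFWIDTH = 25  # bp from each nTSS: initiation core
OUT_MARGIN = 200  # bp past the outermost nTSS before far-out begins
REGIONS = ("center", "core", "NCNC", "out", "far_out")


@dataclass
class EnrichmentProfile:
    """QTL counts per midpoint-relative bin with a resampled background band."""

    bin_edges: np.ndarray
    observed: np.ndarray
    background_mean: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_qtls: int
    n_resample: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def peak_offset(self) -> float:
        """Center of the bin with the largest excess over background."""
        excess = self.observed - self.background_mean
        return float(self.bin_centers[int(np.argmax(excess))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.bin_centers, "observed": self.observed,
            "background_mean": self.background_mean,
            "band_low": self.band_low, "band_high": self.band_high,
        })


def _offsets_to_midpoints(positions: Sequence[tuple[str, int]], ttres: Sequence[TTRE],
                          window: int = PROFILE_WINDOW, orient: str = "none") -> np.ndarray:
    """Midpoint-relative offset of each position to its nearest tTRE.

    Positions farther than ``window`` from every midpoint are dropped. With
    ``orient='dominant'`` offsets flip sign at minus-dominant elements so the
    dominant strand points downstream (positive) — the promoter convention.
    """
    by_contig: dict[str, list[TTRE]] = {}
    for t in ttres:
        by_contig.setdefault(t.contig, []).append(t)
    mid_by_contig = {c: (np.array([t.midpoint for t in ts]), ts)
                     for c, ts in by_contig.items()}
    offsets = []
    for contig, pos in positions:
        if contig not in mid_by_contig:
            continue
        mids, ts = mid_by_contig[contig]
        i = int(np.argmin(np.abs(mids - pos)))
        off = pos - int(mids[i])
        if abs(off) > window:
            continue
        if orient == "dominant" and ts[i].dominant_strand == "-":
            off = -off
        offsets.append(off)
    return np.array(offsets, dtype=int)


def positional_enrichment(qtl_positions: Sequence[tuple[str, int]], ttres: Sequence[TTRE],
                          all_snp_positions: Sequence[tuple[str, int]],
                          n_resample: int = 10_000, bin: int = 10,
                          window: int = PROFILE_WINDOW, orient: str = "none",
                          rng: np.random.Generator | None = None) -> EnrichmentProfile:
    """QTL density around tTRE midpoints against a resampled SNP background.

    Observed counts per offset bin are compared with ``n_resample`` draws of
    the same number of positions from all SNPs in the same +/-``window``
    regions; the 0.5% and 99.5% per-bin quantiles form a 99% band. If the
    background pool is smaller than the QTL set, sampling falls back to
    with-replacement with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    q_off = _offsets_to_midpoints(qtl_positions, ttres, window, orient)
    bg_off = _offsets_to_midpoints(all_snp_positions, ttres, window, orient)
    edges = np.arange(-window, window + bin, bin)
    observed, _ = np.histogram(q_off, bins=edges)
    n_q = len(q_off)
    replace = len(bg_off) < n_q
    if replace:
        logger.warning("background pool (%d) smaller than QTL set (%d); "
                       "sampling with replacement", len(bg_off), n_q)
    counts = np.empty((n_resample, len(edges) - 1))
    for r in range(n_resample):
        draw = rng.choice(bg_off, size=n_q, replace=replace)
        counts[r], _ = np.histogram(draw, bins=edges)
    return EnrichmentProfile(
        bin_edges=edges, observed=observed.astype(float),
        background_mean=counts.mean(axis=0),
        band_low=np.quantile(counts, 0.005, axis=0),
        band_high=np.quantile(counts, 0.995, axis=0),
        n_qtls=n_q, n_resample=n_resample,
    )


def classify_region(offset: int, ttre: TTRE, center_halfwidth: int = CENTER_HALFWIDTH,
                    core_halfwidth: int = CORE_HALFWIDTH, out_margin: int = OUT_MARGIN,
                    window: int = PROFILE_WINDOW) -> str:
    """Assign a midpoint-relative offset to one of the five element regions.

    Precedence center > core > NCNC > out > far_out, so narrow elements
    where a core overlaps the center resolve to center. NCNC is the space
    between center and cores inside the element; out extends ``out_margin``
    bp past the outermost nTSS; everything beyond (to +/-``window``) is
    far_out.
    """
    if abs(offset) > window:
        raise ValueError(f"offset {offset} outside the +/-{window} bp window")
    minus_off = ttre.minus_position - ttre.midpoint
    plus_off = ttre.plus_position - ttre.midpoint
    if abs(offset) <= center_halfwidth:
        return "center"
    if abs(offset - minus_off) <= core_halfwidth or abs(offset - plus_off) <= core_halfwidth:
        return "core"
    if minus_off < offset < plus_off:
        return "NCNC"
    if minus_off - out_margin <= offset <= plus_off + out_margin:
        return "out"
    return "far_out"


def assign_regions(positions: Sequence[tuple[str, int]], ttres: Sequence[TTRE],
                   window: int = PROFILE_WINDOW, **kwargs) -> pd.DataFrame:
    """Region label of each position relative to its nearest tTRE.

    Positions beyond ``window`` of every midpoint are dropped; each kept SNP
    receives exactly one label.
    """
    by_contig: dict[str, list[TTRE]] = {}
    for t in ttres:
        by_contig.setdefault(t.contig, []).append(t)
    mid_by_contig = {c: (np.array([t.midpoint for t in ts]), ts)
                     for c, ts in by_contig.items()}
    rows = []
    for contig, pos in positions:
        if contig not in mid_by_contig:
            continue
        mids, ts = mid_by_contig[contig]
        i = int(np.argmin(np.abs(mids - pos)))
        off = pos - int(mids[i])
        if abs(off) > window:
            continue
        rows.append({"contig": contig, "position": pos, "ttre_id": ts[i].id,
                     "offset": off,
                     "region": classify_region(off, ts[i], window=window, **kwargs)})
    return pd.DataFrame(rows, columns=["contig", "position", "ttre_id", "offset", "region"])


def regional_frequency_test(snp_positions: Sequence[tuple[str, int]],
                            qtl_positions: Sequence[tuple[str, int]],
                            ttres: Sequence[TTRE], **kwargs) -> pd.DataFrame:
    """QTL frequency per element region, each tested against far-out.

    Frequency = QTL count / SNP count in the region. Every non-far-out
    region is compared with far_out in a two-sided Fisher's exact test on
    the (QTL, non-QTL) x (region, far_out) table. Regions with zero QTLs
    everywhere are reported with the test skipped (p = NaN).
    """
    snp_df = assign_regions(snp_positions, ttres, **kwargs)
    qtl_set = {(c, p) for c, p in qtl_positions}
    snp_df["is_qtl"] = [(c, p) in qtl_set
                        for c, p in zip(snp_df["contig"], snp_df["position"])]
    counts = snp_df.groupby("region")["is_qtl"].agg(["sum", "count"])
    counts = counts.reindex(REGIONS, fill_value=0)
    if counts.loc["far_out", "count"] == 0:
        raise ValueError("far_out region contains no SNPs; no baseline to test against")
    fo_q = int(counts.loc["far_out", "sum"])
    fo_n = int(counts.loc["far_out", "count"])
    any_qtl = counts["sum"].sum() > 0
    rows = []
    for region in REGIONS:
        n_q = int(counts.loc[region, "sum"])
        n_s = int(counts.loc[region, "count"])
        freq = n_q / n_s if n_s else np.nan
        if region == "far_out" or n_s == 0 or not any_qtl:
            odds, p = np.nan, np.nan
        else:
            table = [[n_q, n_s - n_q], [fo_q, fo_n - fo_q]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"region": region, "n_snps": n_s, "n_qtls": n_q,
                     "frequency": freq, "odds_ratio": odds, "fisher_p": p})
    return pd.DataFrame(rows)


def overlap_enrichment(qtl_elements: set, annotation_elements: set,
                       background_elements: set) -> tuple[float, float]:
    """Fold enrichment of annotation overlap in a QTL element set.

    fold = (overlap rate among QTL elements) / (overlap rate among
    background elements); p from a two-sided Fisher's exact test on the
    2x2 overlap table.
    """
    if not background_elements:
        raise ValueError("background element set is empty")
    if not qtl_elements:
        raise ValueError("QTL element set is empty")
    q_in = len(qtl_elements & annotation_elements)
    b_in = len(background_elements & annotation_elements)
    q_rate = q_in / len(qtl_elements)
    b_rate = b_in / len(background_elements)
    if q_rate == 0:
        fold = 0.0
    elif b_rate == 0:
        fold = np.inf
    else:
        fold = q_rate / b_rate
    table = [[q_in, len(qtl_elements) - q_in],
             [b_in, len(background_elements) - b_in]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(fold), float(p)


def qq_compare(p_subset, p_all) -> tuple[pd.DataFrame, float, float]:
    """-log10 quantile-quantile points and a two-sided KS test.

    Compares the p-value distribution of a SNP subset (e.g., tiQTLs tested
    for expression association) with the all-SNP distribution. Returns the
    QQ frame (expected vs observed -log10 p at matched quantiles), the KS
    D statistic, and its two-sided p-value.
    """
    ps = np.sort(np.asarray(p_subset, dtype=float))
    pa = np.sort(np.asarray(p_all, dtype=float))
    if ps.size == 0 or pa.size == 0:
        raise ValueError("both p-value samples must be nonempty")
    probs = (np.arange(1, ps.size + 1) - 0.5) / ps.size
    ref = np.quantile(pa, probs)
    tiny = np.finfo(float).tiny
    qq = pd.DataFrame({
        "expected_neglog10": -np.log10(np.maximum(ref, tiny)),
        "observed_neglog10": -np.log10(np.maximum(ps, tiny)),
    })
    if ps.size == pa.size and np.array_equal(ps, pa):
        return qq, 0.0, 1.0  # identical samples
    res = stats.ks_2samp(ps, pa, alternative="two-sided")
    return qq, float(res.statistic), float(res.pvalue)


def ttre_gene_correlation(ttre_phenotypes: pd.DataFrame, expression: pd.DataFrame,
                          ttre_positions: pd.DataFrame, gene_tss: pd.DataFrame,
                          pairs_within: int = 1_000_000) -> pd.DataFrame:
    """Pearson co-expression of tTRE initiation with nearby gene expression.

    All (tTRE, gene) pairs with midpoint within ``pairs_within`` bp of the
    gene TSS are tested across matched individual columns. Distance is
    signed relative to the gene's strand: upstream of the TSS is negative.
    """
    common = [c for c in ttre_phenotypes.columns if c in expression.columns]
    if len(common) < 3:
        raise ValueError("need >= 3 matched individuals for correlation")
    rows = []
    for gid in expression.index:
        if gid not in gene_tss.index:
            continue
        g_contig = gene_tss.loc[gid, "contig"]
        g_pos = int(gene_tss.loc[gid, "position"])
        g_strand = gene_tss.loc[gid, "strand"]
        expr = expression.loc[gid, common].to_numpy(dtype=float)
        for tid in ttre_phenotypes.index:
            if tid not in ttre_positions.index:
                continue
            if ttre_positions.loc[tid, "contig"] != g_contig:
                continue
            mid = int(ttre_positions.loc[tid, "position"])
            dist = mid - g_pos
            if abs(dist) > pairs_within:
                continue
            if g_strand == "-":
                dist = -dist
            phen = ttre_phenotypes.loc[tid, common].to_numpy(dtype=float)
            if np.ptp(phen) == 0 or np.ptp(expr) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(phen, expr)[0, 1])
            rows.append({"ttre_id": tid, "gene_id": gid, "r": r, "distance": dist})
    return pd.DataFrame(rows, columns=["ttre_id", "gene_id", "r", "distance"])
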