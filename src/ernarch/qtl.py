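"""Cis-QTL mapping between genotype dosages and tTRE/gene phenotypes.

Associations are ordinary least squares of the phenotype on alt-allele
dosage with principal-component covariates, equivalent by Frisch-Waugh to
a simple regression after residualizing both sides on the covariates; the
dosage t statistic is referred to a t distribution with n - k - 2 degrees
of freedom (k covariates, intercept, dosage). Multiple testing is
controlled by Benjamini-Hochberg over all variant-element pairs tested in
a run, and a staggered-window local-minimum filter thins significant hits
to likely-primary SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSet",
    "compute_pcs",
    "cis_association",
    "map_cis_qtls",
    "bh_fdr",
    "local_min_filter",
    "scan_pc_count",
]

CIS_WINDOW_TTRE = 2_000  # bp from the tTRE midpoint, initiation phenotypes
CIS_WINDOW_EXPRESSION = 200_000  # bp from the gene TSS, expression phenotype


@dataclass
class CovariateSet:
    """Orthonormal principal-component covariates, individuals x k."""

    components: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(self.components.shape[1]), atol=1e-8):
            raise ValueError("covariate columns must be orthonormal")

    @property
    def k(self) -> int:
        return self.components.shape[1]


def compute_pcs(phenotypes: pd.DataFrame, k: int) -> CovariateSet:
    """Top-k principal components of individuals in phenotype space.

    Rows of ``phenotypes`` are elements, columns individuals. Each element
    (row) is centered across individuals and the left singular vectors of
    the individuals x elements matrix are returned, with a deterministic
    sign convention (the largest-magnitude entry of each component is
    positive).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = phenotypes.shape[1]
    if k >= n:
        raise ValueError(f"k = {k} must be < number of individuals ({n})")
    x = phenotypes.to_numpy(dtype=float).T  # individuals x elements
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    u, s = u[:, :k], s[:k]
    for j in range(k):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    var = s**2
    total = (x**2).sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return CovariateSet(u, ratio)


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project out the intercept and covariate columns."""
    out = y - y.mean(axis=0, keepdims=True) if y.ndim > 1 else y - y.mean()
    if covariates is not None and covariates.size:
        c = covariates - covariates.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(c)
        out = out - q @ (q.T @ out)
    return out


def cis_association(dosage: np.ndarray, phenotype: np.ndarray,
                    covariates: np.ndarray | None = None) -> tuple[float, float, float, float]:
    """OLS effect of dosage on phenotype with covariates: (beta, se, t, p).

    Two-sided p from the t distribution with n - k - 2 degrees of freedom.
    Constant dosage is an error (callers skip those variants).
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = len(d)
    k = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 observations (n={n}, k={k})")
    if np.ptp(d) == 0:
        raise ValueError("constant dosage vector")
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    dres = _residualize(d, cov)
    yres = _residualize(y, cov)
    sxx = float(dres @ dres)
    beta = float(dres @ yres) / sxx
    df = n - k - 2
    rss = float(yres @ yres) - beta**2 * sxx
    rss = max(rss, 0.0)
    se = np.sqrt(rss / df / sxx) if df > 0 else np.nan
    if se == 0:
        t = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2 * stats.t.sf(abs(t), df)
    return beta, float(se), float(t), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone non-decreasing in p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def map_cis_qtls(genotypes: GenotypeTable, phenotypes: pd.DataFrame,
                 element_positions: pd.DataFrame, qtl_type: str = "ti",
                 window: int | None = None, fdr: float | None = None,
                 covariates: CovariateSet | np.ndarray | None = None) -> pd.DataFrame:
    """Test all variant-element pairs within the cis window; BH across the run.

    ``element_positions`` indexes element ids to (contig, position) — tTRE
    midpoints for initiation phenotypes, gene TSSs for expression. Default
    windows/FDR follow the phenotype type: 2 kb / 0.1 for ti and di, 200 kb
    / 0.05 for e. Missing dosages are mean-imputed; constant-dosage variants
    are skipped with a log flag.
    """
    if qtl_type not in ("ti", "di", "e"):
        raise ValueError(f"qtl_type must be ti, di or e, got {qtl_type!r}")
    if window is None:
        window = CIS_WINDOW_EXPRESSION if qtl_type == "e" else CIS_WINDOW_TTRE
    if fdr is None:
        fdr = 0.05 if qtl_type == "e" else 0.1
    cov = covariates.components if isinstance(covariates, CovariateSet) else covariates
    if list(phenotypes.columns) != list(genotypes.samples):
        phenotypes = phenotypes[list(genotypes.samples)]
    dosages = genotypes.imputed_dosages()

    var_pos = np.array([v.position for v in genotypes.variants])
    var_contig = np.array([v.contig for v in genotypes.variants])
    order = np.lexsort((var_pos, var_contig))

    records: list[dict] = []
    n_skipped = 0
    for eid in phenotypes.index:
        if eid not in element_positions.index:
            continue
        e_contig = element_positions.loc[eid, "contig"]
        e_pos = int(element_positions.loc[eid, "position"])
        y = phenotypes.loc[eid].to_numpy(dtype=float)
        in_contig = order[var_contig[order] == e_contig]
        if in_contig.size == 0:
            continue
        pos_sorted = var_pos[in_contig]
        lo = np.searchsorted(pos_sorted, e_pos - window, side="left")
        hi = np.searchsorted(pos_sorted, e_pos + window, side="right")
        for vi in in_contig[lo:hi]:
            d = dosages[vi]
            if np.ptp(d) == 0:
                n_skipped += 1
                continue
            beta, se, t, p = cis_association(d, y, cov)
            v = genotypes.variants[vi]
            records.append({
                "variant_id": v.id, "element_id": eid, "type": qtl_type,
                "contig": v.contig, "position": v.position,
                "cis_distance": v.position - e_pos,
                "beta": beta, "t": t, "p": p,
            })
    if n_skipped:
        logger.info("skipped %d constant-dosage variant tests", n_skipped)
    if not records:
        logger.warning("no variant-element pairs within the %d bp cis window", window)
        return pd.DataFrame(columns=["variant_id", "element_id", "type", "contig",
                                     "position", "cis_distance", "beta", "t", "p",
                                     "q", "significant"])
    df = pd.DataFrame.from_records(records)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < fdr
    return df


def local_min_filter(records: pd.DataFrame, window: int = 5_000,
                     stagger: int = 1_000) -> pd.DataFrame:
    """Thin SNPs to likely-primary hits via staggered-window local p minima.

    The genome is tiled with ``window``-bp windows staggered by ``stagger``
    bp, so each SNP lies in window/stagger windows. A SNP survives iff it is
    the strict p-value minimum in at least one of its windows (per-SNP best
    p across elements is what competes); exact ties at a window minimum
    eliminate all tied SNPs from that window. Rows of surviving SNPs are
    returned.
    """
    if records.empty:
        return records.copy()
    best = records.groupby(["contig", "position"], sort=False)["p"].min().reset_index()
    survivors: set[tuple[str, int]] = set()
    for contig, sub in best.groupby("contig"):
        pos = sub["position"].to_numpy()
        p = sub["p"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos, p = pos[order], p[order]
        starts = set()
        for x in pos:
            first = (int(x) - window + stagger) // stagger  # floor for the leftmost window
            for k in range(first, int(x) // stagger + 1):
                starts.add(k * stagger)
        for start in starts:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + window, side="left")
            if lo == hi:
                continue
            pwin = p[lo:hi]
            pmin = pwin.min()
            idx = np.flatnonzero(pwin == pmin)
            if idx.size == 1:
                survivors.add((contig, int(pos[lo + idx[0]])))
    keep = records.apply(lambda r: (r["contig"], int(r["position"])) in survivors, axis=1)
    return records[keep].copy()


def scan_pc_count(genotypes: GenotypeTable, phenotypes: pd.DataFrame,
                  element_positions: pd.DataFrame, qtl_type: str = "ti",
                  k_max: int = 20, window: int | None = None,
                  fdr: float | None = None) -> tuple[int, dict[int, int]]:
    """Choose the PC count maximizing significant discoveries (k = 0..k_max)."""
    counts: dict[int, int] = {}
    best_k, best_n = 0, -1
    for k in range(0, min(k_max, phenotypes.shape[1] - 1) + 1):
        cov = compute_pcs(phenotypes, k) if k > 0 else None
        df = map_cis_qtls(genotypes, phenotypes, element_positions, qtl_type,
                          window=window, fdr=fdr, covariates=cov)
        n_sig = int(df["significant"].sum()) if not df.empty else 0
        counts[k] = n_sig
        if n_sig > best_n:
            best_k, best_n = k, n_sig
    return best_k, counts
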