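"""Variably expressed elements: replicate-vs-sample dispersion testing.

A tTRE is variably expressed when its initiation level differs more between
individuals than between replicate cultures of the same individual. Each
tTRE gets a one-sided rank-sum p-value comparing absolute deviations from
the mean across samples against those within replicate pairs; the uniform
tail of the p-value distribution estimates the non-variable fraction pi0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["ReplicatePairing", "variable_expression_test", "estimate_variable_fraction"]


@dataclass(frozen=True)
class ReplicatePairing:
    """Column pairs (sample column, replicate column) of the phenotype matrix."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"replicate pair references the same column {a!r}")

    @property
    def replicate_columns(self) -> list[str]:
        return [b for _, b in self.pairs]


def variable_expression_test(phenotypes: pd.DataFrame, pairing: ReplicatePairing) -> pd.Series:
    """Per-tTRE p-value that between-sample spread exceeds replicate spread.

    Within each replicate pair, the absolute deviation from the pair mean
    measures technical/culture noise; across distinct samples (replicate
    columns excluded), the absolute deviation from the sample mean measures
    biological spread. A one-sided Wilcoxon rank-sum test asks whether the
    between-sample deviations are greater.

    Two adjustments keep the null calibrated: a pair's two deviations are
    identical in magnitude, so each pair contributes one value (|a - b| / 2);
    and a deviation from a g-member mean has standard deviation
    sigma * sqrt(1 - 1/g), so both kinds are divided by that factor to make
    them exchangeable when replicate and sample noise levels are equal.
    """
    if len(pairing.pairs) < 2:
        raise ValueError("need >= 2 replicate pairs")
    rep_cols = set(pairing.replicate_columns)
    sample_cols = [c for c in phenotypes.columns if c not in rep_cols]
    if len(sample_cols) < 3:
        raise ValueError("need >= 3 distinct sample columns")
    for a, b in pairing.pairs:
        for c in (a, b):
            if c not in phenotypes.columns:
                raise ValueError(f"pairing references unknown column {c!r}")

    samples = phenotypes[sample_cols].to_numpy(dtype=float)
    n_s = samples.shape[1]
    sample_dev = np.abs(samples - samples.mean(axis=1, keepdims=True))
    sample_dev /= np.sqrt(1.0 - 1.0 / n_s)

    rep_devs = []
    for a, b in pairing.pairs:
        pair = phenotypes[[a, b]].to_numpy(dtype=float)
        # |x - pair mean| = |a - b| / 2, identical for both members: keep one,
        # rescaled by sqrt(1 - 1/2)
        rep_devs.append(np.abs(pair[:, 0] - pair[:, 1])[:, None] / 2 / np.sqrt(0.5))
    rep_dev = np.hstack(rep_devs)

    pvals = np.ones(len(phenotypes))
    for i in range(len(phenotypes)):
        s, r = sample_dev[i], rep_dev[i]
        if np.ptp(np.concatenate([s, r])) == 0:
            pvals[i] = 1.0  # constant tTRE carries no evidence
            continue
        pvals[i] = mannwhitneyu(s, r, alternative="greater").pvalue
    return pd.Series(pvals, index=phenotypes.index, name="p_variable")


def estimate_variable_fraction(pvals, lambda_grid=None,
                               method: str = "tail") -> tuple[float, float]:
    """Estimate (pi0, 1 - pi0) from the full p-value distribution.

    Two estimators of the null (non-variable) fraction pi0:

    - ``"tail"`` (default): Storey-style tail density — for each lambda in
      the grid (default 0.5..0.9 by 0.1), #{p > lambda} / ((1 - lambda) * m)
      estimates the density of the uniform portion; estimates are averaged
      and clipped to [0, 1]. Robust to discrete p-values (rank-sum tests
      have a finite support), but estimates the uniform-tail density, an
      upper bound on pi0 whenever the alternative leaks mass into the tail.
    - ``"bum"``: maximum likelihood under a Beta-uniform mixture
      f(p) = pi0 + (1 - pi0) * a * p^(a-1) with 0 < a < 1. Recovers the
      mixing weight itself — consistent even when the alternative has
      non-vanishing density at p = 1 — but assumes continuous p-values and
      can misfit strongly discrete ones.

    The variable fraction is 1 - pi0 in either case.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "tail":
        if lambda_grid is None:
            lambda_grid = np.arange(0.5, 0.95, 0.1)
        grid = np.asarray(lambda_grid, dtype=float)
        m = p.size
        estimates = [(p > lam).sum() / ((1.0 - lam) * m) for lam in grid]
        pi0 = float(np.clip(np.mean(estimates), 0.0, 1.0))
    elif method == "bum":
        pi0 = _bum_pi0(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pi0, 1.0 - pi0


def _bum_pi0(p: np.ndarray, ll_tolerance: float = 2.0) -> float:
    """Beta-uniform mixture estimate of the uniform weight, by profiling.

    For each Beta shape a on a grid, the mixture weight is fitted by
    1-D maximum likelihood (the log-likelihood is concave in pi0). Among
    shapes whose profile likelihood is within ``ll_tolerance`` of the
    optimum, the largest pi0 is reported: this breaks the ridge that makes
    pi0 unidentifiable when the alternative is itself near-uniform (a -> 1),
    resolving it conservatively toward the null.
    """
    from scipy.optimize import minimize_scalar

    pc = np.clip(p, 1e-250, 1.0)  # density diverges at exactly 0 for a < 1

    def fit_weight(a: float) -> tuple[float, float]:
        g = a * pc ** (a - 1.0)

        def nll(pi0: float) -> float:
            dens = pi0 + (1.0 - pi0) * g
            return -np.log(np.maximum(dens, 1e-300)).sum()

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        return float(res.x), float(res.fun)

    shapes = np.concatenate([np.geomspace(0.005, 0.5, 25),
                             np.linspace(0.55, 0.995, 15)])
    fits = [fit_weight(a) for a in shapes]
    best_nll = min(f[1] for f in fits)
    pi0 = max(f[0] for f in fits if f[1] <= best_nll + ll_tolerance)
    return float(np.clip(pi0, 0.0, 1.0))
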