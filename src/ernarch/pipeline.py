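"""End-to-end study driver: simulate or load, call, normalize, map, localize.

Chains the pipeline stages the way the full analysis runs: aggregate the
per-individual tracks, call divergent elements, build the level and
directionality phenotypes, map ti/di QTLs with BH control, and score
recovery against a truth table when one is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .discovery import (
    TTRE,
    assign_dominant_strand,
    call_ntss,
    pair_bidirectional,
    ttre_window_counts,
)
from .io import GenotypeTable, StrandedSignal
from .normalize import directionality_phenotype, level_phenotype
from .qtl import map_cis_qtls
from .simulate import SimConfig, TruthTable, aggregate_signals

__all__ = ["StudyResult", "run_study", "run_synthetic_study", "recovery_power"]


@dataclass
class StudyResult:
    ttres: list[TTRE]
    plus_counts: pd.DataFrame
    minus_counts: pd.DataFrame
    level: pd.DataFrame
    directionality: pd.DataFrame
    ti_records: pd.DataFrame
    di_records: pd.DataFrame
    element_positions: pd.DataFrame


def run_study(genotypes: GenotypeTable, signals: dict[str, StrandedSignal],
              min_count: int = 50, merge_window: int = 60,
              fdr: float = 0.1) -> StudyResult:
    """Full pass from stranded tracks and genotypes to ti/di QTL tables.

    ``min_count`` applies to the aggregate (summed) track. Replicate
    columns (sample ids not present in the genotype table) contribute to
    peak calling but are excluded from association testing.
    """
    agg = aggregate_signals(signals)
    ntss = call_ntss(agg, min_count=min_count, merge_window=merge_window)
    ttres = pair_bidirectional(ntss)
    if not ttres:
        raise ValueError("no divergent elements called; lower min_count?")
    plus, minus = ttre_window_counts(ttres, signals)
    assign_dominant_strand(ttres, plus, minus)
    level = level_phenotype(plus, minus)
    direction = directionality_phenotype(plus, minus)
    assoc_cols = [s for s in genotypes.samples if s in level.columns]
    positions = pd.DataFrame({"contig": [t.contig for t in ttres],
                              "position": [t.midpoint for t in ttres]},
                             index=[t.id for t in ttres])
    ti = map_cis_qtls(genotypes, level[assoc_cols], positions, "ti", fdr=fdr)
    di = map_cis_qtls(genotypes, direction[assoc_cols], positions, "di", fdr=fdr)
    return StudyResult(ttres, plus, minus, level, direction, ti, di, positions)


def run_synthetic_study(config: SimConfig, min_count: int | None = None,
                        fdr: float = 0.1):
    """Simulate a cohort under ``config`` and run the full pipeline on it.

    Returns (genotypes, truth, signals, StudyResult). The default peak
    threshold scales with cohort depth: a quarter of the expected aggregate
    per-base summit count.
    """
    from .simulate import simulate_genotypes, simulate_procap, simulate_truth

    rng = config.rng()
    genotypes = simulate_genotypes(config, rng)
    truth = simulate_truth(config, genotypes, rng)
    signals = simulate_procap(config, genotypes, truth, rng)
    if min_count is None:
        n_tracks = config.n_individuals + config.n_replicate_pairs
        # the geometric scatter puts ~1/(2*spread) of a strand's reads on
        # the summit base; threshold at a quarter of that expectation
        summit = config.baseline_mean * config.depth * n_tracks / (2 * config.tss_spread)
        min_count = max(2, int(summit / 4))
    result = run_study(genotypes, signals, min_count=min_count, fdr=fdr)
    return genotypes, truth, signals, result


def recovery_power(truth: TruthTable, result: StudyResult, qtl_type: str,
                   match_tolerance: int = 50) -> float:
    """Fraction of planted QTLs recovered as significant at their element.

    A planted QTL counts as recovered when the (variant, element) record is
    significant for a called element whose midpoint lies within
    ``match_tolerance`` bp of the planted midpoint.
    """
    records = result.ti_records if qtl_type == "ti" else result.di_records
    planted = truth.qtls_of_type(qtl_type)
    if planted.empty:
        return float("nan")
    called_mid = {t.id: t.midpoint for t in result.ttres}
    hits = 0
    for _, q in planted.iterrows():
        true_mid = int(truth.ttres.loc[q["target"], "midpoint"])
        sub = records[(records["variant_id"] == q["variant_id"])
                      & records["significant"]]
        for _, r in sub.iterrows():
            if abs(called_mid[r["element_id"]] - true_mid) <= match_tolerance:
                hits += 1
                break
    return hits / len(planted)
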