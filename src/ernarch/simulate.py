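"""Synthetic genotypes and stranded 5'-count tracks with planted effects.

The generator emulates the study design end to end: a population of
individuals with Hardy-Weinberg genotypes, divergent bidirectional
initiation elements whose cores sit a fixed distance (default 70 bp)
either side of a midpoint, negative-binomial count noise with replicate
structure, ~2-fold level (ti) effects acting multiplicatively per allele,
logit-shift directionality (di) effects that preserve total initiation,
and linear-in-dosage expression (e) effects for nearby genes. A truth
table records every planted element and QTL so downstream stages can be
scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeTable, StrandedSignal, Variant

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_truth",
    "simulate_procap",
    "simulate_expression",
    "simulate_mask",
    "aggregate_signals",
    "write_fixture_set",
    "write_vcf",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the study conditions: 67 individuals with 8 replicate
    pairs, initiation cores 70 bp either side of the element midpoint,
    ~2-fold homozygote level effects, and negative-binomial count noise
    (dispersion 0.2, a typical molecular-count reproducibility level).
    """

    n_individuals: int = 67
    n_replicate_pairs: int = 8
    contig: str = "chr1"
    genome_length: int = 1_000_000
    n_ttres: int = 100
    n_variants: int = 2_000
    core_offset: int = 70  # bp, midpoint -> each nTSS
    tss_spread: float = 5.0  # bp, geometric decay scale of initiation positions
    baseline_mean: float = 100.0  # expected counts per tTRE per strand per individual
    dispersion: float = 0.2  # negative-binomial: var = mu + dispersion * mu^2
    ti_fold_hom: float = 2.0  # total fold change between homozygotes
    di_logit_shift: float = 1.0  # log-odds shift of plus-strand allocation per alt allele
    e_beta: float = 1.0  # expression effect per alt allele
    e_noise_sd: float = 1.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    depth: float = 1.0  # global library-depth multiplier
    n_ti_qtls: int = 20
    n_di_qtls: int = 20
    n_e_qtls: int = 10
    cis_window: int = 2_000  # ti/di planting window around the midpoint
    e_cis_window: int = 200_000
    # where planted causal variants sit: level effects at the central
    # TF-binding footprint, directionality effects at the initiation cores
    ti_placement: str = "center"  # "center" (midpoint +/- 25) or "any"
    di_placement: str = "core"  # "core" (an nTSS +/- 25) or "any"
    placement_halfwidth: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.core_offset < 1:
            raise ValueError("core_offset must be >= 1")
        for name in ("genome_length", "n_ttres", "n_variants", "tss_spread",
                     "baseline_mean", "ti_fold_hom", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        span = 2 * (self.core_offset + 250 + 50)
        if self.n_ttres * span > self.genome_length:
            raise ValueError("genome too short for non-overlapping tTREs")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTable:
    """Planted elements and QTLs.

    ``ttres``: one row per element (id, contig, midpoint, nTSS positions,
    class, baseline plus-strand allocation p0). ``qtls``: one row per
    planted QTL (variant id/index, target element or gene, type in
    {ti, di, e}, effect size in the generator's parameterization).
    """

    ttres: pd.DataFrame
    qtls: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["variant_id", "variant_index", "target", "type", "effect"]))

    def qtls_of_type(self, qtl_type: str) -> pd.DataFrame:
        return self.qtls[self.qtls["type"] == qtl_type]


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeTable:
    """Independent biallelic sites in Hardy-Weinberg proportions.

    Alt-allele frequencies are uniform on [maf_low, maf_high]; dosages are
    Binomial(2, f) per individual; positions are uniform over the contig.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_individuals
    positions = np.sort(rng.choice(config.genome_length, size=config.n_variants, replace=False))
    freqs = rng.uniform(config.maf_low, config.maf_high, size=config.n_variants)
    dosages = rng.binomial(2, freqs[:, None], size=(config.n_variants, n)).astype(float)
    samples = [f"NA{i:05d}" for i in range(n)]
    variants = [Variant(config.contig, int(p), "A", "G", f"var_{i:05d}")
                for i, p in enumerate(positions)]
    f_alt = dosages.sum(axis=1) / (2 * n)
    maf = np.minimum(f_alt, 1 - f_alt)
    return GenotypeTable(variants, samples, dosages, maf)


def simulate_truth(config: SimConfig, genotypes: GenotypeTable,
                   rng: np.random.Generator | None = None) -> TruthTable:
    """Place non-overlapping tTREs and assign planted QTLs to targets.

    Elements are laid out on an evenly spaced grid with jitter; each
    element's nTSSs sit at midpoint +/- core_offset. Planted ti/di QTLs
    take an unused polymorphic variant and, under the default placements,
    relocate it to the causal region of the bipartite model — level (ti)
    effects to the central TF-binding footprint (midpoint +/- 25 bp),
    directionality (di) effects to an initiation core (an nTSS +/- 25 bp);
    placement "any" leaves the variant wherever it was drawn inside the
    cis window. ti and di targets are disjoint. e-QTL variants stay where
    drawn and drive a synthetic gene within the expression cis window.
    """
    rng = config.rng() if rng is None else rng
    span = 2 * (config.core_offset + 250 + 50)
    slot = config.genome_length // config.n_ttres
    jitter_max = max(1, (slot - span) // 2)
    mids = []
    for i in range(config.n_ttres):
        base = i * slot + slot // 2
        mids.append(base + int(rng.integers(-jitter_max, jitter_max + 1)))
    mids = np.array(sorted(mids))
    if np.any(np.diff(mids) < span):
        raise ValueError("planted tTREs overlap; increase genome_length")
    ttres = pd.DataFrame({
        "id": [f"ttre_{i:05d}" for i in range(config.n_ttres)],
        "contig": config.contig,
        "midpoint": mids,
        "minus_position": mids - config.core_offset,
        "plus_position": mids + config.core_offset,
        "class": "enhancer",
        "p0": 0.5,
    }).set_index("id", drop=False)

    var_pos = np.array([v.position for v in genotypes.variants])
    polymorphic = np.flatnonzero(genotypes.maf >= config.maf_low)

    qtl_rows: list[dict] = []
    used_targets: set[str] = set()
    used_variants: set[int] = set()
    taken_positions = set(var_pos.tolist())

    def relocate(vi: int, row: pd.Series, placement: str) -> None:
        """Move a planted variant to its causal region of the element."""
        hw = config.placement_halfwidth
        if placement == "center":
            anchor = int(row["midpoint"])
        elif placement == "core":
            anchor = int(row["plus_position"] if rng.random() < 0.5
                         else row["minus_position"])
        else:
            return
        for _ in range(50):
            pos = anchor + int(rng.integers(-hw, hw + 1))
            if pos not in taken_positions:
                break
        old = genotypes.variants[vi]
        taken_positions.discard(old.position)
        taken_positions.add(pos)
        genotypes.variants[vi] = Variant(old.contig, pos, old.ref, old.alt, old.id)
        var_pos[vi] = pos

    def plant(qtl_type: str, n_wanted: int, effect: float, window: int,
              placement: str) -> None:
        order = rng.permutation(len(ttres))
        planted = 0
        for ti in order:
            if planted >= n_wanted:
                break
            row = ttres.iloc[ti]
            if row["id"] in used_targets:
                continue
            if placement == "any":
                near = polymorphic[(np.abs(var_pos[polymorphic] - row["midpoint"])
                                    <= window)]
                near = [v for v in near if v not in used_variants]
            else:
                near = [v for v in polymorphic if v not in used_variants]
            if not near:
                continue
            vi = int(rng.choice(near))
            used_variants.add(vi)
            used_targets.add(row["id"])
            relocate(vi, row, placement)
            qtl_rows.append({"variant_id": genotypes.variants[vi].id,
                             "variant_index": vi, "target": row["id"],
                             "type": qtl_type, "effect": effect})
            planted += 1

    plant("ti", config.n_ti_qtls, config.ti_fold_hom, config.cis_window,
          config.ti_placement)
    plant("di", config.n_di_qtls, config.di_logit_shift, config.cis_window,
          config.di_placement)

    for g in range(config.n_e_qtls):
        cand = [v for v in polymorphic if v not in used_variants]
        if not cand:
            break
        vi = int(rng.choice(cand))
        used_variants.add(vi)
        qtl_rows.append({"variant_id": genotypes.variants[vi].id,
                         "variant_index": vi, "target": f"gene_{g:04d}",
                         "type": "e", "effect": config.e_beta})

    qtls = pd.DataFrame(qtl_rows, columns=["variant_id", "variant_index",
                                           "target", "type", "effect"])
    return TruthTable(ttres, qtls)


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _scatter(rng: np.random.Generator, summit: int, n: int, spread: float,
             track: dict[int, int], lo: int, hi: int) -> None:
    """Scatter n read 5' ends around a summit with two-sided geometric decay."""
    if n <= 0:
        return
    mags = rng.geometric(min(1.0, 1.0 / spread), size=n) - 1
    signs = rng.choice((-1, 1), size=n)
    pos = np.clip(summit + mags * signs, lo, hi - 1)
    uniq, counts = np.unique(pos, return_counts=True)
    for p, c in zip(uniq, counts):
        track[int(p)] = track.get(int(p), 0) + int(c)


def simulate_procap(config: SimConfig, genotypes: GenotypeTable, truth: TruthTable,
                    rng: np.random.Generator | None = None) -> dict[str, StrandedSignal]:
    """Per-individual stranded 5'-count tracks with planted effects.

    Per tTRE and individual, the total initiation count is negative
    binomial with mean 2 * baseline_mean * depth * fold^(dosage/2) for
    ti targets (so the homozygote ratio is the configured fold), split
    between strands by Binomial(total, p) with
    p = logistic(logit(p0) + di_logit_shift * dosage) for di targets —
    the di effect moves directionality without changing the total. Read
    positions decay geometrically (scale tss_spread) around each nTSS,
    keeping the divergent orientation. Replicate individuals (first
    n_replicate_pairs, suffixed ``_rep``) are independent draws from the
    identical means, modelling libraries grown from independent cultures.
    """
    rng = config.rng() if rng is None else rng
    t = truth.ttres
    if np.any(np.diff(np.sort(t["midpoint"].to_numpy()))
              < 2 * (config.core_offset + 1)):
        raise ValueError("planted tTREs overlap")

    ti_map = {r["target"]: r["variant_index"] for _, r in truth.qtls_of_type("ti").iterrows()}
    di_map = {r["target"]: r["variant_index"] for _, r in truth.qtls_of_type("di").iterrows()}

    samples = list(genotypes.samples)
    columns = samples + [f"{s}_rep" for s in samples[:config.n_replicate_pairs]]
    col_individual = {c: (c[:-4] if c.endswith("_rep") else c) for c in columns}
    sample_idx = {s: i for i, s in enumerate(samples)}
    dosages = genotypes.imputed_dosages()

    signals = {c: StrandedSignal(config.contig) for c in columns}
    log_fold = np.log(config.ti_fold_hom)
    for _, row in t.iterrows():
        tid = row["id"]
        mid = int(row["midpoint"])
        p0 = float(row["p0"])
        lo, hi = mid - 500, mid + 500
        for col in columns:
            j = sample_idx[col_individual[col]]
            mu = 2 * config.baseline_mean * config.depth
            if tid in ti_map:
                mu *= np.exp(log_fold * dosages[ti_map[tid], j] / 2)
            logit_p = np.log(p0 / (1 - p0))
            if tid in di_map:
                logit_p += config.di_logit_shift * dosages[di_map[tid], j]
            p_plus = 1.0 / (1.0 + np.exp(-logit_p))
            total = int(_negbin(rng, mu, config.dispersion))
            n_plus = int(rng.binomial(total, p_plus))
            sig = signals[col]
            _scatter(rng, int(row["plus_position"]), n_plus, config.tss_spread,
                     sig.plus, lo, hi)
            _scatter(rng, int(row["minus_position"]), total - n_plus,
                     config.tss_spread, sig.minus, lo, hi)
    return signals


def simulate_expression(config: SimConfig, genotypes: GenotypeTable, truth: TruthTable,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene expression matrix with planted linear dosage effects.

    expression = intercept + beta * dosage + Gaussian noise; each planted
    gene's TSS is placed within the expression cis window of its driver
    variant. Returns (genes x individuals matrix, gene TSS table).
    """
    rng = config.rng() if rng is None else rng
    e_qtls = truth.qtls_of_type("e")
    rows, tss_rows = [], []
    dosages = genotypes.imputed_dosages()
    for _, q in e_qtls.iterrows():
        vi = int(q["variant_index"])
        d = dosages[vi]
        noise = rng.normal(0.0, config.e_noise_sd, size=len(d))
        rows.append(10.0 + float(q["effect"]) * d + noise)
        vpos = genotypes.variants[vi].position
        offset = int(rng.integers(-config.e_cis_window, config.e_cis_window + 1))
        tss = int(np.clip(vpos + offset, 0, config.genome_length - 1))
        tss_rows.append({"gene_id": q["target"], "contig": config.contig,
                         "position": tss, "strand": "+" if rng.random() < 0.5 else "-"})
    gene_ids = [r["gene_id"] for r in tss_rows]
    expr = pd.DataFrame(rows, index=gene_ids, columns=genotypes.samples)
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "contig", "position", "strand"])
    if not tss.empty:
        tss = tss.set_index("gene_id", drop=False)
    return expr, tss


def simulate_mask(config: SimConfig, genotypes: GenotypeTable, fraction: float = 0.1,
                  halfwidth: int = 15, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Allele-mappability mask: a random fraction of variant windows.

    Emulates regions where reads carrying different alleles map unequally;
    elements overlapping the mask are excluded downstream. Returns a BED-
    style (contig, start, end) frame.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = config.rng() if rng is None else rng
    n = genotypes.n_variants
    chosen = np.flatnonzero(rng.random(n) < fraction) if 0 < fraction < 1 else (
        np.arange(n) if fraction == 1 else np.array([], dtype=int))
    rows = [{"contig": genotypes.variants[i].contig,
             "start": max(0, genotypes.variants[i].position - halfwidth),
             "end": genotypes.variants[i].position + halfwidth + 1}
            for i in chosen]
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def aggregate_signals(signals: dict[str, StrandedSignal]) -> StrandedSignal:
    """Sum per-base counts across individuals (the peak-calling track)."""
    it = iter(signals.values())
    agg = next(it)
    out = StrandedSignal(agg.contig, dict(agg.plus), dict(agg.minus))
    for sig in it:
        out = out.add(sig)
    return out


def write_vcf(genotypes: GenotypeTable, path: str) -> None:
    """Write dosages back to a minimal GT-only VCF (1-based positions)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({v.contig for v in genotypes.variants})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        order = sorted(range(len(genotypes.variants)),
                       key=lambda i: (genotypes.variants[i].contig,
                                      genotypes.variants[i].position))
        for i in order:
            v = genotypes.variants[i]
            gts = []
            for d in genotypes.dosages[i]:
                gts.append("./." if np.isnan(d) else gt_codes[int(round(d))])
            fh.write(f"{v.contig}\t{v.position + 1}\t{v.id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_fixture_set(config: SimConfig, outdir: str) -> dict[str, object]:
    """Run the full generator and write VCF, bedGraph pairs, and truth tables.

    Same seed -> byte-identical files. Returns the in-memory objects too.
    """
    from .io import write_bedgraph

    rng = config.rng()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config, rng)
    truth = simulate_truth(config, genotypes, rng)
    signals = simulate_procap(config, genotypes, truth, rng)
    expr, gene_tss = simulate_expression(config, genotypes, truth, rng)

    write_vcf(genotypes, str(out / "genotypes.vcf"))
    for name, sig in signals.items():
        write_bedgraph(sig, str(out / f"{name}.plus.bedGraph"), strand="+")
        write_bedgraph(sig, str(out / f"{name}.minus.bedGraph"), strand="-")
    truth.ttres.to_csv(out / "truth_ttres.tsv", sep="\t", index=False)
    truth.qtls.to_csv(out / "truth_qtls.tsv", sep="\t", index=False)
    with open(out / "truth_ttres.bed", "w") as fh:
        for _, r in truth.ttres.iterrows():
            fh.write(f"{r['contig']}\t{r['minus_position']}\t{r['plus_position'] + 1}"
                     f"\t{r['id']}|{r['class']}\t0\t.\n")
    if not expr.empty:
        expr.to_csv(out / "expression.tsv", sep="\t")
        gene_tss.to_csv(out / "gene_tss.tsv", sep="\t", index=False)
    return {"genotypes": genotypes, "truth": truth, "signals": signals,
            "expression": expr, "gene_tss": gene_tss}
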