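"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). VCF
positions are converted to 0-based on read. Strand-specific 5'-end count
tracks are held sparsely, one ``{position: count}`` map per strand, so
chromosome-sized contigs cost memory proportional to the signal only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StrandedSignal",
    "Variant",
    "GenotypeTable",
    "AnnotatedTSS",
    "read_bedgraph_pair",
    "read_bedgraph",
    "write_bedgraph",
    "read_vcf_dosages",
    "read_annotated_tss",
    "write_bed_ttres",
    "read_bed_ttres",
    "write_qtl_table",
    "read_qtl_table",
    "read_bed_intervals",
    "write_bed_intervals",
]


@dataclass
class StrandedSignal:
    """Sparse per-base 5'-end read counts on the plus and minus strands.

    ``plus`` and ``minus`` are independent maps ``position -> count`` with
    0-based positions and non-negative integer counts.
    """

    contig: str
    plus: dict[int, int] = field(default_factory=dict)
    minus: dict[int, int] = field(default_factory=dict)

    def strand(self, s: str) -> dict[int, int]:
        if s == "+":
            return self.plus
        if s == "-":
            return self.minus
        raise ValueError(f"strand must be '+' or '-', got {s!r}")

    def total(self) -> int:
        return sum(self.plus.values()) + sum(self.minus.values())

    def add(self, other: "StrandedSignal") -> "StrandedSignal":
        """Return a new signal with per-base counts summed."""
        if other.contig != self.contig:
            raise ValueError("cannot add signals on different contigs")
        out = StrandedSignal(self.contig, dict(self.plus), dict(self.minus))
        for pos, c in other.plus.items():
            out.plus[pos] = out.plus.get(pos, 0) + c
        for pos, c in other.minus.items():
            out.minus[pos] = out.minus.get(pos, 0) + c
        return out

    def window_count(self, start: int, end: int, strand: str) -> int:
        """Sum of counts in the half-open interval [start, end)."""
        track = self.strand(strand)
        if len(track) > (end - start):
            return sum(track.get(p, 0) for p in range(start, end))
        return sum(c for p, c in track.items() if start <= p < end)


@dataclass(frozen=True)
class Variant:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    id: str


@dataclass
class GenotypeTable:
    """Biallelic variants with alt-allele dosages per individual.

    ``dosages`` is a variants x individuals float matrix in {0, 1, 2} with
    NaN marking missing genotypes; ``maf`` is the per-variant minor-allele
    frequency computed over non-missing calls (always in [0, 0.5]).
    """

    variants: list[Variant]
    samples: list[str]
    dosages: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.maf, initial=0.0) < 0 or np.nanmax(self.maf, initial=0.0) > 0.5:
                raise ValueError("maf must lie in [0, 0.5]")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed per variant.

        Standard matrix-QTL practice; the fraction imputed is logged.
        """
        d = self.dosages.copy()
        missing = np.isnan(d)
        if missing.any():
            frac = missing.mean()
            logger.info("mean-imputing %.3f%% missing dosages", 100 * frac)
            row_means = np.where(
                missing.all(axis=1), 0.0, np.nanmean(np.where(missing, np.nan, d), axis=1)
            )
            d[missing] = np.broadcast_to(row_means[:, None], d.shape)[missing]
        return d

    def subset(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = list(idx)
        return GenotypeTable(
            [self.variants[i] for i in idx],
            list(self.samples),
            self.dosages[idx, :],
            self.maf[idx],
        )


@dataclass(frozen=True)
class AnnotatedTSS:
    contig: str
    position: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _parse_bedgraph_lines(path: str, negate: bool) -> Iterable[tuple[str, int, int, int]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields, got {len(fields)}")
            try:
                contig = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if negate:
                value = -value
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value} after sign convention")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval [{start},{end})")
            count = int(round(value))
            if abs(value - count) > 1e-6:
                raise ValueError(f"{path}:{lineno}: non-integer count {value}")
            yield contig, start, end, count


def read_bedgraph(path: str, strand: str = "+", dialect: str = "positive",
                  signal: StrandedSignal | None = None, contig: str | None = None) -> StrandedSignal:
    """Read one bedGraph file into (one strand of) a :class:`StrandedSignal`.

    Intervals are expanded per base; total signal is conserved. ``dialect``
    is ``"positive"`` (default) or ``"negated"`` for minus-strand files that
    store negative values. Overlapping intervals on one strand are an error.
    """
    negate = dialect == "negated"
    if dialect not in ("positive", "negated"):
        raise ValueError(f"unknown bedGraph dialect {dialect!r}")
    track: dict[int, int] = {}
    seen_contig = contig
    for ctg, start, end, count in _parse_bedgraph_lines(path, negate):
        if seen_contig is None:
            seen_contig = ctg
        elif ctg != seen_contig:
            raise ValueError(f"{path}: multiple contigs per signal not supported ({seen_contig}, {ctg})")
        if count == 0:
            continue
        for pos in range(start, end):
            if pos in track:
                raise ValueError(f"{path}: overlapping intervals at {ctg}:{pos}")
            track[pos] = count
    if signal is None:
        signal = StrandedSignal(seen_contig if seen_contig is not None else "chr1")
    if strand == "+":
        signal.plus = track
    else:
        signal.minus = track
    return signal


def read_bedgraph_pair(path_plus: str, path_minus: str,
                       minus_dialect: str = "positive") -> StrandedSignal:
    """Read a plus/minus bedGraph pair into one :class:`StrandedSignal`."""
    sig = read_bedgraph(path_plus, strand="+")
    read_bedgraph(path_minus, strand="-", dialect=minus_dialect,
                  signal=sig, contig=None if not sig.plus else sig.contig)
    return sig


def write_bedgraph(signal: StrandedSignal, path: str, strand: str = "+",
                   dialect: str = "positive") -> None:
    """Write one strand as bedGraph, merging adjacent equal-count bases."""
    track = signal.strand(strand)
    sign = -1 if dialect == "negated" else 1
    with open(path, "w") as fh:
        run_start = run_end = None
        run_count = 0
        for pos in sorted(track):
            count = track[pos]
            if count == 0:
                continue
            if run_start is not None and pos == run_end and count == run_count:
                run_end = pos + 1
            else:
                if run_start is not None:
                    fh.write(f"{signal.contig}\t{run_start}\t{run_end}\t{sign * run_count}\n")
                run_start, run_end, run_count = pos, pos + 1, count
        if run_start is not None:
            fh.write(f"{signal.contig}\t{run_start}\t{run_end}\t{sign * run_count}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_dosages(path: str, maf_min: float = 0.05) -> GenotypeTable:
    """Read diploid GT dosages from a VCF.

    Dosage is the alt-allele count per individual. Variants with minor-allele
    frequency below ``maf_min`` are dropped; multi-allelic records are skipped
    with a warning. Missing genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    mafs: list[float] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()  # (n, ploidy+1); last col is phasing
        alleles = gts[:, :-1].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)
        valid = ~np.isnan(dos)
        if not valid.any():
            continue
        f_alt = float(dos[valid].sum() / (2 * valid.sum()))
        maf = min(f_alt, 1.0 - f_alt)
        if maf < maf_min:
            continue
        variants.append(Variant(rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0],
                                rec.ID or f"{rec.CHROM}:{rec.POS}"))
        rows.append(dos)
        mafs.append(maf)
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    dosages = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return GenotypeTable(variants, samples, dosages, np.array(mafs, dtype=float))


# ---------------------------------------------------------------------------
# BED / TSV tables
# ---------------------------------------------------------------------------

def read_annotated_tss(path: str) -> list[AnnotatedTSS]:
    """Read annotated gene TSSs from BED6 (TSS = strand-aware interval start)."""
    out: list[AnnotatedTSS] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            contig, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "+"
            pos = start if strand == "+" else end - 1
            out.append(AnnotatedTSS(contig, pos, strand, name))
    return out


def write_bed_ttres(ttres: Sequence, path: str) -> None:
    """Write tTREs as BED6: span covers both nTSSs, name carries id|class."""
    rows = sorted(ttres, key=lambda t: (t.contig, t.minus_position, t.plus_position))
    with open(path, "w") as fh:
        for t in rows:
            name = f"{t.id}|{t.klass}"
            fh.write(f"{t.contig}\t{t.minus_position}\t{t.plus_position + 1}\t{name}\t0\t.\n")


def read_bed_ttres(path: str) -> pd.DataFrame:
    """Read a tTRE BED6 back into a DataFrame of geometry + class."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            tid, _, klass = name.partition("|")
            minus = int(f[1])
            plus = int(f[2]) - 1
            rows.append({
                "id": tid, "contig": f[0], "minus_position": minus,
                "plus_position": plus, "midpoint": (minus + plus) // 2,
                "class": klass or "unclassified",
            })
    return pd.DataFrame(rows, columns=["id", "contig", "minus_position",
                                       "plus_position", "midpoint", "class"])


_QTL_COLUMNS = ["variant_id", "element_id", "type", "contig", "position",
                "cis_distance", "beta", "t", "p", "q", "significant"]


def write_qtl_table(records: pd.DataFrame, path: str) -> None:
    """Write association records as TSV with a fixed header (round-trip safe)."""
    df = records.copy()
    for col in _QTL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"QTL table missing column {col!r}")
    df = df[_QTL_COLUMNS].sort_values(["contig", "position", "element_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_qtl_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "element_id": str,
                                            "contig": str, "type": str})
    if df.empty:
        df = df.reindex(columns=_QTL_COLUMNS)
    if "significant" in df.columns and df["significant"].dtype != bool:
        df["significant"] = df["significant"].astype(bool)
    return df


def read_bed_intervals(path: str) -> pd.DataFrame:
    """Read a plain BED3+ file into (contig, start, end) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            rows.append({"contig": f[0], "start": int(f[1]), "end": int(f[2])})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def write_bed_intervals(df: pd.DataFrame, path: str) -> None:
    out = df.sort_values(["contig", "start", "end"])
    with open(path, "w") as fh:
        for _, r in out.iterrows():
            fh.write(f"{r['contig']}\t{int(r['start'])}\t{int(r['end'])}\n")
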