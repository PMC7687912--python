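"""The bipartite signature: where ti- and diQTLs sit inside enhancers.

Computes positional enrichment of mapped QTLs around element midpoints
against a resampled all-SNP background, plus the five-way region partition
(center / core / NCNC / out / far-out) with Fisher tests against far-out.
"""

import numpy as np

from ernarch.architecture import positional_enrichment, regional_frequency_test
from ernarch.pipeline import run_synthetic_study
from ernarch.simulate import SimConfig

cfg = SimConfig(seed=1)
genotypes, truth, signals, result = run_synthetic_study(cfg)
snps = [(v.contig, v.position) for v in genotypes.variants]
rng = np.random.default_rng(1)

for name, records in (("tiQTL", result.ti_records), ("diQTL", result.di_records)):
    sig = records[records["significant"]]
    positions = list({(r["contig"], int(r["position"])) for _, r in sig.iterrows()})
    profile = positional_enrichment(positions, result.ttres, snps,
                                    n_resample=1_000, bin=10, rng=rng)
    print(f"{name}: {profile.n_qtls} QTLs, enrichment peak at "
          f"{profile.peak_offset():+.0f} bp from the midpoint")

ti_sig = result.ti_records[result.ti_records["significant"]]
qtl_pos = list({(r["contig"], int(r["position"])) for _, r in ti_sig.iterrows()})
table = regional_frequency_test(snps, qtl_pos, result.ttres)
print("\ntiQTL frequency by region (Fisher vs far_out):")
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# Level QTLs peak at the central TF-binding footprint (offset ~0) while
# directionality QTLs flank it at +/-70 bp, the initiation cores — the
# bipartite architecture the planted cohort encodes.
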