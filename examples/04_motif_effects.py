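"""Allele-level sequence effects: TF motif, Initiator, and TATA-like scores.

Scores a toy variant against a TF position weight matrix, computes the
Initiator-likelihood change between directionality alleles, and the tiered
TATA-like score change in the upstream window.
"""

import math

import numpy as np

from ernarch.motifs import (
    PWMModel,
    VariantWindow,
    allele_delta_pwm,
    inr_likelihood_delta,
    tata_delta,
    tata_score,
)

# --- TF motif disruption at a level QTL ------------------------------------
BASES = "ACGT"
pfm = np.full((4, 7), 0.05 / 3)
for j, b in enumerate("GATTACA"):
    pfm[BASES.index(b), j] = 0.95
pwm = PWMModel("GATTACA_factor", pfm)

variant = VariantWindow("rs_toy", "TTGATTACATT", ref="T", alt="C", offset=5,
                        high_is_alt=False)  # reference allele drives more initiation
for d in allele_delta_pwm(variant, [pwm], strong_threshold=5.0):
    print(f"{d.motif_id}: delta = {d.delta:+.2f} bits "
          f"(high {d.score_high:.2f}, low {d.score_low:.2f})")
# A positive delta means the higher-initiation allele carries the stronger
# TF-binding match — the mechanism expected for central level QTLs.

# --- Initiator element at a directionality QTL ------------------------------
# rows A, C, G, T: a pyrimidine-purine step (C/T then A), the Inr core
inr = PWMModel("Inr", np.array([[0.05, 0.60],
                                [0.45, 0.10],
                                [0.05, 0.10],
                                [0.45, 0.20]]), log_base=math.e)
d_inr = inr_likelihood_delta("CCCATTCC", "CCCGTTCC", inr)
print(f"Inr likelihood delta (high - low allele): {d_inr:+.2f}")

# --- TATA-like elements 40-20 bp upstream -----------------------------------
print(f"TATA scores: TATA={tata_score('TATA')}, TTTA={tata_score('TTTA')}, "
      f"TTAA={tata_score('TTAA')}, TACG={tata_score('TACG')}")
print(f"delta TATA (TATA window vs TTTA window): "
      f"{tata_delta('GGTATAGG', 'GGTTTAGG')}")
# Tiers 4/2/1/0 grade the canonical TATA, single and double A<->T
# inversions; a positive delta says the high-directionality allele carries
# the stronger TATA-like element upstream of its nTSS.
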