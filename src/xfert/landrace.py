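"""Reported summary data for the BMP15 p.R212X nonsense variant in the
Bavarian German Landrace pig population.

The raw genotype and breeding-value records behind these numbers are held by
the breeding organisation and are not redistributable; what travels with the
package are the published summary tables (genotype concordance counts, parent
genotype counts, dosage-group sizes, per-trait allele-substitution effects and
economic weights).  They serve two purposes: as inputs to the worked examples
and acceptance checks, and as the calibration targets the synthetic population
generator reproduces.
"""

from __future__ import annotations

import math

# --- the candidate variant -------------------------------------------------

CAUSAL_CHROM = "X"
CAUSAL_POS = 44_618_787          # Sscrofa11.1, 1-based
CAUSAL_REF = "C"
CAUSAL_ALT = "T"
STOP_CODON_INDEX = 212           # premature stop, p.R212X
# Mature-protein length inferred from the reported 47.5 % truncated fraction
# ((L - 211) / L = 0.475 has the unique integer solution L = 402); the record
# itself does not print the length.
PROTEIN_LENGTH = 402

# Associated region on the X chromosome (bp, inclusive).
REGION_START = 38_600_000
REGION_END = 108_700_000

# --- GWAS panel ------------------------------------------------------------

N_CHIP_SNPS = 50_649
N_CASES = 17
N_CONTROLS = 1_818
# Of the 17 small-vulva cases, only 11 were T/T on regenotyping.
N_TRUE_CASES = 11

# --- concordance survey (4941 genotyped sows) ------------------------------
# Genotype counts ordered (C/C, C/T, T/T).

CONCORDANCE_COUNTS = {
    "small_vulvae": (4, 3, 36),        # 43 affected gilts
    "normal_siblings": (0, 29, 0),     # 29 unaffected full siblings
    "fertile": (4263, 606, 0),         # 4869 fertile herdbook sows
}

# --- genotyped parents (dosage derivation inputs) ---------------------------

PARENT_COUNTS = {
    "boar_C": 367,
    "boar_T": 27,
    "sow_CC": 4263,
    "sow_CT": 606,
}

# --- dosage groups ----------------------------------------------------------
# Expected T-allele dosage -> (total sows, of which parent-derived).

DOSAGE_GROUPS = {
    0.000: (8400, 4156),
    0.062: (9623, 9623),
    0.069: (1092, 1092),
    0.131: (9969, 9969),
    0.500: (1185, 1185),
    0.569: (565, 565),
    1.000: (1455, 579),
}

# --- allele-substitution effects on breeding values -------------------------
# trait -> (n sows with reliability >= 40 %, effect per dosage unit, SE, P).

TRAIT_EFFECTS = {
    "live_born_piglets": (20_549, 0.411, 0.021, 4.50e-83),
    "feed_conversion_ratio": (10_072, -0.028, 0.004, 7.60e-15),
    "daily_gain": (10_072, -0.847, 1.684, 6.15e-01),
    "lean_meat_content": (10_072, -0.889, 0.059, 2.50e-51),
    "belly_meat_content": (10_072, -0.906, 0.057, 2.21e-56),
    "loin_eye_area": (10_072, -1.216, 0.097, 1.12e-35),
    "loin_to_fat_ratio": (10_072, -0.031, 0.002, 1.06e-51),
    "carcass_length": (10_072, -0.030, 0.045, 5.13e-01),
    "intramuscular_fat_content": (10_072, 0.068, 0.007, 6.20e-25),
    "ph1": (10_072, 0.002, 0.002, 1.16e-01),
    "drip_loss": (10_072, -0.005, 0.004, 2.16e-01),
}

N_TRAIT_TESTS = 11

# Euro per trait unit for the economically weighted traits.
ECONOMIC_WEIGHTS = {
    "live_born_piglets": 3.98,
    "feed_conversion_ratio": 22.70,
    "lean_meat_content": 1.66,
}


def concordance_fixture():
    """The 4941-sow concordance survey as an in-memory genotype panel.

    Returns ``(GenotypeMatrix, classes)``: one X marker, one sample per
    surveyed sow, and a phenotype-class label per sample, built from
    CONCORDANCE_COUNTS.
    """
    import numpy as np

    from .geno_qc import GenotypeMatrix, MarkerPanel

    samples, classes, codes = [], {}, []
    for group, counts in CONCORDANCE_COUNTS.items():
        for code, n in enumerate(counts):
            for k in range(n):
                sid = f"{group}_{code}_{k}"
                samples.append(sid)
                classes[sid] = group
                codes.append(code)
    panel = MarkerPanel([f"{CAUSAL_CHROM}:{CAUSAL_POS}"], [CAUSAL_CHROM],
                        [CAUSAL_POS], [CAUSAL_REF], [CAUSAL_ALT])
    gm = GenotypeMatrix(samples, np.array(["F"] * len(samples)), panel,
                        np.array(codes, dtype=np.int8)[:, None])
    return gm, classes


def dosage_sd() -> float:
    """Standard deviation of the T-allele dosage over the dosage groups."""
    tot = sum(n for n, _ in DOSAGE_GROUPS.values())
    mean = sum(d * n for d, (n, _) in DOSAGE_GROUPS.items()) / tot
    var = sum(n * (d - mean) ** 2 for d, (n, _) in DOSAGE_GROUPS.items()) / tot
    return math.sqrt(var)


def calibrated_residual_sd(trait: str) -> float:
    """Residual SD that makes an OLS fit of EBV on dosage reproduce the
    reported standard error at the reported sample size.

    SE(b) = sigma / (sd(x) * sqrt(n)), so sigma = SE * sd(x) * sqrt(n).
    """
    n, _, se, _ = TRAIT_EFFECTS[trait]
    return se * dosage_sd() * math.sqrt(n)
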