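"""Synthetic pedigreed pig populations with an X-linked recessive
infertility locus.

The generator emulates the structure the downstream analyses assume: a
herdbook-style population bred over discrete generations, SNP haplotypes with
block-wise linkage disequilibrium, an X-chromosomal causal allele segregating
at low frequency whose homozygous females are infertile (and therefore never
become dams), noisy case labelling of the infertile gilts, and per-trait
breeding values that respond linearly to the true causal-allele dosage.

Inheritance model
-----------------
Founder haplotypes are mosaics of a small pool of ancestral block haplotypes
(one pool per LD block of ``ld_block_len`` bp); within a block, marker allele
frequencies follow a latent linear gradient.  Meiosis copies parental
haplotypes block-wise with a fixed per-block-boundary switch probability, so
markers within a block travel together and an association signal spreads over
the block containing the causal locus.  Males carry a single X haplotype:
daughters receive the sire's X intact plus a recombinant of the dam's two X
haplotypes; sons receive only a maternal recombinant.  For export to diploid
file formats a male X call is represented as homozygous (codes 0/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landrace
from .geno_qc import GenotypeMatrix, MarkerPanel

__all__ = [
    "SimConfig", "Population", "CaseControlLabels",
    "simulate_population", "simulate_case_labels", "simulate_ebvs",
    "genotype_matrix", "write_pedigree", "write_ebvs",
]


def _default_chrom_lengths() -> dict:
    return {"1": 140_000_000, "2": 130_000_000, "X": 126_000_000}


def _default_trait_effects() -> dict:
    return {t: eff for t, (_, eff, _, _) in landrace.TRAIT_EFFECTS.items()}


def _default_trait_residual_sd() -> dict:
    return {t: landrace.calibrated_residual_sd(t)
            for t in landrace.TRAIT_EFFECTS}


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults give the desk-scale study design: ~5,000 markers on two
    autosomes plus X, a causal X locus at alt frequency 0.062, a 17-case /
    1,818-control genotyped panel with 6/17 of the case labels wrong, and
    eleven breeding-value traits whose true per-dosage effects and noise
    levels reproduce the reported effect table.
    """

    n_founder_boars: int = 80
    n_founder_sows: int = 1200
    n_generations: int = 3
    n_markers_per_chrom: int = 1666
    chrom_lengths: dict = field(default_factory=_default_chrom_lengths)
    causal_chrom: str = "X"
    causal_pos: int = landrace.CAUSAL_POS
    causal_alt_freq: float = 0.062
    ld_block_len: int = 2_000_000
    case_label_error: float = 6.0 / 17.0
    case_detection: float = 1.0
    n_cases: int | None = 17
    n_controls: int = 1818
    litter_size: int = 10
    n_ancestral_haplotypes: int = 8
    trait_effects: dict = field(default_factory=_default_trait_effects)
    trait_residual_sd: dict = field(default_factory=_default_trait_residual_sd)
    reliability_range: tuple = (0.40, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("causal_alt_freq", "case_label_error", "case_detection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_founder_boars <= 0 or self.n_founder_sows <= 0:
            raise ValueError("need at least one founder of each sex")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} "
                             "missing from chrom_lengths")
        if not 1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]:
            raise ValueError("causal_pos outside causal chromosome")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if any(sd < 0 for sd in self.trait_residual_sd.values()):
            raise ValueError("negative residual standard deviation")
        if self.causal_alt_freq in (0.0, 1.0):
            warnings.warn("degenerate causal allele frequency "
                          f"{self.causal_alt_freq}: locus is monomorphic",
                          stacklevel=2)

    def causal_block_interval(self) -> tuple[int, int]:
        """bp interval (inclusive) of the LD block holding the causal locus."""
        b = (self.causal_pos - 1) // self.ld_block_len
        return b * self.ld_block_len + 1, (b + 1) * self.ld_block_len


@dataclass
class Population:
    """A simulated pedigreed population with phased genotypes."""

    config: SimConfig
    panel: MarkerPanel                    # all chromosomes, ordered
    chrom_slices: dict                    # chrom -> slice into panel columns
    haplotypes: dict                      # chrom -> int8 (n, 2, m_chrom)
    ids: np.ndarray                       # individual ids (str)
    sire: np.ndarray                      # index into arrays, -1 unknown
    dam: np.ndarray
    sex: np.ndarray                       # 'M'/'F'
    generation: np.ndarray
    causal_index: int                     # column within the X-local panel

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def causal_dose(self) -> np.ndarray:
        """True alt-allele count at the causal locus (males 0/1)."""
        hx = self.haplotypes[self.config.causal_chrom][:, :, self.causal_index]
        dose = hx.sum(axis=1).astype(np.int8)
        males = self.sex == "M"
        dose[males] = hx[males, 0]
        return dose

    @property
    def fertility_status(self) -> np.ndarray:
        """True per-individual fertility: females homozygous for the causal
        alt allele are infertile; everyone else is fertile."""
        dose = self.causal_dose()
        return ~((self.sex == "F") & (dose == 2))

    def causal_freq(self, generation: int | None = None) -> float:
        """Sex-aware causal alt-allele frequency (optionally one generation)."""
        mask = (np.ones(self.n_individuals, bool) if generation is None
                else self.generation == generation)
        dose = self.causal_dose()[mask].astype(float)
        weights = np.where(self.sex[mask] == "M", 1.0, 2.0)
        return float(dose.sum() / weights.sum())

    def genotype_codes(self, indices) -> np.ndarray:
        """Alt-allele codes across the full panel for the given individuals.

        Male X calls come out as 0/2 (hemizygous diploid dialect) because the
        single male X haplotype is stored duplicated.
        """
        indices = np.asarray(indices)
        parts = [self.haplotypes[c][indices].sum(axis=1, dtype=np.int8)
                 for c in self.chrom_slices]
        return np.concatenate(parts, axis=1)

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def pedigree_frame(self) -> pd.DataFrame:
        def name(i):
            return self.ids[i] if i >= 0 else "0"
        return pd.DataFrame({
            "id": self.ids,
            "sire": [name(i) for i in self.sire],
            "dam": [name(i) for i in self.dam],
            "sex": self.sex,
            "generation": self.generation,
        })


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def _marker_positions(rng, length: int, m: int) -> np.ndarray:
    spacing = length / m
    jitter = rng.uniform(0.05, 0.95, size=m)
    pos = np.floor((np.arange(m) + jitter) * spacing).astype(np.int64) + 1
    return pos


def _block_index(pos: np.ndarray, block_len: int) -> np.ndarray:
    _, inverse = np.unique((pos - 1) // block_len, return_inverse=True)
    return inverse


def _founder_haplotypes(rng, cfg: SimConfig, pos: np.ndarray,
                        blocks: np.ndarray, n_copies: int,
                        causal_local: int | None) -> np.ndarray:
    """Draw founder haplotype copies as mosaics of ancestral block haplotypes."""
    m = len(pos)
    K = cfg.n_ancestral_haplotypes
    out = np.empty((n_copies, m), dtype=np.int8)
    for b in range(blocks.max() + 1):
        cols = np.flatnonzero(blocks == b)
        # latent within-block frequency gradient
        p0, p1 = rng.uniform(0.15, 0.85, size=2)
        p = np.linspace(p0, p1, num=len(cols))
        anc = (rng.random((K, len(cols))) < p).astype(np.int8)
        weights = np.full(K, 1.0 / K)
        if causal_local is not None and blocks[causal_local] == b:
            j = np.flatnonzero(cols == causal_local)[0]
            anc[:, j] = 0
            anc[0, j] = 1           # ancestral haplotype 0 carries the alt
            f = cfg.causal_alt_freq
            weights = np.full(K, (1.0 - f) / (K - 1))
            weights[0] = f
        choice = rng.choice(K, size=n_copies, p=weights)
        out[:, cols] = anc[choice]
    return out


def _meiosis(rng, haps: np.ndarray, blocks: np.ndarray,
             p_switch: float) -> np.ndarray:
    """Recombinant gametes from parental haplotype pairs.

    ``haps`` is (n, 2, m); blocks are copied jointly, with a switch of the
    active parental haplotype at each block boundary with ``p_switch``.
    """
    n, _, m = haps.shape
    n_blocks = blocks.max() + 1
    start = rng.integers(0, 2, size=(n, 1))
    switches = rng.random((n, n_blocks - 1)) < p_switch if n_blocks > 1 \
        else np.empty((n, 0), bool)
    sel_blocks = (start + np.concatenate(
        [np.zeros((n, 1), int), np.cumsum(switches, axis=1)], axis=1)) % 2
    sel = sel_blocks.astype(np.int8)[:, blocks]       # (n, m)
    return np.where(sel == 0, haps[:, 0, :], haps[:, 1, :])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig) -> Population:
    """Breed a pedigreed population under the configured design.

    Founders are unrelated; each later generation is produced by mating a
    fixed number of fertile dams (litters of ``litter_size``, sire drawn per
    litter) drawn from the previous generation.  Homozygous-alt females are
    infertile and are never drawn as dams.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_lengths)

    # panel ------------------------------------------------------------
    pos_by_chrom, blocks_by_chrom = {}, {}
    causal_local = None
    for c in chroms:
        pos = _marker_positions(rng, cfg.chrom_lengths[c],
                                cfg.n_markers_per_chrom)
        if c == cfg.causal_chrom:
            i = int(np.argmin(np.abs(pos - cfg.causal_pos)))
            pos[i] = cfg.causal_pos
            if np.any(np.diff(pos) <= 0):        # collision with a neighbour
                pos = np.unique(pos)
            causal_local = int(np.searchsorted(pos, cfg.causal_pos))
        pos_by_chrom[c] = pos
        blocks_by_chrom[c] = _block_index(pos, cfg.ld_block_len)

    ids, chrom_col, pos_col = [], [], []
    chrom_slices, off = {}, 0
    for c in chroms:
        pos = pos_by_chrom[c]
        ids.extend(f"snp_{c}_{p}" for p in pos)
        chrom_col.extend([c] * len(pos))
        pos_col.extend(pos.tolist())
        chrom_slices[c] = slice(off, off + len(pos))
        off += len(pos)
    panel = MarkerPanel(np.array(ids, dtype=object),
                        np.array(chrom_col, dtype=object),
                        np.array(pos_col),
                        np.array(["C"] * off, dtype=object),
                        np.array(["T"] * off, dtype=object))

    p_switch = min(0.5, 1e-8 * cfg.ld_block_len)   # ~1 cM/Mb

    # founders ----------------------------------------------------------
    n_b, n_s = cfg.n_founder_boars, cfg.n_founder_sows
    n0 = n_b + n_s
    sex0 = np.array(["M"] * n_b + ["F"] * n_s)
    haplotypes = {}
    for c in chroms:
        blocks = blocks_by_chrom[c]
        cl = causal_local if c == cfg.causal_chrom else None
        if c == cfg.causal_chrom:
            # boars: one X copy (stored duplicated); sows: two
            copies = _founder_haplotypes(rng, cfg, pos_by_chrom[c], blocks,
                                         n_b + 2 * n_s, cl)
            h = np.empty((n0, 2, len(pos_by_chrom[c])), dtype=np.int8)
            h[:n_b, 0] = copies[:n_b]
            h[:n_b, 1] = copies[:n_b]
            h[n_b:] = copies[n_b:].reshape(n_s, 2, -1)
        else:
            copies = _founder_haplotypes(rng, cfg, pos_by_chrom[c], blocks,
                                         2 * n0, cl)
            h = copies.reshape(n0, 2, -1)
        haplotypes[c] = h

    sire = [np.full(n0, -1)]
    dam = [np.full(n0, -1)]
    sexes = [sex0]
    gens = [np.zeros(n0, int)]

    # later generations ---------------------------------------------------
    prev_range = np.arange(n0)
    prev_sex = sex0
    n_total = n0
    for g in range(1, cfg.n_generations):
        h_x_prev = haplotypes[cfg.causal_chrom]
        prev_idx = prev_range
        females = prev_idx[prev_sex == "F"]
        dose_f = h_x_prev[females][:, :, causal_local].sum(axis=1)
        fertile_females = females[dose_f < 2]
        males = prev_idx[prev_sex == "M"]
        if len(fertile_females) == 0 or len(males) == 0:
            raise ValueError(f"generation {g}: no eligible parents")
        n_dams = min(len(fertile_females), cfg.n_founder_sows)
        dams_g = rng.choice(fertile_females, size=n_dams, replace=False)
        n_sires = min(len(males), cfg.n_founder_boars)
        sires_pool = rng.choice(males, size=n_sires, replace=False)
        litter_sires = rng.choice(sires_pool, size=n_dams, replace=True)

        n_off = n_dams * cfg.litter_size
        off_dam = np.repeat(dams_g, cfg.litter_size)
        off_sire = np.repeat(litter_sires, cfg.litter_size)
        off_sex = np.where(rng.random(n_off) < 0.5, "F", "M")

        for c in chroms:
            blocks = blocks_by_chrom[c]
            m = haplotypes[c].shape[2]
            child = np.empty((n_off, 2, m), dtype=np.int8)
            dam_gam = _meiosis(rng, haplotypes[c][off_dam], blocks, p_switch)
            if c == cfg.causal_chrom:
                sire_x = haplotypes[c][off_sire, 0]  # transmitted intact
                fem = off_sex == "F"
                child[fem, 0] = sire_x[fem]
                child[fem, 1] = dam_gam[fem]
                child[~fem, 0] = dam_gam[~fem]       # sons: maternal X only
                child[~fem, 1] = dam_gam[~fem]
            else:
                child[:, 0] = _meiosis(rng, haplotypes[c][off_sire], blocks,
                                       p_switch)
                child[:, 1] = dam_gam
            haplotypes[c] = np.concatenate([haplotypes[c], child])
        sire.append(off_sire)
        dam.append(off_dam)
        sexes.append(off_sex)
        gens.append(np.full(n_off, g))
        prev_range = np.arange(n_total, n_total + n_off)
        prev_sex = off_sex
        n_total += n_off

    generation = np.concatenate(gens)
    sex = np.concatenate(sexes)
    all_ids = np.array([f"G{g}{'B' if s == 'M' else 'S'}{i:06d}"
                        for i, (g, s) in enumerate(zip(generation, sex))],
                       dtype=object)
    return Population(
        config=cfg,
        panel=panel,
        chrom_slices=chrom_slices,
        haplotypes=haplotypes,
        ids=all_ids,
        sire=np.concatenate(sire),
        dam=np.concatenate(dam),
        sex=sex,
        generation=generation,
        causal_index=causal_local,
    )


@dataclass
class CaseControlLabels:
    """A labelled case-control panel drawn from a simulated population."""

    sample_indices: np.ndarray       # into Population arrays
    sample_ids: list
    status: np.ndarray               # 1 case, 0 control
    n_true_cases: int
    n_false_cases: int

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.sample_ids, "status": self.status})


def simulate_case_labels(pop: Population,
                         config: SimConfig) -> CaseControlLabels:
    """Label cases and controls in the final generation, with label error.

    Each homozygous-alt (infertile) female is detected as a case with
    probability ``case_detection``; mislabelled cases — fertile females
    wrongly scored as affected — are added so the expected false fraction is
    ``case_label_error``.  Controls are drawn from the remaining fertile
    females (the stand-in for proven, littered sows).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0xCA5E])
    last = pop.generation.max()
    fem = np.flatnonzero((pop.sex == "F") & (pop.generation == last))
    if len(fem) == 0:
        raise ValueError("population has no final-generation females")
    dose = pop.causal_dose()[fem]
    altalt = fem[dose == 2]
    others = fem[dose < 2]

    detected = altalt[rng.random(len(altalt)) < cfg.case_detection]
    if cfg.n_cases is not None:
        if cfg.n_cases > len(fem):
            raise ValueError("requested case count exceeds available females")
        n_false = int(round(cfg.n_cases * cfg.case_label_error))
        n_true = min(cfg.n_cases - n_false, len(detected))
        n_false = cfg.n_cases - n_true
        true_cases = rng.choice(detected, size=n_true, replace=False)
        false_cases = rng.choice(others, size=n_false, replace=False)
    else:
        true_cases = detected
        e = cfg.case_label_error
        n_false = int(round(len(detected) * e / (1.0 - e))) if e < 1 else 0
        false_cases = rng.choice(others, size=n_false, replace=False)
    cases = np.concatenate([true_cases, false_cases]).astype(int)

    eligible = np.setdiff1d(others, false_cases)
    if cfg.n_controls > len(eligible):
        raise ValueError("requested control count exceeds eligible females")
    controls = rng.choice(eligible, size=cfg.n_controls, replace=False)

    idx = np.concatenate([cases, controls])
    status = np.concatenate([np.ones(len(cases), int),
                             np.zeros(len(controls), int)])
    return CaseControlLabels(
        sample_indices=idx,
        sample_ids=[str(s) for s in pop.ids[idx]],
        status=status,
        n_true_cases=len(true_cases),
        n_false_cases=len(false_cases),
    )


def simulate_ebvs(pop: Population, config: SimConfig) -> pd.DataFrame:
    """Breeding values for all fertile sows: truth plus Gaussian noise.

    EBV = effect x (true causal dosage) + N(0, residual SD) per trait, with a
    reliability drawn uniformly from ``reliability_range``.  Returns a long
    table (id, trait, ebv, reliability).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0xEB])
    sows = np.flatnonzero((pop.sex == "F") & pop.fertility_status)
    dose = pop.causal_dose()[sows].astype(float)
    frames = []
    for trait, effect in cfg.trait_effects.items():
        sd = cfg.trait_residual_sd.get(trait, 0.0)
        if sd < 0:
            raise ValueError(f"negative residual SD for {trait}")
        ebv = effect * dose + (rng.normal(0.0, sd, len(sows)) if sd > 0
                               else 0.0)
        rel = rng.uniform(*cfg.reliability_range, size=len(sows))
        frames.append(pd.DataFrame({
            "id": pop.ids[sows], "trait": trait,
            "ebv": ebv, "reliability": rel,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_dosage_group_ebvs(trait: str = "live_born_piglets",
                               n_sows: int | None = None,
                               seed: int = 0,
                               effect: float | None = None,
                               residual_sd: float | None = None
                               ) -> tuple[pd.DataFrame, dict]:
    """EBV panel with sows allocated to the reported dosage groups.

    Sows are assigned to the seven expected-dosage groups in the reported
    proportions (largest-remainder rounding so the counts sum exactly to
    ``n_sows``, default the trait's reported sample size); each sow's EBV is
    effect x dosage plus Gaussian noise whose SD is calibrated so the OLS
    standard error reproduces the reported one.  Returns the EBV table and
    an id -> dosage map.
    """
    n_trait, eff_pub, _, _ = landrace.TRAIT_EFFECTS[trait]
    n_sows = n_trait if n_sows is None else n_sows
    effect = eff_pub if effect is None else effect
    residual_sd = (landrace.calibrated_residual_sd(trait)
                   if residual_sd is None else residual_sd)
    rng = np.random.default_rng(seed)
    doses = np.array(list(landrace.DOSAGE_GROUPS))
    weights = np.array([n for n, _ in landrace.DOSAGE_GROUPS.values()],
                       dtype=float)
    exact = weights / weights.sum() * n_sows
    counts = np.floor(exact).astype(int)
    rem = np.argsort(exact - counts)[::-1]
    counts[rem[:n_sows - counts.sum()]] += 1
    x = np.repeat(doses, counts)
    ids = [f"sow{i}" for i in range(n_sows)]
    ebv = effect * x + rng.normal(0.0, residual_sd, n_sows)
    df = pd.DataFrame({"id": ids, "trait": trait, "ebv": ebv,
                       "reliability": 1.0})
    return df, dict(zip(ids, x))


def genotype_matrix(pop: Population, sample_ids) -> GenotypeMatrix:
    """Chip-style genotype matrix for the named individuals."""
    idx = pop.index_of(sample_ids)
    return GenotypeMatrix(
        samples=[str(s) for s in sample_ids],
        sex=pop.sex[idx],
        panel=pop.panel,
        codes=pop.genotype_codes(idx),
    )


def write_pedigree(pop: Population, path: str) -> None:
    pop.pedigree_frame().to_csv(path, sep="\t", index=False)


def write_ebvs(ebvs: pd.DataFrame, path: str) -> None:
    ebvs.to_csv(path, sep="\t", index=False)
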