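"""Expected mutant-allele dosage of sows from parental genotypes.

The locus is X-linked: a sire is hemizygous C or T, a dam is C/C or C/T
(T/T females are infertile, so a dam can never be T/T).  A daughter's
expected T-allele count given the parents is then a simple lookup — exact
when both parents are genotyped, and involving the sex-specific population
allele frequencies q_m (boars) and q_f (sows) when a parent is ungenotyped:

    sire \\ dam      C/C        C/T          unknown
    C               0          0.5          q_f
    T               1          1            1
    unknown         q_m        q_m + 0.5    q_m + q_f

Directly genotyped sows bypass the derivation: their dosage is their own
alt-allele count (0 or 1; fertile sows are never 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: grouping tolerance when tallying dosage values
GROUP_TOL = 1e-12

SIRE_GENOTYPES = ("C", "T", None)
DAM_GENOTYPES = ("C/C", "C/T", None)


@dataclass
class PopFreqs:
    """Sex-specific alt-allele frequencies among parents."""

    q_m: float
    q_f: float

    def __post_init__(self) -> None:
        if not (0 <= self.q_m <= 1 and 0 <= self.q_f <= 1):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class ParentGenotypes:
    sire: str | None          # "C", "T" or None (unknown)
    dam: str | None           # "C/C", "C/T" or None (unknown)

    def __post_init__(self) -> None:
        if self.sire not in SIRE_GENOTYPES:
            raise ValueError(f"inadmissible sire genotype {self.sire!r}")
        if self.dam == "T/T":
            raise ValueError("dam genotype T/T is inadmissible: homozygous "
                             "females are infertile and cannot be parents")
        if self.dam not in DAM_GENOTYPES:
            raise ValueError(f"inadmissible dam genotype {self.dam!r}")


@dataclass
class DosageAssignment:
    sow_id: str
    dosage: float
    provenance: str           # parental-genotype cell or "genotyped"


def estimate_parent_freqs(n_c_boars: int, n_t_boars: int,
                          n_cc_sows: int, n_ct_sows: int) -> PopFreqs:
    """q_m = T-boars / all boars; q_f = het sows / (2 x all sows)."""
    if min(n_c_boars, n_t_boars, n_cc_sows, n_ct_sows) < 0:
        raise ValueError("negative genotype count")
    boars = n_c_boars + n_t_boars
    sows = n_cc_sows + n_ct_sows
    if boars == 0 or sows == 0:
        raise ValueError("need at least one genotyped parent of each sex")
    return PopFreqs(q_m=n_t_boars / boars, q_f=n_ct_sows / (2 * sows))


def expected_dosage(pg: ParentGenotypes, f: PopFreqs,
                    condition_on_fertility: bool = False) -> float:
    """Expected daughter T-allele count for one parental-genotype cell.

    By default an ungenotyped dam transmits the alt allele with marginal
    probability q_f — exact when q_f is estimated from fertile dams, since a
    fertile dam is C/C or C/T and transmits T with probability
    P(C/T)/2 = q_f.  With ``condition_on_fertility`` q_f is instead treated
    as a whole-population (Hardy-Weinberg) frequency and the transmission
    probability from a necessarily non-T/T dam becomes q_f / (1 + q_f).
    """
    qf = f.q_f / (1.0 + f.q_f) if condition_on_fertility else f.q_f
    sire_t = {"C": 0.0, "T": 1.0, None: f.q_m}[pg.sire]
    dam_t = {"C/C": 0.0, "C/T": 0.5, None: qf}[pg.dam]
    return 1.0 if pg.sire == "T" else sire_t + dam_t


_CELL_NAMES = {
    ("C", "C/C"): "C-boar x C/C-sow",
    ("C", "C/T"): "C-boar x C/T-sow",
    ("C", None): "C-boar x ungenotyped sow",
    ("T", "C/C"): "T-boar",
    ("T", "C/T"): "T-boar",
    ("T", None): "T-boar",
    (None, "C/C"): "ungenotyped boar x C/C-sow",
    (None, "C/T"): "ungenotyped boar x C/T-sow",
    (None, None): "both parents ungenotyped",
}


def assign_dosages(pedigree: pd.DataFrame, parent_genotypes: dict,
                   freqs: PopFreqs, own_genotypes: dict | None = None,
                   condition_on_fertility: bool = False) -> list:
    """Per-sow dosage assignments from a pedigree and parental genotypes.

    ``pedigree`` needs columns (id, sire, dam) with "0" for unknown parents;
    ``parent_genotypes`` maps a parent id to "C"/"T" (boars) or
    "C/C"/"C/T" (dams).  Sows present in ``own_genotypes`` (id -> alt count
    0/1) bypass derivation.
    """
    own = own_genotypes or {}
    out = []
    for row in pedigree.itertuples(index=False):
        sid = str(row.id)
        if sid in own:
            out.append(DosageAssignment(sid, float(own[sid]), "genotyped"))
            continue
        sire_g = parent_genotypes.get(str(row.sire))
        dam_g = parent_genotypes.get(str(row.dam))
        pg = ParentGenotypes(sire_g, dam_g)
        d = expected_dosage(pg, freqs, condition_on_fertility)
        out.append(DosageAssignment(sid, d, _CELL_NAMES[(sire_g, dam_g)]))
    return out


def dosage_groups(assignments) -> pd.DataFrame:
    """Tally of sows per distinct dosage value, ascending.

    Values within ``GROUP_TOL`` of each other collapse into one group.
    Returns columns (dosage, n, n_parent_derived).
    """
    if not assignments:
        return pd.DataFrame(columns=["dosage", "n", "n_parent_derived"])
    order = sorted(assignments, key=lambda a: a.dosage)
    rows = []
    for a in order:
        if rows and abs(a.dosage - rows[-1][0]) <= GROUP_TOL:
            rows[-1][1] += 1
            rows[-1][2] += a.provenance != "genotyped"
        else:
            rows.append([a.dosage, 1, int(a.provenance != "genotyped")])
    return pd.DataFrame(rows, columns=["dosage", "n", "n_parent_derived"])


def write_dosages(assignments, path: str) -> None:
    pd.DataFrame([a.__dict__ for a in assignments]).to_csv(
        path, sep="\t", index=False)


def read_dosages(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sow_id": str})
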