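"""Genotype I/O, quality control, allele frequencies and concordance tables.

Genotypes are held as alt-allele counts (0/1/2, ``-1`` for missing) in a
sample x marker matrix.  The X chromosome is handled sex-aware throughout:
boars are hemizygous and are stored under a *diploid dialect* — a male X call
is exported/imported as homozygous (code 0 or 2) and contributes a single
allele to frequency computations.  A male X code of 1 is a data error.

Coordinates are 1-based inclusive everywhere (VCF/GFF3 convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

MISSING = -1

#: chromosome names treated as the X chromosome
X_NAMES = frozenset({"X", "chrX", "x"})


class GenotypeError(ValueError):
    """Malformed genotype data (bad codes, duplicate ids, dialect violation)."""


class QcError(ValueError):
    """Quality control removed every marker."""


def is_x(chrom: str) -> bool:
    return chrom in X_NAMES


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Ordered SNP panel: id, chromosome, 1-based position, ref/alt alleles."""

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.validate()

    def validate(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise GenotypeError(f"positions not strictly increasing on {c}")
        if np.any(self.ref == self.alt):
            raise GenotypeError("ref and alt allele identical for some marker")

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    @property
    def x_mask(self) -> np.ndarray:
        return np.fromiter((is_x(c) for c in self.chrom), dtype=bool,
                           count=self.n_markers)

    def subset(self, idx) -> "MarkerPanel":
        return MarkerPanel(self.ids[idx], self.chrom[idx], self.pos[idx],
                           self.ref[idx], self.alt[idx])

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.ids == marker_id)
        if len(hits) == 0:
            raise KeyError(marker_id)
        return int(hits[0])


@dataclass
class GenotypeMatrix:
    """Sample x marker alt-allele dosage codes with sex/X awareness."""

    samples: list
    sex: np.ndarray              # 'M' / 'F' per sample
    panel: MarkerPanel
    codes: np.ndarray            # int8, (n_samples, n_markers), -1 missing

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sex = np.asarray(self.sex, dtype="<U1")
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("duplicated sample ids")
        if self.codes.shape != (len(self.samples), self.panel.n_markers):
            raise GenotypeError("codes shape does not match samples x panel")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise GenotypeError("genotype codes must be in {-1, 0, 1, 2}")
        self._check_dialect()

    def _check_dialect(self) -> None:
        xm = self.panel.x_mask
        if not xm.any():
            return
        males = self.sex == "M"
        if males.any() and np.any(self.codes[np.ix_(males, xm)] == 1):
            raise GenotypeError(
                "male X genotype coded 1: hemizygous calls must use the "
                "homozygous dialect {0, 2}")

    # -- basics ------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.panel.n_markers

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker (all samples count)."""
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.codes != MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, total allele count) per marker, sex-aware on X."""
        codes = self.codes
        called = codes != MISSING
        males = (self.sex == "M")[:, None]
        xm = self.panel.x_mask[None, :]
        # weight per called genotype: 1 allele for a male X call, else 2
        w = np.where(males & xm, 1, 2) * called
        alt = np.where(males & xm, codes // 2, codes) * called
        return alt.sum(axis=0).astype(float), w.sum(axis=0).astype(float)

    def alt_freq(self) -> np.ndarray:
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    # -- subsetting ---------------------------------------------------------

    def subset_markers(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.sex, self.panel.subset(idx),
                              self.codes[:, idx])

    def subset_samples(self, ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        rows = np.array([lookup[s] for s in ids], dtype=int)
        return GenotypeMatrix(list(ids), self.sex[rows], self.panel,
                              self.codes[rows])


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write an uncompressed VCF 4.2 file (diploid dialect on male X)."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(gm.panel.chrom):          # preserves order
        length = int(gm.panel.pos[gm.panel.chrom == chrom].max()) + 1
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(gm.n_markers):
            rec = out.new_record(
                contig=str(gm.panel.chrom[j]),
                start=int(gm.panel.pos[j]) - 1,
                alleles=(str(gm.panel.ref[j]), str(gm.panel.alt[j])),
                id=str(gm.panel.ids[j]),
            )
            for i, s in enumerate(gm.samples):
                c = gm.codes[i, j]
                gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(int(c),
                                                           (None, None))
                rec.samples[s]["GT"] = gt
            out.write(rec)


def read_vcf(path: str, sex=None) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF into a GenotypeMatrix.

    ``sex`` maps sample id -> 'M'/'F'; unmapped samples default to 'F'
    (the association panels here are all-female).
    """
    sex = sex or {}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            raise GenotypeError("duplicated sample ids in VCF")
        ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeError(
                    f"record at {rec.chrom}:{rec.pos} is not biallelic")
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue                     # half-missing -> missing
                col[i] = sum(gt)
            rows.append(col)
    panel = MarkerPanel(ids, chroms, poss, refs, alts)
    codes = (np.stack(rows, axis=1) if rows
             else np.empty((len(samples), 0), dtype=np.int8))
    sx = np.array([sex.get(s, "F") for s in samples])
    return GenotypeMatrix(samples, sx, panel, codes)


def write_ped_map(gm: GenotypeMatrix, prefix: str) -> None:
    """Write PLINK text PED/MAP (``prefix.ped`` / ``prefix.map``)."""
    with open(prefix + ".map", "w") as out:
        for j in range(gm.n_markers):
            out.write(f"{gm.panel.chrom[j]}\t{gm.panel.ids[j]}\t0\t"
                      f"{gm.panel.pos[j]}\n")
    with open(prefix + ".ped", "w") as out:
        for i, s in enumerate(gm.samples):
            sexcode = "1" if gm.sex[i] == "M" else "2"
            fields = ["FAM", s, "0", "0", sexcode, "-9"]
            for j in range(gm.n_markers):
                c = gm.codes[i, j]
                r, a = gm.panel.ref[j], gm.panel.alt[j]
                pair = {0: (r, r), 1: (r, a), 2: (a, a)}.get(int(c), ("0", "0"))
                fields.extend(pair)
            out.write("\t".join(map(str, fields)) + "\n")


def read_ped_map(prefix: str, sex=None) -> GenotypeMatrix:
    """Read PLINK text PED/MAP.  Half-missing allele pairs become missing.

    Sex is taken from PED column 5 unless overridden via ``sex``.
    """
    sex = sex or {}
    mp = pd.read_csv(prefix + ".map", sep=r"\s+", header=None,
                     names=["chrom", "id", "cm", "pos"], dtype=str)
    panel = MarkerPanel(mp["id"].to_numpy(), mp["chrom"].to_numpy(),
                        mp["pos"].astype(int).to_numpy(),
                        np.array(["A"] * len(mp), dtype=object),
                        np.array(["B"] * len(mp), dtype=object))
    m = panel.n_markers
    samples, sexes, rows = [], [], []
    allele_sets: list[set] = [set() for _ in range(m)]
    raw: list[list[tuple[str, str]]] = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeError("PED record has wrong field count")
            samples.append(parts[1])
            sexes.append(sex.get(parts[1], "M" if parts[4] == "1" else "F"))
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            raw.append(pairs)
            for j, (a, b) in enumerate(pairs):
                allele_sets[j].update(x for x in (a, b) if x != "0")
    if len(set(samples)) != len(samples):
        raise GenotypeError("duplicated sample ids in PED")
    # PED carries no ref/alt polarity: alleles are assigned lexicographically
    ref = np.empty(m, dtype=object)
    alt = np.empty(m, dtype=object)
    for j, alleles in enumerate(allele_sets):
        ordered = sorted(alleles)
        if len(ordered) > 2:
            raise GenotypeError(f"marker {panel.ids[j]} has >2 alleles")
        ref[j] = ordered[0] if ordered else "A"
        alt[j] = ordered[1] if len(ordered) > 1 else ("B" if ref[j] != "B"
                                                      else "A")
    panel = MarkerPanel(panel.ids, panel.chrom, panel.pos, ref, alt)
    for pairs in raw:
        row = np.full(m, MISSING, dtype=np.int8)
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            row[j] = (a == alt[j]) + (b == alt[j])
        rows.append(row)
    codes = (np.stack(rows) if rows
             else np.empty((0, m), dtype=np.int8))
    return GenotypeMatrix(samples, np.array(sexes), panel, codes)


def read_genotypes(path: str, fmt: str | None = None, sex=None
                   ) -> GenotypeMatrix:
    """Read genotypes from VCF or PED/MAP; format inferred from extension."""
    if fmt is None:
        low = path.lower()
        if low.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif low.endswith(".ped") or os.path.exists(path + ".ped"):
            fmt = "ped"
        else:
            raise ValueError(f"cannot infer genotype format of {path}")
    if fmt == "vcf":
        return read_vcf(path, sex=sex)
    if fmt == "ped":
        prefix = path[:-4] if path.lower().endswith(".ped") else path
        return read_ped_map(prefix, sex=sex)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(gm: GenotypeMatrix, path: str, fmt: str = "vcf") -> None:
    if fmt == "vcf":
        write_vcf(gm, path)
    elif fmt == "ped":
        prefix = path[:-4] if path.lower().endswith(".ped") else path
        write_ped_map(gm, prefix)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype TSV with columns (id, status), status in {0, 1}."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not set(df["status"]).issubset({0, 1}):
        raise ValueError("phenotype status must be 0/1")
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    n_input: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_retained: int
    min_call_rate: float
    min_maf: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(gm: GenotypeMatrix, min_call_rate: float = 0.90,
              min_maf: float = 0.01) -> tuple[GenotypeMatrix, QcReport]:
    """Retain markers with call rate > ``min_call_rate`` and MAF > ``min_maf``.

    Both comparisons are strict, mirroring the filtering rule "calling rates
    higher than 90% and minor allele frequency above 1%".  MAF uses sex-aware
    allele totals on the X.  Markers failing call rate are counted there;
    of the remainder, markers failing MAF are counted under MAF.
    """
    if not (0 < min_call_rate < 1 and 0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    cr_ok = gm.call_rate() > min_call_rate
    maf = gm.maf()
    maf_ok = np.nan_to_num(maf, nan=0.0) > min_maf
    keep = cr_ok & maf_ok
    report = QcReport(
        n_input=gm.n_markers,
        n_fail_call_rate=int((~cr_ok).sum()),
        n_fail_maf=int((cr_ok & ~maf_ok).sum()),
        n_retained=int(keep.sum()),
        min_call_rate=min_call_rate,
        min_maf=min_maf,
    )
    if gm.n_markers and not keep.any():
        raise QcError("quality control removed every marker")
    return gm.subset_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# allele frequency and concordance
# ---------------------------------------------------------------------------

def allele_frequency(female_counts, male_counts=None) -> float:
    """Alt-allele frequency from genotype class counts.

    ``female_counts`` is (n ref/ref, n ref/alt, n alt/alt); each female
    contributes two alleles.  ``male_counts`` is an optional (n ref, n alt)
    pair of hemizygous males contributing one allele each.
    """
    counts = list(female_counts) + (list(male_counts) if male_counts else [])
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype count")
    n_rr, n_ra, n_aa = female_counts
    alt = n_ra + 2 * n_aa
    total = 2 * (n_rr + n_ra + n_aa)
    if male_counts is not None:
        m_ref, m_alt = male_counts
        alt += m_alt
        total += m_ref + m_alt
    if total == 0:
        raise ValueError("no alleles observed")
    return alt / total


GENOTYPE_CLASSES = ("ref/ref", "ref/alt", "alt/alt", "missing")


@dataclass
class ConcordanceTable:
    """Genotype-class x phenotype-class counts, missing calls kept explicit."""

    counts: pd.DataFrame      # index GENOTYPE_CLASSES, one column per class

    @classmethod
    def from_counts(cls, by_class: dict) -> "ConcordanceTable":
        """Build from ``{class: (n_refref, n_refalt, n_altalt)}`` counts."""
        df = pd.DataFrame(
            {k: list(v) + [0] * (4 - len(v)) for k, v in by_class.items()},
            index=list(GENOTYPE_CLASSES), dtype=int)
        return cls(df)

    def margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __getitem__(self, key):
        return self.counts.loc[key]


def concordance_table(gm: GenotypeMatrix, marker_id: str,
                      classes: dict) -> ConcordanceTable:
    """Cross-tabulate genotype at one marker against phenotype classes.

    ``classes`` maps every sample id to its phenotype class label.  Samples
    with a missing genotype are counted in an explicit "missing" row.
    """
    j = gm.panel.index_of(marker_id)
    missing_class = [s for s in gm.samples if s not in classes]
    if missing_class:
        raise ValueError(f"samples without phenotype class: "
                         f"{missing_class[:3]}...")
    labels = sorted(set(classes[s] for s in gm.samples))
    df = pd.DataFrame(0, index=list(GENOTYPE_CLASSES), columns=labels,
                      dtype=int)
    male_x = gm.panel.x_mask[j]
    for i, s in enumerate(gm.samples):
        c = int(gm.codes[i, j])
        if c == MISSING:
            row = "missing"
        elif male_x and gm.sex[i] == "M":
            row = "ref/ref" if c == 0 else "alt/alt"
        else:
            row = GENOTYPE_CLASSES[c]
        df.loc[row, classes[s]] += 1
    return ConcordanceTable(df)
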