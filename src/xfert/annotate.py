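"""Coding-consequence classification and candidate-variant filtering.

A deliberately small consequence caller: one transcript model per variant,
codon-level classification of SNVs (stop_gained / missense / synonymous),
mod-3 classification of CDS indels (frameshift / inframe_indel), and
everything else non_coding.  Protein change notation uses "X" for a stop
(HGVS "*" is accepted on parse).

Candidate filtering reproduces the positional-cloning logic used to pin a
causal variant inside an associated region: keep variants of the wanted
consequence classes that every obligate carrier carries and that are absent
from all samples of an unaffected out-population.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import gffutils
import pyfaidx
from Bio.Seq import Seq

CODING_CLASSES = ("stop_gained", "missense", "synonymous",
                  "frameshift", "inframe_indel")
ALL_CLASSES = CODING_CLASSES + ("non_coding",)


class ReferenceMismatch(ValueError):
    """Variant ref allele disagrees with the transcript reference sequence."""


@dataclass
class TranscriptModel:
    """Minimal transcript: ordered CDS intervals plus their reference sequence.

    ``cds_intervals`` are 1-based inclusive genomic intervals in ascending
    genomic order; ``interval_seqs`` hold the matching plus-strand reference
    sequence.  For a minus-strand transcript the coding sequence is the
    reverse complement read through the intervals 3'->5' genomically.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: list            # [(start, end), ...] ascending
    interval_seqs: list            # plus-strand sequence per interval
    codon_table: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = 0
        for (s, e), seq in zip(self.cds_intervals, self.interval_seqs):
            if s <= prev_end:
                raise ValueError("CDS intervals must be ordered, disjoint")
            if e - s + 1 != len(seq):
                raise ValueError("interval sequence length mismatch")
            prev_end = e
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3

    def cds_sequence(self) -> str:
        plus = "".join(self.interval_seqs)
        if self.strand == "+":
            return plus
        return str(Seq(plus).reverse_complement())

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, None if intronic."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds_intervals):
                if s <= pos <= e:
                    return offset + (e - pos) + 1
                offset += e - s + 1
        return None

    def reference_base(self, pos: int) -> str | None:
        for (s, e), seq in zip(self.cds_intervals, self.interval_seqs):
            if s <= pos <= e:
                return seq[pos - s]
        return None

    @classmethod
    def from_gff3(cls, gff_path: str, fasta_path: str,
                  transcript_id: str | None = None,
                  codon_table: int = 1) -> "TranscriptModel":
        """Build a transcript model from a GFF3 file and reference FASTA."""
        db = gffutils.create_db(gff_path, ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
        cds = [f for f in db.features_of_type("CDS")]
        if transcript_id is not None:
            cds = [f for f in cds
                   if transcript_id in f.attributes.get("Parent", [])
                   or f.attributes.get("ID", [""])[0] == transcript_id]
        if not cds:
            raise ValueError("no CDS features found for transcript")
        cds.sort(key=lambda f: f.start)
        chrom = cds[0].seqid
        strand = cds[0].strand
        fasta = pyfaidx.Fasta(fasta_path)
        seqs = [str(fasta[chrom][f.start - 1:f.end]).upper() for f in cds]
        tid = (transcript_id
               or cds[0].attributes.get("Parent", ["transcript"])[0])
        return cls(tid, chrom, strand,
                   [(f.start, f.end) for f in cds], seqs, codon_table)


@dataclass
class SeqVariant:
    """A genomic variant with optional per-sample alt-allele counts.

    ``genotypes`` maps sample id -> alt-allele count; hemizygous males use
    0/1.
    """

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt allele are identical")


@dataclass
class Consequence:
    kind: str                     # one of ALL_CLASSES
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def notation(self) -> str | None:
        if self.kind in ("stop_gained", "missense", "synonymous"):
            return protein_notation(self)
        return None


def classify_consequence(v: SeqVariant, t: TranscriptModel) -> Consequence:
    """Classify a variant against one transcript model.

    SNVs inside the CDS are translated strand-aware (alt codon producing a
    stop -> stop_gained; same amino acid -> synonymous; else missense).
    Indels wholly inside the CDS are frameshift iff the length change is not
    a multiple of 3, else inframe_indel.  Variants outside the CDS — or
    straddling a CDS boundary, which is classified conservatively — are
    non_coding.
    """
    if v.chrom != t.chrom:
        raise ValueError(f"variant on {v.chrom}, transcript on {t.chrom}")
    span = range(v.pos, v.pos + max(len(v.ref), 1))
    inside = [t.genomic_to_cds(p) is not None for p in span]
    if not any(inside):
        return Consequence("non_coding")
    if not all(inside):
        warnings.warn(f"variant at {v.chrom}:{v.pos} spans a CDS boundary; "
                      "classified non_coding", stacklevel=2)
        return Consequence("non_coding")
    # reference integrity check on the first base
    ref_base = t.reference_base(v.pos)
    if ref_base is not None and v.ref[0].upper() != ref_base.upper():
        raise ReferenceMismatch(
            f"ref allele {v.ref!r} at {v.chrom}:{v.pos} does not match "
            f"reference base {ref_base!r}")

    if len(v.ref) == 1 and len(v.alt) == 1:
        cds_pos = t.genomic_to_cds(v.pos)
        cds = t.cds_sequence()
        codon_index = (cds_pos - 1) // 3 + 1
        within = (cds_pos - 1) % 3
        codon = cds[(codon_index - 1) * 3: codon_index * 3]
        alt_base = v.alt if t.strand == "+" else str(
            Seq(v.alt).reverse_complement())
        alt_codon = codon[:within] + alt_base.upper() + codon[within + 1:]
        ref_aa = str(Seq(codon).translate(table=t.codon_table))
        alt_aa = str(Seq(alt_codon).translate(table=t.codon_table))
        if alt_aa == "*":
            return Consequence("stop_gained", codon_index, ref_aa, "X")
        if alt_aa == ref_aa:
            return Consequence("synonymous", codon_index, ref_aa, alt_aa)
        return Consequence("missense", codon_index, ref_aa, alt_aa)

    # indel wholly inside the CDS
    cds_pos = t.genomic_to_cds(v.pos)
    codon_index = (cds_pos - 1) // 3 + 1
    if (len(v.ref) - len(v.alt)) % 3 != 0:
        return Consequence("frameshift", codon_index)
    return Consequence("inframe_indel", codon_index)


def protein_notation(c: Consequence) -> str:
    """"p.<refAA><codon><altAA>" with X for a premature stop."""
    if c.kind not in ("stop_gained", "missense", "synonymous"):
        raise ValueError(f"no protein notation for class {c.kind!r}")
    return f"p.{c.ref_aa}{c.codon_index}{c.alt_aa}"


_NOTATION_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")


def parse_protein_notation(s: str) -> tuple[str, int, str]:
    """Parse "p.R212X" (or HGVS-style "p.R212*") back to its fields."""
    m = _NOTATION_RE.match(s)
    if not m:
        raise ValueError(f"cannot parse protein notation {s!r}")
    ref_aa, idx, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    return ref_aa, idx, "X" if alt_aa == "*" else alt_aa


@dataclass
class AnnotatedVariant:
    variant: SeqVariant
    consequence: Consequence


def filter_candidates(variants, region, classes, carriers=(),
                      absent_in=()):
    """Positional-cloning filter over annotated variants.

    ``variants`` is an iterable of AnnotatedVariant; ``region`` is
    (chrom, start, end) with inclusive bp bounds.  A variant survives if it
    lies inside the region, belongs to one of the wanted ``classes``, every
    obligate ``carrier`` sample carries >= 1 alt allele, and every
    ``absent_in`` sample carries none.  Returns (kept, per-class tally of the
    kept variants).
    """
    chrom, start, end = region
    if start > end:
        raise ValueError("malformed region: start > end")
    classes = set(classes)
    kept, tally = [], {}
    for av in variants:
        v = av.variant
        for s in list(carriers) + list(absent_in):
            if s not in v.genotypes:
                raise KeyError(f"sample {s!r} has no genotype for "
                               f"{v.chrom}:{v.pos}")
        if v.chrom != chrom or not (start <= v.pos <= end):
            continue
        if av.consequence.kind not in classes:
            continue
        if any(v.genotypes[s] < 1 for s in carriers):
            continue
        if any(v.genotypes[s] > 0 for s in absent_in):
            continue
        kept.append(av)
        k = av.consequence.kind
        tally[k] = tally.get(k, 0) + 1
    return kept, tally


def truncation_fraction(stop_codon_index: int, protein_length: int) -> float:
    """Percent of the protein lost to a premature stop (the stop residue and
    everything downstream count as missing)."""
    if not 1 <= stop_codon_index <= protein_length:
        raise ValueError("stop codon index outside the protein")
    return 100.0 * (protein_length - stop_codon_index + 1) / protein_length
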