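"""Candidate de novo mutation calling from joint variant records.

Two candidate generators are provided:

* trio mode — a genotype-level Mendelian-violation rule: the embryo's
  genotype carries an alt allele present in neither parent's genotype.  This
  deliberately over-calls (parental mosaics whose genotype is 0/0 but whose
  reads carry the allele slip through); the downstream filter cascade is
  what removes them, and that division of labour is the point of the
  pipeline.
* somatic mode — an embryo-vs-one-parent comparison in the tumour/normal
  style: any embryo alt read with zero alt reads in the named parent.  The
  two per-parent comparisons are intersected downstream.

Both run after a basic cohort-wide depth/quality gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import Pedigree, Trio, VariantRecord


@dataclass
class CandidateDNM:
    """An embryo variant absent from the compared parent genotype(s)."""

    embryo: str
    record: VariantRecord
    vaf: float
    father_alt_reads: int
    mother_alt_reads: int
    source: str  # "trio" or "somatic"
    parent: str | None = None  # somatic mode: which parent was compared
    annotations: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.embryo, *self.record.key)

    @property
    def locus(self) -> tuple[str, int]:
        return (self.record.chrom, self.record.pos)

    @property
    def chrom(self) -> str:
        return self.record.chrom

    @property
    def pos0(self) -> int:
        return self.record.pos0

    @property
    def is_indel(self) -> bool:
        return self.record.is_indel

    @property
    def surviving(self) -> bool:
        return not self.flags


def basic_quality_gate(
    records: Sequence[VariantRecord],
    min_depth: int = 10,
    min_qual: float = 10.0,
) -> list[VariantRecord]:
    """Keep records with QUAL strictly above ``min_qual`` (QUAL <= 10 is the
    low-quality condition) and per-sample depth >= ``min_depth`` in every
    cohort sample."""
    kept: list[VariantRecord] = []
    for rec in records:
        if rec.qual <= min_qual:
            continue
        ok = True
        for name, call in rec.samples.items():
            if call.depth is None:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos} sample {name}: missing depth; record rejected"
                )
                ok = False
                break
            if call.depth < min_depth:
                ok = False
                break
        if ok:
            kept.append(rec)
    return kept


def call_trio_dnms(
    records: Sequence[VariantRecord], trio: Trio
) -> list[CandidateDNM]:
    """Mendelian-violation candidates for one trio: embryo genotype carries
    the alt, neither parent genotype does.  Parental alt read counts are
    recorded for the downstream noise filters but do not gate here."""
    out: list[CandidateDNM] = []
    for rec in records:
        if trio.embryo not in rec.samples:
            warnings.warn(f"{rec.chrom}:{rec.pos}: embryo {trio.embryo} absent; skipped")
            continue
        embryo_call = rec.samples[trio.embryo]
        if not embryo_call.has_alt:
            continue
        father = rec.samples.get(trio.father)
        mother = rec.samples.get(trio.mother)
        if father is None or mother is None:
            warnings.warn(f"{rec.chrom}:{rec.pos}: a parent of {trio.embryo} absent; skipped")
            continue
        if father.has_alt or mother.has_alt:
            continue
        out.append(
            CandidateDNM(
                embryo=trio.embryo,
                record=rec,
                vaf=embryo_call.vaf,
                father_alt_reads=father.ad_alt,
                mother_alt_reads=mother.ad_alt,
                source="trio",
            )
        )
    return out


def call_cohort_dnms(
    records: Sequence[VariantRecord], pedigree: Pedigree
) -> list[CandidateDNM]:
    """Trio-mode candidates for every trio in the pedigree."""
    out: list[CandidateDNM] = []
    for trio in pedigree.trios:
        out.extend(call_trio_dnms(records, trio))
    return out


def call_somatic_pairwise(
    records: Sequence[VariantRecord],
    embryo: str,
    parent: str,
    min_alt_reads: int = 1,
) -> list[CandidateDNM]:
    """Tumour/normal style candidates for one embryo against one parent:
    embryo shows >= min_alt_reads alt reads, the parent shows none."""
    out: list[CandidateDNM] = []
    for rec in records:
        if embryo not in rec.samples or parent not in rec.samples:
            continue
        embryo_call = rec.samples[embryo]
        parent_call = rec.samples[parent]
        if embryo_call.ad_alt < min_alt_reads or parent_call.ad_alt != 0:
            continue
        out.append(
            CandidateDNM(
                embryo=embryo,
                record=rec,
                vaf=embryo_call.vaf,
                father_alt_reads=parent_call.ad_alt,
                mother_alt_reads=0,
                source="somatic",
                parent=parent,
            )
        )
    return out


def call_somatic_cohort(
    records: Sequence[VariantRecord], pedigree: Pedigree, min_alt_reads: int = 1
) -> list[CandidateDNM]:
    """Somatic-mode candidates for every embryo against each of its parents.

    Both per-parent comparisons are returned; the cascade's intersection
    stage keeps only calls present against both parents.
    """
    out: list[CandidateDNM] = []
    for trio in pedigree.trios:
        for parent in (trio.father, trio.mother):
            out.extend(
                call_somatic_pairwise(records, trio.embryo, parent, min_alt_reads)
            )
    return out
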