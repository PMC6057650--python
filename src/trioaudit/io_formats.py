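"""Genomic data model and plain-text format I/O.

This module owns the in-memory containers the rest of the pipeline operates
on — reference genomes, interval tracks, normalized variant records and
pedigrees — and the conversions between them and the standard on-disk
formats (FASTA, 3-column BED, VCFv4.2 with GT/AD/DP, and a TSV pedigree).

Coordinate conventions: all internal coordinates (interval tracks, off-target
site spans) are 0-based half-open.  ``VariantRecord.pos`` keeps the VCF
1-based convention because it is written back out verbatim; ``pos0`` exposes
the 0-based position for interval arithmetic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from pyfaidx import Fasta

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file does not satisfy the format contract (missing fields etc.)."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A reference assembly held as uppercase DNA strings keyed by chromosome."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            up = seq.upper()
            if set(up) - DNA_ALPHABET:
                bad = sorted(set(up) - DNA_ALPHABET)
                raise FormatError(f"chromosome {name}: non-DNA characters {bad}")
            self.sequences[name] = up

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice of a chromosome."""
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------


@dataclass
class IntervalTrack:
    """A set of genomic intervals (0-based half-open), e.g. repeats."""

    intervals: list[tuple[str, int, int]]
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad interval {chrom}:{start}-{end}")

    def merge(self) -> "IntervalTrack":
        return merge_intervals(self)

    def covered_bases(self) -> int:
        merged = self.merge()
        return sum(e - s for _, s, e in merged.intervals)

    def _index(self) -> dict[str, tuple[list[int], list[int]]]:
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, s, e in self.merge().intervals:
            starts, ends = by_chrom.setdefault(chrom, ([], []))
            starts.append(s)
            ends.append(e)
        return by_chrom

    def contains(self, chrom: str, pos: int, adjacency: int = 0) -> bool:
        """True if ``pos`` (0-based) lies inside, or within ``adjacency``
        bases of, any interval on ``chrom``."""
        idx = getattr(self, "_cached_index", None)
        if idx is None:
            idx = self._index()
            object.__setattr__(self, "_cached_index", idx)
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        i = bisect.bisect_right(starts, pos + adjacency) - 1
        return i >= 0 and pos < ends[i] + adjacency


def merge_intervals(track: IntervalTrack) -> IntervalTrack:
    """Collapse a track to disjoint, sorted intervals covering the same bases.

    Abutting intervals ([0,5) and [5,9)) are joined.
    """
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(track.intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return IntervalTrack(out, label=track.label)


def read_bed(path: str | Path, label: str = "") -> IntervalTrack:
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line with <3 columns: {line!r}")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalTrack(intervals, label=label or Path(path).stem)


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    """3-column BED, 0-based half-open, sorted by (chrom, start)."""
    with open(path, "w") as fh:
        for chrom, start, end in sorted(track.intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Variant records
# ---------------------------------------------------------------------------


@dataclass
class SampleCall:
    """Per-sample evidence at one variant locus."""

    gt: tuple[int, int]  # allele indices; 0 = ref, 1 = the record's alt
    ad_ref: int
    ad_alt: int
    depth: int

    def __post_init__(self) -> None:
        if self.ad_ref + self.ad_alt > self.depth:
            raise ValueError(
                f"AD sums to {self.ad_ref + self.ad_alt} > DP {self.depth}"
            )

    @property
    def vaf(self) -> float:
        return self.ad_alt / self.depth if self.depth else 0.0

    @property
    def has_alt(self) -> bool:
        return 1 in self.gt


@dataclass
class VariantRecord:
    """One normalized (single-alt) variant locus across the joint cohort."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    samples: dict[str, SampleCall]

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("empty allele")
        if self.ref == self.alt:
            raise ValueError("ref == alt")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def vaf(self, sample: str) -> float:
        return self.samples[sample].vaf


def read_joint_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a joint multi-sample VCF into normalized per-alt records.

    Multiallelic rows are split into one record per alt allele, keeping the
    shared DP (the ``bcftools norm -m -any`` convention): the split record's
    GT maps the chosen alt to allele 1 and every other allele to 0, and its
    AD keeps the row's REF depth plus the chosen alt's depth.

    Returns (records, sample names in column order).
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for row in vcf:
            alts = row.alts or ()
            for k, alt in enumerate(alts):
                samples: dict[str, SampleCall] = {}
                for name in sample_names:
                    call = row.samples[name]
                    ad = call.get("AD")
                    dp = call.get("DP")
                    if ad is None or dp is None:
                        raise FormatError(
                            f"{row.chrom}:{row.pos} sample {name}: missing AD/DP"
                        )
                    gt_raw = call.get("GT") or (0, 0)
                    gt = tuple(1 if a == k + 1 else 0 for a in gt_raw)
                    if len(gt) == 1:
                        gt = (gt[0], gt[0])
                    samples[name] = SampleCall(
                        gt=gt,  # type: ignore[arg-type]
                        ad_ref=int(ad[0]),
                        ad_alt=int(ad[k + 1]),
                        depth=int(dp),
                    )
                records.append(
                    VariantRecord(
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=row.ref,
                        alt=str(alt),
                        qual=float(row.qual) if row.qual is not None else 0.0,
                        samples=samples,
                    )
                )
    return records, sample_names


def _fmt_qual(q: float) -> str:
    return f"{q:g}"


def write_joint_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write normalized records as a plain-text VCFv4.2 file.

    The writer is byte-stable: writing the result of :func:`read_joint_vcf`
    on its own output reproduces the file exactly.
    """
    if contigs is None:
        contigs = {}
        for rec in records:
            end = rec.pos + len(rec.ref)
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), end)
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = "\t".join(
        ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        + list(samples)
    )
    lines.append(header)
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        cols = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            rec.alt,
            _fmt_qual(rec.qual),
            ".",
            ".",
            "GT:AD:DP",
        ]
        for name in samples:
            call = rec.samples[name]
            gt = "/".join(str(a) for a in call.gt)
            cols.append(f"{gt}:{call.ad_ref},{call.ad_alt}:{call.depth}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trio:
    father: str
    mother: str
    embryo: str


@dataclass
class Pedigree:
    """Trio structure plus the treatment-group assignment of each embryo."""

    trios: list[Trio]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for trio in self.trios:
            if trio.embryo in seen:
                raise ValueError(f"embryo {trio.embryo} appears in two trios")
            seen.add(trio.embryo)
        for embryo in seen:
            if embryo not in self.group_of:
                raise ValueError(f"embryo {embryo} has no treatment group")

    @property
    def embryos(self) -> list[str]:
        return [t.embryo for t in self.trios]

    @property
    def parents(self) -> list[str]:
        out: list[str] = []
        for t in self.trios:
            for p in (t.father, t.mother):
                if p not in out:
                    out.append(p)
        return out

    @property
    def samples(self) -> list[str]:
        """All cohort samples, parents first then embryos."""
        return self.parents + self.embryos

    def trio_of(self, embryo: str) -> Trio:
        for t in self.trios:
            if t.embryo == embryo:
                return t
        raise KeyError(embryo)

    def parents_of(self, embryo: str) -> tuple[str, str]:
        t = self.trio_of(embryo)
        return (t.father, t.mother)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for embryo in self.embryos:
            out.setdefault(self.group_of[embryo], []).append(embryo)
        return out


def read_pedigree_tsv(path: str | Path) -> Pedigree:
    """Pedigree TSV: columns sample, role (father/mother/embryo), trio_id, group."""
    rows: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("sample\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"pedigree line with {len(fields)} columns: {line!r}")
            rows.append(tuple(fields))  # type: ignore[arg-type]
    by_trio: dict[str, dict[str, str]] = {}
    group_of: dict[str, str] = {}
    embryo_order: list[tuple[str, str]] = []
    for sample, role, trio_id, group in rows:
        if role in ("father", "mother"):
            by_trio.setdefault(trio_id, {})[role] = sample
        elif role == "embryo":
            embryo_order.append((trio_id, sample))
            group_of[sample] = group
        else:
            raise FormatError(f"unknown pedigree role {role!r}")
    trios = []
    for trio_id, embryo in embryo_order:
        info = by_trio.get(trio_id, {})
        if "father" not in info or "mother" not in info:
            raise FormatError(f"trio {trio_id}: missing a parent")
        trios.append(Trio(info["father"], info["mother"], embryo))
    return Pedigree(trios=trios, group_of=group_of)


def write_pedigree_tsv(pedigree: Pedigree, path: str | Path) -> None:
    lines = ["sample\trole\ttrio_id\tgroup"]
    trio_ids: dict[tuple[str, str], str] = {}
    for t in pedigree.trios:
        pair = (t.father, t.mother)
        if pair not in trio_ids:
            trio_ids[pair] = f"trio{len(trio_ids) + 1}"
    written: set[str] = set()
    for t in pedigree.trios:
        tid = trio_ids[(t.father, t.mother)]
        for sample, role in ((t.father, "father"), (t.mother, "mother")):
            if sample not in written:
                lines.append(f"{sample}\t{role}\t{tid}\t-")
                written.add(sample)
    for t in pedigree.trios:
        tid = trio_ids[(t.father, t.mother)]
        lines.append(f"{t.embryo}\tembryo\t{tid}\t{pedigree.group_of[t.embryo]}")
    Path(path).write_text("\n".join(lines) + "\n")
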