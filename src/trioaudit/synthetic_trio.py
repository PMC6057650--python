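"""Synthetic whole-genome trio cohorts with a truth ledger.

Generates the statistical structure the trio DNM analysis assumes, at toy
genome scale:

* a random reference with annotated repeat intervals and embedded
  microsatellite runs;
* Mendelian-inherited heterozygous variants (each parental het transmits to
  each offspring with probability 1/2);
* embryonic de novo mutations whose allele fraction follows the cell-stage
  model VAF = 0.5 * 2**(1 - s) for a heterozygous mutation arising in one
  cell of a 2**(s-1)-cell embryo (stage 1: 0.5, stage 2: 0.25, ...);
* low-VAF parental mosaic variants that leak into embryos (transmitted
  independently to each embryo with probability equal to the parental VAF),
  the main source of false DNMs shared between siblings;
* microsatellite-adjacent artifact indels in embryo evidence only,
  emulating alignment false positives at un-annotated repeats;
* on-target (and optional off-target) CRISPR edit alleles with mosaicism.

Read evidence is depth-sampled per sample and locus: total depth is Poisson
with the configured mean, variant reads are Binomial(depth, VAF), and
samples that do not carry an allele acquire stray variant reads at a small
per-read error rate so the downstream noise filters have realistic input.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .guide_offtarget import GuideSpec, OffTargetSite
from .io_formats import (
    Genome,
    IntervalTrack,
    Pedigree,
    SampleCall,
    VariantRecord,
    write_bed,
    write_joint_vcf,
    write_pedigree_tsv,
)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate the trio WGS design this pipeline audits: ~40x mean
    depth, an inbred-colony heterozygosity of ~1.2e-4 variants/base
    (≈325k variants over a 2.8 Gb genome), ~40% of the genome annotated as
    repeat, ~20 de novo mutations per embryo split between the one-cell and
    two-cell stages, and a handful of low-VAF parental mosaics.
    """

    n_chrom: int = 1
    chrom_len: int = 1_000_000
    repeat_fraction: float = 0.4
    microsat_per_mb: int = 50
    inherited_het_rate: float = 1.2e-4
    dnm_count_mean: float = 20.0
    dnm_stage_probs: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.5})
    dnm_indel_fraction: float = 0.1
    parental_mosaic_count: int = 2
    parental_mosaic_vaf: float = 0.05
    artifact_indel_count: int = 5
    mean_depth: float = 39.5
    error_rate: float = 1e-3
    base_qual: float = 60.0
    embryo_count_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_fraction", "inherited_het_rate", "parental_mosaic_vaf",
                     "dnm_indel_fraction", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.dnm_stage_probs:
            total = sum(self.dnm_stage_probs.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ConfigError("dnm_stage_probs must sum to 1")
            if any(s < 1 for s in self.dnm_stage_probs):
                raise ConfigError("embryonic stages start at 1")


def stage_vaf(stage: int) -> float:
    """Expected allele fraction of a heterozygous mutation arising in one
    cell of a 2**(stage-1)-cell embryo."""
    return 0.5 * 2.0 ** (1 - stage)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """What was planted, for recovery scoring."""

    inherited: list[dict] = field(default_factory=list)
    dnms: list[dict] = field(default_factory=list)
    parental_mosaics: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)
    edits: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimVariant:
    """One planted allele with per-sample true allele fractions."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    # sample -> (true vaf, constitutional?)  constitutional alleles are
    # genotyped 0/1 regardless of sampled reads; mosaic evidence is genotyped
    # from sampled AD with the calling rule.
    evidence: dict[str, tuple[float, bool]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Cohort:
    genome: Genome
    repeats: IntervalTrack
    microsats: IntervalTrack
    pedigree: Pedigree
    variants: list[SimVariant]
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_len: int,
    target_bases: int,
    min_len: int,
    max_len: int,
    taken: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Place random non-overlapping intervals totalling exactly target_bases."""
    placed: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target_bases:
        attempts += 1
        if attempts > 200_000:
            raise ConfigError(
                "chromosome too small for requested repeat coverage"
            )
        length = min(int(rng.integers(min_len, max_len + 1)), target_bases - covered)
        if chrom_len <= length:
            raise ConfigError("chromosome too small to host requested repeats")
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(s < end and start < e for s, e in taken) or any(
            s < end and start < e for s, e in placed
        ):
            continue
        placed.append((start, end))
        covered += length
    return placed


def simulate_reference(
    config: SimConfig, seed: int | None = None
) -> tuple[Genome, IntervalTrack, IntervalTrack]:
    """Random reference plus repeat and microsatellite annotation tracks.

    Repeat intervals are placed non-overlapping until they cover exactly
    round(repeat_fraction * chrom_len) bases per chromosome.  Microsatellites
    are homopolymer or dinucleotide runs of >= 8 units written into the
    sequence and recorded in their own track.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sequences: dict[str, str] = {}
    repeat_iv: list[tuple[str, int, int]] = []
    micro_iv: list[tuple[str, int, int]] = []
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        seq = np.frombuffer(
            _random_sequence(rng, config.chrom_len).encode(), dtype=np.uint8
        ).copy()
        # microsatellite runs, non-overlapping
        n_micro = int(round(config.microsat_per_mb * config.chrom_len / 1e6))
        placed: list[tuple[int, int]] = []
        for _ in range(n_micro):
            unit = str(_random_sequence(rng, 1 if rng.random() < 0.5 else 2))
            n_units = int(rng.integers(8, 16))
            run = (unit * n_units)[: n_units * len(unit)]
            for _attempt in range(1000):
                start = int(rng.integers(1, config.chrom_len - len(run) - 1))
                end = start + len(run)
                if not any(s - 2 < end and start < e + 2 for s, e in placed):
                    break
            else:
                raise ConfigError("chromosome too small for requested microsatellites")
            seq[start:end] = np.frombuffer(run.encode(), dtype=np.uint8)
            placed.append((start, end))
            micro_iv.append((chrom, start, end))
        target = int(round(config.repeat_fraction * config.chrom_len))
        if target > 0:
            for s, e in _place_nonoverlapping(
                rng, config.chrom_len, target, 200, 2000, placed
            ):
                repeat_iv.append((chrom, s, e))
        sequences[chrom] = seq.tobytes().decode()
    genome = Genome(sequences)
    repeats = IntervalTrack(sorted(repeat_iv), label="repeats").merge()
    microsats = IntervalTrack(sorted(micro_iv), label="microsatellites").merge()
    return genome, repeats, microsats


def build_pedigree(
    config: SimConfig,
    groups: Sequence[str] = ("cas9_only", "no_injection", "sham", "tyr2f", "tyr2r"),
    shared_parents: Mapping[str, str] | None = None,
) -> Pedigree:
    """One parent pair per group (the two gRNA groups share a pair by
    default, mirroring the original cross design), embryo_count_per_group
    embryos each."""
    if shared_parents is None:
        shared_parents = {"tyr2r": "tyr2f"}
    from .io_formats import Trio

    pair_of_group: dict[str, tuple[str, str]] = {}
    trios: list[Trio] = []
    group_of: dict[str, str] = {}
    pair_idx = 0
    for group in groups:
        donor = shared_parents.get(group)
        if donor is not None and donor in pair_of_group:
            father, mother = pair_of_group[donor]
        else:
            pair_idx += 1
            father, mother = f"father{pair_idx}", f"mother{pair_idx}"
        pair_of_group[group] = (father, mother)
        for i in range(config.embryo_count_per_group):
            embryo = f"{group}_e{i + 1}"
            trios.append(Trio(father, mother, embryo))
            group_of[embryo] = group
    return Pedigree(trios=trios, group_of=group_of)


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


def _pick_locus(
    rng: np.random.Generator,
    genome: Genome,
    occupied: set[tuple[str, int]],
    avoid: Sequence[IntervalTrack] = (),
    adjacency: int = 2,
) -> tuple[str, int]:
    """A fresh (chrom, 1-based pos) away from chromosome ends, not already
    used, and (optionally) clear of the given tracks."""
    chroms = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    for _ in range(100_000):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        pos = int(rng.integers(2, len(genome.sequences[chrom]) - 1))  # 1-based
        if (chrom, pos) in occupied:
            continue
        if genome.sequences[chrom][pos - 1] == "N":
            continue
        if any(t.contains(chrom, pos - 1, adjacency) for t in avoid):
            continue
        occupied.add((chrom, pos))
        return chrom, pos
    raise ConfigError("could not find a free locus; genome too small or too occupied")


def _snv_alleles(rng: np.random.Generator, genome: Genome, chrom: str, pos: int) -> tuple[str, str]:
    ref = genome.sequences[chrom][pos - 1]
    alt = "ACGT"[int(rng.integers(0, 4))]
    while alt == ref:
        alt = "ACGT"[int(rng.integers(0, 4))]
    return ref, alt


def _indel_alleles(
    rng: np.random.Generator, genome: Genome, chrom: str, pos: int, size: int | None = None
) -> tuple[str, str]:
    """Anchored 1-base-position indel (insertion or deletion) at pos."""
    anchor = genome.sequences[chrom][pos - 1]
    if size is None:
        size = int(rng.integers(1, 4))
    if rng.random() < 0.5:
        ins = _random_sequence(rng, size)
        return anchor, anchor + ins
    seq = genome.sequences[chrom]
    size = min(size, len(seq) - pos - 1)
    if size < 1:
        ins = _random_sequence(rng, 1)
        return anchor, anchor + ins
    return anchor + seq[pos : pos + size], anchor


def simulate_trio_genotypes(
    genome: Genome,
    config: SimConfig,
    pedigree: Pedigree,
    rng: np.random.Generator,
    repeats: IntervalTrack | None = None,
    microsats: IntervalTrack | None = None,
) -> tuple[list[SimVariant], TruthSet]:
    """Plant inherited variants, de novo mutations, parental mosaics and
    microsatellite artifact indels; return the variants and the truth ledger.

    De novo mutations are placed in the callable genome (outside repeat and
    microsatellite annotation), since the analysis excludes repeat-proximal
    variants by construction; artifact indels are deliberately placed
    adjacent to microsatellite runs.
    """
    repeats = repeats or IntervalTrack([], "repeats")
    microsats = microsats or IntervalTrack([], "microsatellites")
    truth = TruthSet()
    variants: list[SimVariant] = []
    occupied: set[tuple[str, int]] = set()

    embryos_of_parent: dict[str, list[str]] = {}
    for trio in pedigree.trios:
        for parent in (trio.father, trio.mother):
            embryos_of_parent.setdefault(parent, []).append(trio.embryo)

    # inherited heterozygous variants, one parent of origin each
    for parent in pedigree.parents:
        n_het = int(rng.poisson(config.inherited_het_rate * genome.total_size))
        for _ in range(n_het):
            chrom, pos = _pick_locus(rng, genome, occupied)
            ref, alt = _snv_alleles(rng, genome, chrom, pos)
            ev: dict[str, tuple[float, bool]] = {parent: (0.5, True)}
            transmitted: list[str] = []
            for embryo in embryos_of_parent[parent]:
                if rng.random() < 0.5:
                    ev[embryo] = (0.5, True)
                    transmitted.append(embryo)
            variants.append(SimVariant(chrom, pos, ref, alt, ev))
            truth.inherited.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "parent": parent, "transmitted_to": transmitted}
            )

    # parental mosaics: present in parental reads at low VAF (genotype 0/0),
    # each embryo of that parent inherits the allele with probability = VAF
    for parent in pedigree.parents:
        for _ in range(config.parental_mosaic_count):
            chrom, pos = _pick_locus(rng, genome, occupied)
            ref, alt = _snv_alleles(rng, genome, chrom, pos)
            ev = {parent: (config.parental_mosaic_vaf, False)}
            transmitted = []
            for embryo in embryos_of_parent[parent]:
                if rng.random() < config.parental_mosaic_vaf:
                    ev[embryo] = (0.5, True)
                    transmitted.append(embryo)
            variants.append(SimVariant(chrom, pos, ref, alt, ev))
            truth.parental_mosaics.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "parent": parent, "vaf": config.parental_mosaic_vaf,
                 "transmitted_to": transmitted}
            )

    # de novo mutations with stage-dependent allele fractions
    stages = sorted(config.dnm_stage_probs)
    stage_p = np.array([config.dnm_stage_probs[s] for s in stages])
    for embryo in pedigree.embryos:
        k = int(rng.poisson(config.dnm_count_mean))
        for _ in range(k):
            chrom, pos = _pick_locus(
                rng, genome, occupied, avoid=(repeats, microsats), adjacency=2
            )
            is_indel = rng.random() < config.dnm_indel_fraction
            if is_indel:
                ref, alt = _indel_alleles(rng, genome, chrom, pos)
            else:
                ref, alt = _snv_alleles(rng, genome, chrom, pos)
            stage = int(stages[int(rng.choice(len(stages), p=stage_p))])
            vaf = stage_vaf(stage)
            variants.append(SimVariant(chrom, pos, ref, alt, {embryo: (vaf, False)}))
            truth.dnms.append(
                {"embryo": embryo, "chrom": chrom, "pos": pos, "ref": ref,
                 "alt": alt, "stage": stage, "expected_vaf": vaf,
                 "is_indel": is_indel}
            )

    # microsatellite-adjacent artifact indels, embryo evidence only
    ms = microsats.merge().intervals
    if ms and config.artifact_indel_count > 0:
        for embryo in pedigree.embryos:
            for _ in range(config.artifact_indel_count):
                for _attempt in range(1000):
                    chrom, s, e = ms[int(rng.integers(0, len(ms)))]
                    pos = s if rng.random() < 0.5 else e + 1  # 1-based, 1bp adjacent
                    if pos < 2 or pos >= len(genome.sequences[chrom]):
                        continue
                    if (chrom, pos) not in occupied:
                        break
                else:
                    continue
                occupied.add((chrom, pos))
                ref, alt = _indel_alleles(rng, genome, chrom, pos)
                vaf = float(rng.uniform(0.1, 0.4))
                variants.append(SimVariant(chrom, pos, ref, alt, {embryo: (vaf, False)}))
                truth.artifacts.append(
                    {"embryo": embryo, "chrom": chrom, "pos": pos, "ref": ref,
                     "alt": alt, "vaf": vaf}
                )

    variants.sort(key=lambda v: v.key)
    return variants, truth


# ---------------------------------------------------------------------------
# CRISPR edits
# ---------------------------------------------------------------------------


def _cut_position(site: OffTargetSite) -> int:
    """1-based blunt-cut position, 3 bp 5' of the PAM on the matched strand."""
    if site.strand == "+":
        return site.start + 17  # 0-based start+16 -> 1-based +17
    return site.start + 7


def plant_crispr_edits(
    variants: list[SimVariant],
    truth: TruthSet,
    genome: Genome,
    guide: GuideSpec,
    sites: Sequence[OffTargetSite],
    embryos: Sequence[str],
    rng: np.random.Generator,
    on_target_efficiency: float = 0.88,
    mosaic_allele_dist: Mapping[int, float] | None = None,
    off_sites: Sequence[OffTargetSite] = (),
    off_target_efficiency: float = 1.0,
    stage_probs: Mapping[int, float] | None = None,
) -> None:
    """Plant mosaic edit alleles at the guide's on-target cut site (and
    optionally at chosen off-target sites) for the given embryos, in place.

    With probability ``on_target_efficiency`` an embryo receives k distinct
    indel alleles at the cut position (k from ``mosaic_allele_dist``; default
    30%/50%/20% for 1/2/3 alleles, the observed mosaicism spectrum).  Each
    allele's VAF follows the embryonic-stage model, with stages forced >= 2
    when the embryo is mosaic (k >= 2) so allele fractions of distinct
    lineages can coexist; allele sets whose VAFs would exceed 1 are resampled.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    on_targets = [s for s in sites if s.is_on_target]
    if not on_targets:
        raise ValueError("no on-target site flagged in `sites`")
    if mosaic_allele_dist is None:
        mosaic_allele_dist = {1: 0.3, 2: 0.5, 3: 0.2}
    if stage_probs is None:
        stage_probs = {1: 0.5, 2: 0.5}
    ks = sorted(mosaic_allele_dist)
    kp = np.array([mosaic_allele_dist[k] for k in ks], dtype=float)
    kp = kp / kp.sum()
    stages = sorted(stage_probs)
    sp = np.array([stage_probs[s] for s in stages], dtype=float)
    sp = sp / sp.sum()

    def draw_vafs(k: int) -> list[float]:
        for _ in range(1000):
            out = []
            for _i in range(k):
                s = int(stages[int(rng.choice(len(stages), p=sp))])
                if k >= 2:
                    s = max(s, 2)
                out.append(stage_vaf(s))
            if sum(out) <= 1.0:
                return out
        raise ValueError("could not draw a consistent mosaic allele set")

    def plant(site: OffTargetSite, embryo: str, k: int) -> None:
        pos = _cut_position(site)
        chrom = site.chrom
        vafs = draw_vafs(k)
        used_alts: set[str] = {
            v.alt for v in variants if v.chrom == chrom and v.pos == pos
        }
        for vaf in vafs:
            for size in range(1, 30):
                ref, alt = _indel_alleles(rng, genome, chrom, pos, size=size)
                if alt not in used_alts:
                    break
            used_alts.add(alt)
            variants.append(SimVariant(chrom, pos, ref, alt, {embryo: (vaf, False)}))
            truth.edits.append(
                {"embryo": embryo, "chrom": chrom, "pos": pos, "ref": ref,
                 "alt": alt, "vaf": vaf, "on_target": bool(site.is_on_target),
                 "guide": guide.name}
            )

    for embryo in embryos:
        if rng.random() < on_target_efficiency:
            k = int(ks[int(rng.choice(len(ks), p=kp))])
            plant(on_targets[0], embryo, k)
        for site in off_sites:
            if rng.random() < off_target_efficiency:
                plant(site, embryo, 1)
    variants.sort(key=lambda v: v.key)


# ---------------------------------------------------------------------------
# Read evidence
# ---------------------------------------------------------------------------


def sample_allele_depths(
    vaf: float, mean_depth: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """(ad_ref, ad_alt, depth): depth ~ Poisson(mean_depth),
    ad_alt ~ Binomial(depth, vaf)."""
    if not (0.0 <= vaf <= 1.0):
        raise ValueError("vaf must be in [0, 1]")
    depth = int(rng.poisson(mean_depth))
    ad_alt = int(rng.binomial(depth, vaf)) if depth else 0
    return depth - ad_alt, ad_alt, depth


def genotype_from_ad(ad_alt: int, depth: int, min_frac: float = 0.05, min_reads: int = 2) -> bool:
    """Mosaic genotype call from allele depth: carries alt if the alt
    fraction reaches min_frac with at least min_reads supporting reads."""
    return depth > 0 and ad_alt >= min_reads and ad_alt / depth >= min_frac


def realize_records(
    variants: Sequence[SimVariant],
    samples: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Depth-sample every (variant, sample) pair into joint VariantRecords."""
    records: list[VariantRecord] = []
    for var in variants:
        calls: dict[str, SampleCall] = {}
        for sample in samples:
            true_vaf, constitutional = var.evidence.get(sample, (0.0, False))
            draw_vaf = true_vaf if true_vaf > 0 else config.error_rate
            ad_ref, ad_alt, depth = sample_allele_depths(
                draw_vaf, config.mean_depth, rng
            )
            if true_vaf == 0.0:
                gt = (0, 0)  # stray error reads are never genotyped
            elif constitutional:
                gt = (0, 1)
            else:
                gt = (0, 1) if genotype_from_ad(ad_alt, depth) else (0, 0)
            calls[sample] = SampleCall(gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, depth=depth)
        records.append(
            VariantRecord(
                chrom=var.chrom, pos=var.pos, ref=var.ref, alt=var.alt,
                qual=config.base_qual, samples=calls,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Orchestration and emission
# ---------------------------------------------------------------------------


def embed_guide_targets(
    genome: Genome,
    guides: Mapping[str, GuideSpec],
    rng: np.random.Generator,
    avoid: Sequence[IntervalTrack] = (),
    pam: str = "TGG",
) -> dict[str, tuple[str, int]]:
    """Write each guide's perfect protospacer+PAM into the reference at a
    random location clear of the given tracks; returns guide -> (chrom,
    0-based start).  Mutates ``genome.sequences``."""
    placed: dict[str, tuple[str, int]] = {}
    taken: list[tuple[str, int, int]] = []
    for name, guide in guides.items():
        target = guide.protospacer + pam
        chroms = list(genome.sequences)
        for _attempt in range(10_000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            seq = genome.sequences[chrom]
            if len(seq) < len(target) + 200:
                continue
            start = int(rng.integers(100, len(seq) - len(target) - 100))
            end = start + len(target)
            if any(c == chrom and s < end + 50 and start - 50 < e for c, s, e in taken):
                continue
            if any(
                t.contains(chrom, p, 0) for t in avoid for p in (start - 50, start, end + 50)
            ):
                continue
            genome.sequences[chrom] = seq[:start] + target + seq[end:]
            placed[name] = (chrom, start)
            taken.append((chrom, start, end))
            break
        else:
            raise ConfigError(f"could not place on-target site for guide {name}")
    return placed


def simulate_cohort(
    config: SimConfig,
    pedigree: Pedigree | None = None,
    guides: Mapping[str, GuideSpec] | None = None,
    treated_groups: Mapping[str, str] | None = None,
) -> tuple[Cohort, list[VariantRecord]]:
    """Full simulation: reference, genotypes, optional edits, read evidence.

    ``guides`` maps guide name -> GuideSpec; ``treated_groups`` maps
    treatment-group name -> guide name for the groups that receive edits.
    Each treated guide's perfect target is embedded into the reference.
    Returns the cohort (with truth ledger) and the realized joint records.
    """
    rng = np.random.default_rng(config.seed)
    genome, repeats, microsats = simulate_reference(config, seed=int(rng.integers(2**31)))
    if guides and treated_groups:
        used = {treated_groups[g] for g in treated_groups}
        embed_guide_targets(
            genome,
            {name: guides[name] for name in sorted(used)},
            rng,
            avoid=(repeats, microsats),
        )
    if pedigree is None:
        pedigree = build_pedigree(config)
    variants, truth = simulate_trio_genotypes(
        genome, config, pedigree, rng, repeats=repeats, microsats=microsats
    )
    if guides and treated_groups:
        from .guide_offtarget import enumerate_offtargets

        groups = pedigree.groups()
        for group, guide_name in treated_groups.items():
            guide = guides[guide_name]
            sites = enumerate_offtargets(genome, guide)
            if not any(s.is_on_target for s in sites):
                raise ConfigError(
                    f"guide {guide_name} has no perfect match in the simulated genome"
                )
            plant_crispr_edits(
                variants, truth, genome, guide, sites,
                embryos=groups.get(group, []), rng=rng,
                stage_probs=config.dnm_stage_probs,
            )
    records = realize_records(variants, pedigree.samples, config, rng)
    cohort = Cohort(genome, repeats, microsats, pedigree, variants, truth, config)
    return cohort, records


def emit_cohort(
    cohort: Cohort, records: Sequence[VariantRecord], outdir: str | Path
) -> dict[str, Path]:
    """Write the joint VCF, pedigree TSV, truth JSON, annotation BEDs and
    reference FASTA; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "pedigree": outdir / "pedigree.tsv",
        "truth": outdir / "truth.json",
        "repeats": outdir / "repeats.bed",
        "microsats": outdir / "microsatellites.bed",
        "fasta": outdir / "reference.fa",
    }
    contigs = {c: len(s) for c, s in cohort.genome.sequences.items()}
    write_joint_vcf(records, cohort.pedigree.samples, paths["vcf"], contigs=contigs)
    write_pedigree_tsv(cohort.pedigree, paths["pedigree"])
    cohort.truth.to_json(paths["truth"])
    write_bed(cohort.repeats, paths["repeats"])
    write_bed(cohort.microsats, paths["microsats"])
    cohort.genome.to_fasta(paths["fasta"])
    return paths
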