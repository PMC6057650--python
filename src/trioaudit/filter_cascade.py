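"""Ordered false-positive filtration of candidate de novo mutations.

The trio cascade applies, in order:

1.  minimum variant allele fraction (default 10%, chosen to admit mosaic
    alleles down to the two-cell stage);
2.  parental noise — any alt-supporting read in either parent;
3.  known-variant catalogues (strain background), matched on (chrom, pos, alt);
4.  cross noise — aggregate alt-read fraction across all other non-parental
    cohort samples above a small ceiling (default 2%);
5.  inside or within 1 bp of a merged repeat interval;
6.  candidate shared by two or more embryos (almost certainly a parental
    mosaic, not independent de novo events);
7.  mosaic re-insertion — a second alt allele at a surviving locus meeting
    the VAF floor is re-added (the one count-increasing stage);
8.  indels only: inside or adjacent to a microsatellite/homopolymer run
    (a deterministic stand-in for visual inspection of indel alignments).

Candidates overlapping a declared on-target window are tallied separately
before stage 1 and never counted as DNMs.  A per-stage ledger records
surviving SNV and indel counts per embryo.

The somatic-mode cascade mirrors the published tumour/normal re-analysis:
alignment-score annotation floor, depth and alt-read floors, VAF floor,
zero parental alt reads, presence in the comparisons against both parents,
no sharing between embryos, known catalogues (any strain), repeat proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dnm_calling import CandidateDNM, call_trio_dnms
from .io_formats import IntervalTrack, Pedigree, Trio, VariantRecord

TRIO_STAGES = [
    "candidates",
    "not_on_target",
    "vaf",
    "parental_noise",
    "known_variants",
    "cross_noise",
    "repeats",
    "shared",
    "mosaic_reinsertion",
    "indel_microsat",
]

SOMATIC_STAGES = [
    "candidates",
    "not_on_target",
    "annotation",
    "depth_alt_reads",
    "vaf",
    "parental_noise",
    "both_parents",
    "shared",
    "known_variants",
    "repeats",
]


@dataclass
class FilterConfig:
    min_vaf: float = 0.10
    parental_alt_max: int = 0
    cross_noise_max: float = 0.02
    cross_noise_per_sample: bool = False
    repeat_adjacency: int = 1
    drop_shared: bool = True
    mosaic_reinsertion: bool = True
    indel_microsat_scan: bool = True
    # somatic-mode extras
    annotation_name: str = "ASMD"
    annotation_min: float = 140.0
    somatic_min_depth: int = 10
    somatic_min_alt_reads: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_vaf <= 1.0) or self.cross_noise_max < 0:
            raise ValueError("invalid filter thresholds")


@dataclass
class Resources:
    """Everything the cascade consults besides the candidates themselves."""

    repeats: IntervalTrack = field(default_factory=lambda: IntervalTrack([], "repeats"))
    microsats: IntervalTrack = field(
        default_factory=lambda: IntervalTrack([], "microsatellites")
    )
    known_catalogs: list[set[tuple[str, int, str]]] = field(default_factory=list)
    cohort_records: list[VariantRecord] = field(default_factory=list)
    pedigree: Pedigree | None = None
    on_target_windows: list[tuple[str, int, int]] = field(default_factory=list)

    def in_on_target_window(self, chrom: str, pos0: int) -> bool:
        return any(
            c == chrom and s <= pos0 < e for c, s, e in self.on_target_windows
        )

    def is_known(self, chrom: str, pos: int, alt: str) -> bool:
        return any((chrom, pos, alt) in cat for cat in self.known_catalogs)


class FilterConfigurationError(RuntimeError):
    pass


@dataclass
class FilterLedger:
    """Per-embryo (SNV, indel) survivor counts after every stage."""

    stages: list[str] = field(default_factory=list)
    counts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    on_target: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, candidates: Iterable[CandidateDNM]) -> None:
        per_embryo: dict[str, set[tuple]] = {}
        indel_keys: dict[str, set[tuple]] = {}
        for cand in candidates:
            if not cand.surviving:
                continue
            bucket = per_embryo.setdefault(cand.embryo, set())
            bucket.add(cand.record.key)
            if cand.is_indel:
                indel_keys.setdefault(cand.embryo, set()).add(cand.record.key)
        self.stages.append(stage)
        embryos = set(self.counts) | set(per_embryo)
        for embryo in embryos:
            history = self.counts.setdefault(
                embryo, [(0, 0)] * (len(self.stages) - 1)
            )
            keys = per_embryo.get(embryo, set())
            n_indel = len(indel_keys.get(embryo, set()))
            history.append((len(keys) - n_indel, n_indel))

    def to_rows(self) -> list[dict]:
        rows = []
        for embryo, history in sorted(self.counts.items()):
            for stage, (snv, indel) in zip(self.stages, history):
                rows.append(
                    {"embryo": embryo, "stage": stage, "snv": snv, "indel": indel}
                )
        return rows

    def final_counts(self) -> dict[str, tuple[int, int]]:
        return {e: hist[-1] for e, hist in self.counts.items()}


def _exempt(cand: CandidateDNM) -> bool:
    return bool(cand.annotations.get("reinserted"))


def _cross_noise_exceeds(
    cand: CandidateDNM, config: FilterConfig, resources: Resources
) -> bool:
    rec = cand.record
    exclude = {cand.embryo}
    if resources.pedigree is not None:
        try:
            exclude.update(resources.pedigree.parents_of(cand.embryo))
        except KeyError:
            pass
    others = [call for name, call in rec.samples.items() if name not in exclude]
    if not others:
        return False
    if config.cross_noise_per_sample:
        return any(
            c.depth > 0 and c.ad_alt / c.depth > config.cross_noise_max for c in others
        )
    total_alt = sum(c.ad_alt for c in others)
    total_depth = sum(c.depth for c in others)
    return total_depth > 0 and total_alt / total_depth > config.cross_noise_max


def _flag_shared(candidates: list[CandidateDNM], flag: str) -> None:
    by_key: dict[tuple, set[str]] = {}
    for cand in candidates:
        if cand.surviving or _exempt(cand):
            by_key.setdefault(cand.record.key, set()).add(cand.embryo)
    for cand in candidates:
        if not cand.surviving or _exempt(cand):
            continue
        if len(by_key.get(cand.record.key, set())) >= 2:
            cand.flags.add(flag)


def _split_on_target(
    candidates: Sequence[CandidateDNM], resources: Resources, ledger: FilterLedger
) -> list[CandidateDNM]:
    ledger.record("candidates", candidates)
    kept: list[CandidateDNM] = []
    on_count: dict[str, set[tuple]] = {}
    for cand in candidates:
        if resources.in_on_target_window(cand.record.chrom, cand.record.pos0):
            on_count.setdefault(cand.embryo, set()).add(cand.record.key)
        else:
            kept.append(cand)
    ledger.on_target = {e: len(k) for e, k in on_count.items()}
    ledger.record("not_on_target", kept)
    return kept


def apply_cascade(
    candidates: Sequence[CandidateDNM],
    config: FilterConfig,
    resources: Resources,
) -> tuple[list[CandidateDNM], FilterLedger]:
    """Run the trio-mode filter cascade; returns (surviving candidates,
    per-stage ledger).  Candidates are flagged in place with the name of the
    stage that removed them."""
    if resources.known_catalogs is None:
        raise FilterConfigurationError("known_variants filter enabled without catalogs")
    ledger = FilterLedger()
    cands = _split_on_target(list(candidates), resources, ledger)

    for cand in cands:
        if not _exempt(cand) and cand.vaf < config.min_vaf:
            cand.flags.add("vaf")
    ledger.record("vaf", cands)

    for cand in cands:
        if cand.surviving and not _exempt(cand):
            if cand.father_alt_reads + cand.mother_alt_reads > config.parental_alt_max:
                cand.flags.add("parental_noise")
    ledger.record("parental_noise", cands)

    for cand in cands:
        if cand.surviving and not _exempt(cand):
            rec = cand.record
            if resources.is_known(rec.chrom, rec.pos, rec.alt):
                cand.flags.add("known_variants")
    ledger.record("known_variants", cands)

    for cand in cands:
        if cand.surviving and not _exempt(cand):
            if _cross_noise_exceeds(cand, config, resources):
                cand.flags.add("cross_noise")
    ledger.record("cross_noise", cands)

    for cand in cands:
        if cand.surviving and not _exempt(cand):
            rec = cand.record
            if resources.repeats.contains(rec.chrom, rec.pos0, config.repeat_adjacency):
                cand.flags.add("repeats")
    ledger.record("repeats", cands)

    if config.drop_shared:
        _flag_shared(cands, "shared")
    ledger.record("shared", cands)

    if config.mosaic_reinsertion and resources.cohort_records:
        cands = cands + _reinsert_mosaics(cands, config, resources)
    ledger.record("mosaic_reinsertion", cands)

    if config.indel_microsat_scan:
        for cand in cands:
            if cand.surviving and cand.is_indel:
                rec = cand.record
                if resources.microsats.contains(
                    rec.chrom, rec.pos0, config.repeat_adjacency
                ):
                    cand.flags.add("indel_microsat")
    ledger.record("indel_microsat", cands)

    survivors = [c for c in cands if c.surviving]
    return survivors, ledger


def _reinsert_mosaics(
    cands: list[CandidateDNM], config: FilterConfig, resources: Resources
) -> list[CandidateDNM]:
    """Stage 7: at each surviving locus, re-add any second alt allele in the
    same embryo's reads meeting the VAF floor.  Re-inserted candidates are
    exempt from the per-variant predicates (they stand in for the manual
    re-addition of mosaic alleles), but indels still face stage 8."""
    by_locus: dict[tuple[str, int], list[VariantRecord]] = {}
    for rec in resources.cohort_records:
        by_locus.setdefault((rec.chrom, rec.pos), []).append(rec)
    existing = {(c.embryo, *c.record.key) for c in cands}
    added: list[CandidateDNM] = []
    for cand in cands:
        if not cand.surviving:
            continue
        for rec in by_locus.get(cand.locus, []):
            if rec.alt == cand.record.alt and rec.ref == cand.record.ref:
                continue
            call = rec.samples.get(cand.embryo)
            if call is None or call.vaf < config.min_vaf:
                continue
            key = (cand.embryo, *rec.key)
            if key in existing:
                continue
            existing.add(key)
            father_alt = mother_alt = 0
            if resources.pedigree is not None:
                try:
                    f, m = resources.pedigree.parents_of(cand.embryo)
                    father_alt = rec.samples[f].ad_alt if f in rec.samples else 0
                    mother_alt = rec.samples[m].ad_alt if m in rec.samples else 0
                except KeyError:
                    pass
            added.append(
                CandidateDNM(
                    embryo=cand.embryo,
                    record=rec,
                    vaf=call.vaf,
                    father_alt_reads=father_alt,
                    mother_alt_reads=mother_alt,
                    source=cand.source,
                    annotations={"reinserted": 1.0},
                )
            )
    return added


# ---------------------------------------------------------------------------
# Validation classification
# ---------------------------------------------------------------------------


@dataclass
class ValidationCall:
    pooled_parent_alt_reads: int
    pooled_parent_vaf: float
    embryo_vaf: float
    verdict: str  # "validated" | "not_validated"


def classify_validation(
    pooled_parent: tuple[int, float], embryo_vaf: float
) -> ValidationCall:
    """Deep-resequencing verdict for one candidate locus.

    Not validated iff the pooled parent sample shows more than 100 alt reads
    AND more than 1% alt fraction (the allele was in the parents all along),
    or the embryo shows less than 1% alt fraction (the call does not
    reproduce)."""
    alt_reads, parent_vaf = pooled_parent
    if alt_reads < 0 or not (0 <= parent_vaf <= 1) or not (0 <= embryo_vaf <= 1):
        raise ValueError("invalid validation inputs")
    not_validated = (alt_reads > 100 and parent_vaf > 0.01) or embryo_vaf < 0.01
    return ValidationCall(
        pooled_parent_alt_reads=alt_reads,
        pooled_parent_vaf=parent_vaf,
        embryo_vaf=embryo_vaf,
        verdict="not_validated" if not_validated else "validated",
    )


# ---------------------------------------------------------------------------
# Distant-parent re-analysis
# ---------------------------------------------------------------------------


def _truncated_filter_count(
    records: Sequence[VariantRecord],
    trio: Trio,
    config: FilterConfig,
    resources: Resources,
) -> int:
    """Candidate count after filters {vaf, parental noise, known, repeats}
    only — the stages that remain well-defined when the parents are wrong."""
    n = 0
    for cand in call_trio_dnms(records, trio):
        rec = cand.record
        if cand.vaf < config.min_vaf:
            continue
        if cand.father_alt_reads + cand.mother_alt_reads > config.parental_alt_max:
            continue
        if resources.is_known(rec.chrom, rec.pos, rec.alt):
            continue
        if resources.repeats.contains(rec.chrom, rec.pos0, config.repeat_adjacency):
            continue
        if resources.in_on_target_window(rec.chrom, rec.pos0):
            continue
        n += 1
    return n


@dataclass
class ParentSwapResult:
    per_embryo: dict[str, dict]  # embryo -> {correct, swapped, control_row}
    median_inflation: float


def parent_swap_analysis(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    wrong_parents: tuple[str, str],
    config: FilterConfig,
    resources: Resources,
) -> ParentSwapResult:
    """Re-run DNM calling for every embryo with a fixed (wrong) parent pair
    and compare truncated-cascade survivor counts against the correct
    parentage.  Embryos whose true parents are the fixed pair are control
    rows and excluded from the inflation median."""
    import statistics

    father, mother = wrong_parents
    per_embryo: dict[str, dict] = {}
    inflations: list[int] = []
    for trio in pedigree.trios:
        correct = _truncated_filter_count(records, trio, config, resources)
        swapped_trio = Trio(father, mother, trio.embryo)
        swapped = _truncated_filter_count(records, swapped_trio, config, resources)
        control = {trio.father, trio.mother} == {father, mother}
        per_embryo[trio.embryo] = {
            "correct": correct,
            "swapped": swapped,
            "control_row": control,
        }
        if not control:
            inflations.append(swapped - correct)
    median_inflation = float(statistics.median(inflations)) if inflations else 0.0
    return ParentSwapResult(per_embryo=per_embryo, median_inflation=median_inflation)


# ---------------------------------------------------------------------------
# Somatic-mode cascade
# ---------------------------------------------------------------------------


def apply_somatic_cascade(
    candidates: Sequence[CandidateDNM],
    config: FilterConfig,
    resources: Resources,
) -> tuple[list[CandidateDNM], FilterLedger]:
    """Filter somatic-mode (embryo-vs-parent) candidates.

    Input is the union of per-parent comparisons; the ``both_parents`` stage
    keeps only calls present against both parents, then collapses each
    (embryo, variant) to a single candidate.
    """
    if resources.pedigree is None:
        raise FilterConfigurationError("somatic cascade requires a pedigree")
    ledger = FilterLedger()
    cands = _split_on_target(list(candidates), resources, ledger)

    for cand in cands:
        ann = cand.annotations.get(config.annotation_name)
        if ann is not None and ann < config.annotation_min:
            cand.flags.add("annotation")
    ledger.record("annotation", cands)

    for cand in cands:
        if not cand.surviving:
            continue
        rec = cand.record
        f, m = resources.pedigree.parents_of(cand.embryo)
        calls = [rec.samples[s] for s in (cand.embryo, f, m) if s in rec.samples]
        if any(c.depth < config.somatic_min_depth for c in calls):
            cand.flags.add("depth_alt_reads")
            continue
        embryo_call = rec.samples[cand.embryo]
        if not rec.is_indel and embryo_call.ad_alt < config.somatic_min_alt_reads:
            cand.flags.add("depth_alt_reads")
    ledger.record("depth_alt_reads", cands)

    for cand in cands:
        if cand.surviving and cand.vaf < config.min_vaf:
            cand.flags.add("vaf")
    ledger.record("vaf", cands)

    for cand in cands:
        if not cand.surviving:
            continue
        rec = cand.record
        f, m = resources.pedigree.parents_of(cand.embryo)
        parent_alt = sum(
            rec.samples[s].ad_alt for s in (f, m) if s in rec.samples
        )
        if parent_alt > config.parental_alt_max:
            cand.flags.add("parental_noise")
    ledger.record("parental_noise", cands)

    # intersection of the two per-parent comparisons
    parents_seen: dict[tuple, set[str]] = {}
    for cand in cands:
        if cand.surviving:
            parents_seen.setdefault((cand.embryo, cand.record.key), set()).add(
                cand.parent or ""
            )
    collapsed: set[tuple] = set()
    for cand in cands:
        if not cand.surviving:
            continue
        key = (cand.embryo, cand.record.key)
        if len(parents_seen.get(key, set())) < 2:
            cand.flags.add("both_parents")
        elif key in collapsed:
            cand.flags.add("duplicate_comparison")
        else:
            collapsed.add(key)
    ledger.record("both_parents", cands)

    if config.drop_shared:
        _flag_shared(cands, "shared")
    ledger.record("shared", cands)

    for cand in cands:
        if cand.surviving:
            rec = cand.record
            if resources.is_known(rec.chrom, rec.pos, rec.alt):
                cand.flags.add("known_variants")
    ledger.record("known_variants", cands)

    for cand in cands:
        if cand.surviving:
            rec = cand.record
            if resources.repeats.contains(rec.chrom, rec.pos0, config.repeat_adjacency):
                cand.flags.add("repeats")
    ledger.record("repeats", cands)

    survivors = [c for c in cands if c.surviving]
    return survivors, ledger
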