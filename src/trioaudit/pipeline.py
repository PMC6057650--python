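"""End-to-end orchestration: simulate -> call -> filter -> intersect -> test.

``run_pipeline`` executes the whole audit on a synthetic cohort and returns
a :class:`RunReport` that is byte-identically reproducible given the same
config and seed.  ``compare_groups_report`` runs the published battery of
group comparisons (Kruskal-Wallis within controls, Wilcoxon within treated,
Wilcoxon combined untreated-vs-treated, SNVs and indels separately, with a
Bonferroni gate over the first four tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import tables
from .dnm_calling import call_cohort_dnms, basic_quality_gate
from .filter_cascade import FilterConfig, FilterLedger, Resources, apply_cascade
from .guide_offtarget import GuideSpec, enumerate_offtargets, window_intersect
from .io_formats import Pedigree
from .stats_power import (
    PowerQuery,
    TestResult,
    bonferroni_gate,
    kruskal_wallis,
    poisson_detect_power,
    summarize_cohort,
    wilcoxon_rank_sum,
)
from .synthetic_trio import Cohort, SimConfig, emit_cohort, simulate_cohort, stage_vaf


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    guides: dict[str, str] = field(
        default_factory=lambda: dict(tables.GUIDE_SEQUENCES)
    )
    # treatment group -> guide name; groups absent here are untreated
    treated_groups: dict[str, str] = field(
        default_factory=lambda: {"tyr2f": "Tyr2F", "tyr2r": "Tyr2R"}
    )
    control_groups: tuple[str, ...] = ("cas9_only", "no_injection", "sham")
    intersect_window: int = 10
    on_target_halfwidth: int = 30
    power_effect_vaf: float = 0.28
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        filters = FilterConfig(**raw.pop("filters", {}))
        if "control_groups" in raw:
            raw["control_groups"] = tuple(raw["control_groups"])
        return cls(sim=sim, filters=filters, **raw)


@dataclass
class RunReport:
    config: dict
    ledger_rows: list[dict]
    final_counts: dict[str, dict]
    offtarget_hits: dict[str, int]
    tests: dict[str, dict]
    bonferroni: dict[str, dict]
    power: dict
    truth_recovery: dict
    medians: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def final_counts_table(ledger: FilterLedger, pedigree: Pedigree) -> pd.DataFrame:
    """Per-embryo final (SNV, indel) survivor counts with treatment group,
    ordered as in the pedigree."""
    rows = []
    finals = ledger.final_counts()
    for embryo in pedigree.embryos:
        snv, indel = finals.get(embryo, (0, 0))
        rows.append(
            {"sample": embryo, "group": pedigree.group_of[embryo],
             "final_snv": snv, "final_indel": indel}
        )
    return pd.DataFrame(rows)


def compare_groups_report(
    counts: pd.DataFrame,
    control_groups: Sequence[str],
    treated_groups: Sequence[str],
) -> tuple[dict[str, TestResult], dict[str, tuple[float, bool]]]:
    """The published battery of rank tests on a per-embryo counts table.

    ``counts`` needs columns group, final_snv, final_indel.  Tests:
    Kruskal-Wallis across the control groups, Wilcoxon between the two
    treated groups (first listed group is the W-defining sample), and
    Wilcoxon of all untreated vs all treated; each for SNVs and indels.
    The Bonferroni gate (family alpha 0.05) covers the four within-arm tests.
    """
    present = set(counts["group"])
    if len(present) < 2:
        raise ValueError(">= 2 groups required")

    def col(group: str, column: str) -> list[float]:
        return counts.loc[counts["group"] == group, column].tolist()

    results: dict[str, TestResult] = {}
    for column, label in (("final_snv", "snv"), ("final_indel", "indel")):
        ctrl = [col(g, column) for g in control_groups]
        results[f"controls_{label}"] = kruskal_wallis(ctrl, labels=list(control_groups))
        x_grp, y_grp = treated_groups[0], treated_groups[1]
        results[f"treated_{label}"] = wilcoxon_rank_sum(
            col(x_grp, column), col(y_grp, column), labels=(x_grp, y_grp)
        )
        untreated = [v for g in control_groups for v in col(g, column)]
        treated = [v for g in treated_groups[::-1] for v in col(g, column)]
        results[f"combined_{label}"] = wilcoxon_rank_sum(
            untreated, treated, labels=("untreated", "treated")
        )
    family = ["controls_snv", "controls_indel", "treated_snv", "treated_indel"]
    gate = bonferroni_gate([results[name].p_value for name in family])
    bonf = {name: g for name, g in zip(family, gate)}
    return results, bonf


def published_group_tests() -> tuple[dict[str, TestResult], dict[str, tuple[float, bool]]]:
    """The six published group comparisons, recomputed from the packaged
    count table."""
    counts = tables.fixture_embryo_counts()
    return compare_groups_report(
        counts, tables.CONTROL_GROUPS, tables.TREATED_GROUPS
    )


def _truth_recovery(cohort: Cohort, survivor_keys: set, records_by_key: dict,
                    min_vaf: float) -> dict:
    truth = cohort.truth

    def sampled_vaf(embryo: str, entry: dict) -> float:
        rec = records_by_key.get((entry["chrom"], entry["pos"], entry["ref"], entry["alt"]))
        if rec is None or embryo not in rec.samples:
            return 0.0
        return rec.samples[embryo].vaf

    dnms_eligible = [
        d for d in truth.dnms if sampled_vaf(d["embryo"], d) >= min_vaf
    ]
    dnms_recovered = [
        d for d in dnms_eligible
        if (d["embryo"], d["chrom"], d["pos"], d["ref"], d["alt"]) in survivor_keys
    ]
    shared_mosaics = [
        m for m in truth.parental_mosaics if len(m["transmitted_to"]) >= 2
    ]
    shared_leaked = [
        (e, m["chrom"], m["pos"], m["ref"], m["alt"])
        for m in shared_mosaics for e in m["transmitted_to"]
    ]
    artifacts = [
        (a["embryo"], a["chrom"], a["pos"], a["ref"], a["alt"])
        for a in truth.artifacts
    ]
    return {
        "dnms_planted": len(truth.dnms),
        "dnms_eligible": len(dnms_eligible),
        "dnms_recovered": len(dnms_recovered),
        "recall_eligible": (
            len(dnms_recovered) / len(dnms_eligible) if dnms_eligible else None
        ),
        "shared_mosaic_leaks": len(shared_leaked),
        "shared_mosaic_surviving": sum(1 for k in shared_leaked if k in survivor_keys),
        "artifact_indels_planted": len(artifacts),
        "artifact_indels_surviving": sum(1 for k in artifacts if k in survivor_keys),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic audit and assemble the report."""
    guides = {
        name: GuideSpec(seq, ("NGG",), name)
        for name, seq in config.guides.items()
    }
    cohort, records = simulate_cohort(
        config.sim,
        guides=guides,
        treated_groups=config.treated_groups,
    )
    if config.outdir:
        emit_cohort(cohort, records, config.outdir)

    gated = basic_quality_gate(records)
    candidates = call_cohort_dnms(gated, cohort.pedigree)

    # off-target scan of each guide against the simulated reference, then
    # intersection with the unfiltered candidates (the published order)
    site_lists = {}
    on_target_windows: list[tuple[str, int, int]] = []
    hits_per_embryo: dict[str, int] = {e: 0 for e in cohort.pedigree.embryos}
    for name, guide in guides.items():
        sites = enumerate_offtargets(cohort.genome, guide)
        site_lists[name] = sites
        for s in sites:
            if s.is_on_target:
                on_target_windows.append(
                    (s.chrom, s.start - config.on_target_halfwidth,
                     s.end + config.on_target_halfwidth)
                )
        for var, _site in window_intersect(sites, candidates, config.intersect_window):
            hits_per_embryo[var.embryo] = hits_per_embryo.get(var.embryo, 0) + 1

    resources = Resources(
        repeats=cohort.repeats,
        microsats=cohort.microsats,
        known_catalogs=[],
        cohort_records=records,
        pedigree=cohort.pedigree,
        on_target_windows=on_target_windows,
    )
    survivors, ledger = apply_cascade(candidates, config.filters, resources)
    survivor_keys = {c.key for c in survivors}
    records_by_key = {r.key: r for r in records}

    counts = final_counts_table(ledger, cohort.pedigree)
    treated_pair = list(config.treated_groups)
    if len(treated_pair) >= 2:
        tests, bonf = compare_groups_report(counts, config.control_groups, treated_pair)
    else:
        # untreated-only design: only the within-controls comparisons exist
        tests = {}
        for column, label in (("final_snv", "snv"), ("final_indel", "indel")):
            groups = [
                counts.loc[counts["group"] == g, column].tolist()
                for g in config.control_groups
            ]
            tests[f"controls_{label}"] = kruskal_wallis(
                groups, labels=list(config.control_groups)
            )
        gate = bonferroni_gate([t.p_value for t in tests.values()])
        bonf = {name: g for name, g in zip(tests, gate)}

    power = poisson_detect_power(
        PowerQuery(
            depth=config.sim.mean_depth,
            vaf=config.power_effect_vaf,
            min_vaf=config.filters.min_vaf,
        )
    )
    recovery = _truth_recovery(
        cohort, survivor_keys, records_by_key, config.filters.min_vaf
    )
    medians = summarize_cohort(counts[["final_snv", "final_indel"]])

    report = RunReport(
        config={
            "sim": asdict(config.sim),
            "filters": asdict(config.filters),
            "guides": config.guides,
            "treated_groups": config.treated_groups,
            "control_groups": list(config.control_groups),
            "intersect_window": config.intersect_window,
        },
        ledger_rows=ledger.to_rows(),
        final_counts={
            row["sample"]: {"group": row["group"], "snv": row["final_snv"],
                            "indel": row["final_indel"]}
            for row in counts.to_dict("records")
        },
        offtarget_hits=hits_per_embryo,
        tests={name: res.to_dict() for name, res in tests.items()},
        bonferroni={
            name: {"critical": c, "significant": sig} for name, (c, sig) in bonf.items()
        },
        power={
            "lambda": power.lam,
            "min_alt_reads": power.min_alt_reads,
            "detect_probability": power.detect_probability,
            "miss_probability": power.miss_probability,
        },
        truth_recovery=recovery,
        medians=medians,
    )
    if config.outdir:
        report.to_json(Path(config.outdir) / "report.json")
    return report
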