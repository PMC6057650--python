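"""Filter cascade behaviour: per-stage predicates, ledger, validation
classification, parent-swap analysis and the somatic-mode cascade."""

import copy

import pytest

from trioaudit import (
    FilterConfig,
    IntervalTrack,
    Pedigree,
    Resources,
    SampleCall,
    Trio,
    VariantRecord,
    apply_cascade,
    apply_somatic_cascade,
    call_cohort_dnms,
    call_somatic_cohort,
    classify_validation,
    parent_swap_analysis,
    simulate_cohort,
    SimConfig,
)
from trioaudit.dnm_calling import CandidateDNM


def make_candidate(vaf=0.3, father_alt=0, mother_alt=0, pos=100, alt="T",
                   ref="A", embryo="kid", cohort_ad=None, qual=50.0):
    depth = 100  # vaf to two decimals maps exactly onto read counts
    ad_alt = int(round(vaf * depth))
    samples = {
        "dad": SampleCall((0, 0), depth - father_alt, father_alt, depth),
        "mum": SampleCall((0, 0), depth - mother_alt, mother_alt, depth),
        embryo: SampleCall((0, 1), depth - ad_alt, ad_alt, depth),
    }
    for name, extra_alt in (cohort_ad or {}).items():
        samples[name] = SampleCall((0, 0), depth - extra_alt, extra_alt, depth)
    rec = VariantRecord("chr1", pos, ref, alt, qual, samples)
    return CandidateDNM(
        embryo=embryo, record=rec, vaf=rec.samples[embryo].vaf,
        father_alt_reads=father_alt, mother_alt_reads=mother_alt, source="trio",
    )


PED = Pedigree(trios=[Trio("dad", "mum", "kid"), Trio("dad", "mum", "sib")],
               group_of={"kid": "sham", "sib": "sham"})


def resources(**kwargs):
    defaults = dict(pedigree=PED)
    defaults.update(kwargs)
    return Resources(**defaults)


class TestTrioCascade:
    def test_vaf_boundary(self):
        low = make_candidate(vaf=0.09, pos=10)
        edge = make_candidate(vaf=0.10, pos=20)
        survivors, _ = apply_cascade([low, edge], FilterConfig(), resources())
        assert [c.record.pos for c in survivors] == [20]
        assert low.flags == {"vaf"}

    def test_single_parental_read_removes(self):
        cand = make_candidate(mother_alt=1)
        survivors, _ = apply_cascade([cand], FilterConfig(), resources())
        assert survivors == [] and cand.flags == {"parental_noise"}

    def test_known_variant_dropped(self):
        cand = make_candidate(pos=100, alt="T")
        res = resources(known_catalogs=[{("chr1", 100, "T")}])
        survivors, _ = apply_cascade([cand], FilterConfig(), res)
        assert survivors == [] and cand.flags == {"known_variants"}

    def test_cross_noise_threshold_is_strict(self):
        # two non-parental samples, 100 reads each: 2% of 200 = 4 reads,
        # and the filter fires only on strictly more
        at_limit = make_candidate(pos=10, cohort_ad={"o1": 4, "o2": 0})
        over = make_candidate(pos=20, cohort_ad={"o1": 3, "o2": 2})
        survivors, _ = apply_cascade([at_limit, over], FilterConfig(), resources())
        assert [c.record.pos for c in survivors] == [10]
        assert over.flags == {"cross_noise"}

    def test_repeat_adjacency(self):
        track = IntervalTrack([("chr1", 100, 200)])
        inside = make_candidate(pos=150)
        adjacent = make_candidate(pos=201, alt="G")  # pos0=200, 1bp adjacent
        clear = make_candidate(pos=202, alt="C")  # pos0=201, 2bp away
        survivors, _ = apply_cascade(
            [inside, adjacent, clear], FilterConfig(), resources(repeats=track)
        )
        assert [c.record.pos for c in survivors] == [202]

    def test_shared_between_embryos_dropped(self):
        a = make_candidate(pos=500, embryo="kid")
        b = make_candidate(pos=500, embryo="sib")
        lone = make_candidate(pos=900, embryo="kid", alt="G")
        survivors, _ = apply_cascade([a, b, lone], FilterConfig(), resources())
        assert {c.record.pos for c in survivors} == {900}
        assert a.flags == b.flags == {"shared"}

    def test_mosaic_reinsertion_adds_second_allele(self):
        cand = make_candidate(pos=100, alt="T")
        # same locus, different alt, embryo reads at 20% but genotype 0/0
        other = VariantRecord(
            "chr1", 100, "A", "G", 50.0,
            {"dad": SampleCall((0, 0), 40, 0, 40),
             "mum": SampleCall((0, 0), 40, 0, 40),
             "kid": SampleCall((0, 0), 32, 8, 40)},
        )
        res = resources(cohort_records=[cand.record, other])
        survivors, ledger = apply_cascade([cand], FilterConfig(), res)
        assert {(c.record.alt) for c in survivors} == {"T", "G"}
        idx = ledger.stages.index("mosaic_reinsertion")
        counts = ledger.counts["kid"]
        assert counts[idx][0] > counts[idx - 1][0]  # the one increasing stage

    def test_indel_microsat_scan(self):
        track = IntervalTrack([("chr1", 100, 120)])
        indel = make_candidate(pos=121, ref="A", alt="AT")  # adjacent
        snv = make_candidate(pos=121, alt="G")
        survivors, _ = apply_cascade(
            [indel, snv], FilterConfig(), resources(microsats=track)
        )
        assert survivors == [snv]
        assert indel.flags == {"indel_microsat"}

    def test_on_target_tallied_separately(self):
        on = make_candidate(pos=100, ref="A", alt="AT")
        off = make_candidate(pos=5000, alt="G")
        res = resources(on_target_windows=[("chr1", 50, 150)])
        survivors, ledger = apply_cascade([on, off], FilterConfig(), res)
        assert [c.record.pos for c in survivors] == [5000]
        assert ledger.on_target == {"kid": 1}

    def test_ledger_monotone_except_reinsertion(self, base_cohort):
        cohort, records = base_cohort
        cands = call_cohort_dnms(records, cohort.pedigree)
        res = Resources(repeats=cohort.repeats, microsats=cohort.microsats,
                        cohort_records=records, pedigree=cohort.pedigree)
        _, ledger = apply_cascade(cands, FilterConfig(), res)
        idx_reinsert = ledger.stages.index("mosaic_reinsertion")
        for embryo, history in ledger.counts.items():
            totals = [s + i for s, i in history]
            for j in range(1, len(totals)):
                if j == idx_reinsert:
                    continue
                assert totals[j] <= totals[j - 1], (embryo, ledger.stages[j])

    def test_idempotent_on_survivors(self, base_cohort):
        cohort, records = base_cohort
        cands = call_cohort_dnms(records, cohort.pedigree)
        res = Resources(repeats=cohort.repeats, microsats=cohort.microsats,
                        cohort_records=records, pedigree=cohort.pedigree)
        survivors, _ = apply_cascade(cands, FilterConfig(), res)
        survivors_again, _ = apply_cascade(
            copy.deepcopy(survivors), FilterConfig(), res
        )
        assert {c.key for c in survivors_again} == {c.key for c in survivors}

    def test_final_set_matches_simultaneous_predicates(self, base_cohort):
        # order-independence of the per-variant stages: applying all
        # predicates at once (then the shared rule) gives the same survivors
        cohort, records = base_cohort
        cands = call_cohort_dnms(records, cohort.pedigree)
        config = FilterConfig(mosaic_reinsertion=False)
        res = Resources(repeats=cohort.repeats, microsats=cohort.microsats,
                        cohort_records=records, pedigree=cohort.pedigree)
        survivors, _ = apply_cascade(copy.deepcopy(cands), config, res)

        def passes(c):
            rec = c.record
            if c.vaf < 0.10:
                return False
            if c.father_alt_reads + c.mother_alt_reads > 0:
                return False
            others = [call for name, call in rec.samples.items()
                      if name not in {c.embryo, *cohort.pedigree.parents_of(c.embryo)}]
            alt = sum(o.ad_alt for o in others)
            dp = sum(o.depth for o in others)
            if dp and alt / dp > 0.02:
                return False
            if cohort.repeats.contains(rec.chrom, rec.pos0, 1):
                return False
            if rec.is_indel and cohort.microsats.contains(rec.chrom, rec.pos0, 1):
                return False
            return True

        flat = [c for c in cands if passes(c)]
        shared = {}
        for c in flat:
            shared.setdefault(c.record.key, set()).add(c.embryo)
        oracle = {c.key for c in flat if len(shared[c.record.key]) < 2}
        assert {c.key for c in survivors} == oracle


class TestValidation:
    def test_parent_conjunction(self):
        assert classify_validation((101, 0.02), 0.3).verdict == "not_validated"
        assert classify_validation((500, 0.005), 0.3).verdict == "validated"
        assert classify_validation((100, 0.5), 0.3).verdict == "validated"

    def test_embryo_floor(self):
        assert classify_validation((0, 0.0), 0.009).verdict == "not_validated"
        assert classify_validation((0, 0.0), 0.01).verdict == "validated"


class TestParentSwap:
    def _cohort(self, het_rate, seed=31):
        config = SimConfig(chrom_len=150_000, inherited_het_rate=het_rate,
                           parental_mosaic_count=0, artifact_indel_count=0,
                           error_rate=0.0, embryo_count_per_group=2, seed=seed)
        return simulate_cohort(config)

    def test_identity_swap_inflation_zero(self):
        cohort, records = self._cohort(5e-4)
        trio = cohort.pedigree.trios[0]
        res = Resources(repeats=cohort.repeats, pedigree=cohort.pedigree)
        result = parent_swap_analysis(
            records, cohort.pedigree, (trio.father, trio.mother),
            FilterConfig(), res,
        )
        row = result.per_embryo[trio.embryo]
        assert row["control_row"] and row["swapped"] == row["correct"]

    def test_correct_counts_unchanged_by_analysis(self):
        cohort, records = self._cohort(5e-4)
        res = Resources(repeats=cohort.repeats, pedigree=cohort.pedigree)
        trio = cohort.pedigree.trios[0]
        first = parent_swap_analysis(records, cohort.pedigree,
                                     (trio.father, trio.mother),
                                     FilterConfig(), res)
        other = cohort.pedigree.trios[-1]
        second = parent_swap_analysis(records, cohort.pedigree,
                                      (other.father, other.mother),
                                      FilterConfig(), res)
        for embryo in cohort.pedigree.embryos:
            assert (first.per_embryo[embryo]["correct"]
                    == second.per_embryo[embryo]["correct"])


class TestSomaticCascade:
    def _records_and_ped(self):
        depth = 40
        recs = []
        # alt reads 3: below the SNV alt-read floor
        recs.append(VariantRecord("chr1", 10, "A", "T", 50.0, {
            "dad": SampleCall((0, 0), depth, 0, depth),
            "mum": SampleCall((0, 0), depth, 0, depth),
            "kid": SampleCall((0, 1), depth - 3, 3, depth),
        }))
        # healthy candidate, present vs both parents
        recs.append(VariantRecord("chr1", 20, "A", "T", 50.0, {
            "dad": SampleCall((0, 0), depth, 0, depth),
            "mum": SampleCall((0, 0), depth, 0, depth),
            "kid": SampleCall((0, 1), depth - 10, 10, depth),
        }))
        # present vs father only (mother has alt reads)
        recs.append(VariantRecord("chr1", 30, "A", "T", 50.0, {
            "dad": SampleCall((0, 0), depth, 0, depth),
            "mum": SampleCall((0, 0), depth - 2, 2, depth),
            "kid": SampleCall((0, 1), depth - 10, 10, depth),
        }))
        ped = Pedigree(trios=[Trio("dad", "mum", "kid")],
                       group_of={"kid": "sham"})
        return recs, ped

    def test_alt_read_floor_and_intersection(self):
        recs, ped = self._records_and_ped()
        cands = call_somatic_cohort(recs, ped)
        res = Resources(pedigree=ped, cohort_records=recs)
        survivors, ledger = apply_somatic_cascade(cands, FilterConfig(), res)
        assert {c.record.pos for c in survivors} == {20}
        assert len(survivors) == 1  # collapsed to one per (embryo, variant)
        flagged = {c.record.pos: c.flags for c in cands if c.flags}
        assert "depth_alt_reads" in flagged[10]
        # a maternal alt read: removed by the parental-noise stage, which
        # precedes the intersection stage
        assert "parental_noise" in flagged[30]

    def test_intersection_requires_both_comparisons(self):
        # relax the parental-read ceiling so the one-sided call at pos 30
        # reaches the intersection stage, which then removes it
        recs, ped = self._records_and_ped()
        cands = call_somatic_cohort(recs, ped)
        res = Resources(pedigree=ped, cohort_records=recs)
        config = FilterConfig(parental_alt_max=2)
        survivors, _ = apply_somatic_cascade(cands, config, res)
        assert {c.record.pos for c in survivors} == {20}
        flagged = {c.record.pos: c.flags for c in cands if c.flags}
        assert "both_parents" in flagged[30]

    def test_annotation_floor(self):
        recs, ped = self._records_and_ped()
        cands = call_somatic_cohort(recs, ped)
        for c in cands:
            c.annotations["ASMD"] = 120.0
        res = Resources(pedigree=ped, cohort_records=recs)
        survivors, _ = apply_somatic_cascade(cands, FilterConfig(), res)
        assert survivors == []

    def test_contains_trio_survivors_at_equal_thresholds(self, base_cohort):
        cohort, records = base_cohort
        config = FilterConfig(mosaic_reinsertion=False, somatic_min_alt_reads=2)
        res = Resources(repeats=cohort.repeats, microsats=cohort.microsats,
                        cohort_records=records, pedigree=cohort.pedigree)
        trio_surv, _ = apply_cascade(
            call_cohort_dnms(records, cohort.pedigree), config, res)
        somatic_surv, _ = apply_somatic_cascade(
            call_somatic_cohort(records, cohort.pedigree), config, res)
        trio_keys = {c.key for c in trio_surv}
        somatic_keys = {c.key for c in somatic_surv}
        assert trio_keys <= somatic_keys
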