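"""Simulator statistical structure and determinism."""

import dataclasses

import numpy as np
import pytest

from trioaudit import (
    GuideSpec,
    PowerQuery,
    SimConfig,
    basic_quality_gate,
    build_pedigree,
    call_cohort_dnms,
    emit_cohort,
    enumerate_offtargets,
    plant_crispr_edits,
    poisson_detect_power,
    read_joint_vcf,
    sample_allele_depths,
    simulate_cohort,
    simulate_reference,
    simulate_trio_genotypes,
    stage_vaf,
)
from trioaudit.synthetic_trio import ConfigError, embed_guide_targets


class TestReference:
    def test_zero_repeat_fraction(self):
        config = SimConfig(chrom_len=50_000, repeat_fraction=0.0, seed=1)
        _, repeats, _ = simulate_reference(config)
        assert repeats.intervals == []

    def test_determinism(self):
        config = SimConfig(chrom_len=50_000, seed=5)
        a = simulate_reference(config)
        b = simulate_reference(config)
        assert a[0].sequences == b[0].sequences
        assert a[1].intervals == b[1].intervals
        assert a[2].intervals == b[2].intervals

    def test_repeat_coverage_hits_target(self):
        # placement covers exactly the requested fraction of bases
        fractions = []
        for seed in range(20):
            config = SimConfig(chrom_len=100_000, repeat_fraction=0.4, seed=seed)
            _, repeats, _ = simulate_reference(config)
            fractions.append(repeats.covered_bases() / config.chrom_len)
        assert all(0.38 <= f <= 0.42 for f in fractions)

    def test_microsat_runs_embedded(self):
        config = SimConfig(chrom_len=50_000, seed=3, microsat_per_mb=100)
        genome, _, micro = simulate_reference(config)
        assert micro.intervals
        for chrom, s, e in micro.intervals[:10]:
            run = genome.sequences[chrom][s:e]
            # a true repeat run: at most two distinct characters, length >= 8
            assert len(run) >= 8 and len(set(run)) <= 2

    def test_impossible_config_raises(self):
        with pytest.raises(ConfigError):
            simulate_reference(SimConfig(chrom_len=500, repeat_fraction=0.9, seed=0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(repeat_fraction=1.5)
        with pytest.raises(ConfigError):
            SimConfig(dnm_stage_probs={1: 0.6, 2: 0.6})


class TestGenotypes:
    def test_no_planting_requested(self):
        config = SimConfig(chrom_len=30_000, dnm_count_mean=0.0,
                           parental_mosaic_count=0, artifact_indel_count=0,
                           seed=2)
        genome, repeats, micro = simulate_reference(config)
        ped = build_pedigree(config, groups=("sham",))
        rng = np.random.default_rng(0)
        _, truth = simulate_trio_genotypes(genome, config, ped, rng, repeats, micro)
        assert truth.dnms == [] and truth.parental_mosaics == []

    def test_dnm_count_poisson_mean(self):
        config = SimConfig(chrom_len=400_000, dnm_count_mean=20.0,
                           inherited_het_rate=0.0, parental_mosaic_count=0,
                           artifact_indel_count=0, embryo_count_per_group=200,
                           repeat_fraction=0.1, seed=4)
        genome, repeats, micro = simulate_reference(config)
        ped = build_pedigree(config, groups=("sham",))
        rng = np.random.default_rng(4)
        _, truth = simulate_trio_genotypes(genome, config, ped, rng, repeats, micro)
        counts = {}
        for d in truth.dnms:
            counts[d["embryo"]] = counts.get(d["embryo"], 0) + 1
        per_embryo = [counts.get(e, 0) for e in ped.embryos]
        se = np.sqrt(20.0 / len(per_embryo))
        assert abs(np.mean(per_embryo) - 20.0) <= 3 * se

    def test_inherited_variant_has_one_parent(self, base_cohort):
        cohort, _ = base_cohort
        carriers = {v.key: [s for s, (vaf, const) in v.evidence.items() if const]
                    for v in cohort.variants}
        for entry in cohort.truth.inherited:
            key = (entry["chrom"], entry["pos"], entry["ref"], entry["alt"])
            parents = [s for s in carriers[key] if s in cohort.pedigree.parents]
            assert parents == [entry["parent"]]

    def test_stage_vaf_law(self):
        assert stage_vaf(1) == 0.5
        assert stage_vaf(2) == 0.25
        assert stage_vaf(3) == 0.125

    def test_mendelian_property_no_candidates_without_planting(self):
        # inherited variation only, noise-free: trio calling finds nothing
        config = SimConfig(chrom_len=100_000, dnm_count_mean=0.0,
                           parental_mosaic_count=0, artifact_indel_count=0,
                           error_rate=0.0, inherited_het_rate=1e-3, seed=6)
        cohort, records = simulate_cohort(config)
        gated = basic_quality_gate(records)
        assert call_cohort_dnms(gated, cohort.pedigree) == []


class TestAlleleDepths:
    def test_extremes(self, rng):
        for _ in range(50):
            ad_ref, ad_alt, depth = sample_allele_depths(0.0, 40, rng)
            assert ad_alt == 0 and ad_ref == depth
            ad_ref, ad_alt, depth = sample_allele_depths(1.0, 40, rng)
            assert ad_ref == 0 and ad_alt == depth

    def test_agrees_with_power_model(self):
        # empirical detection over many draws matches the Poisson model
        rng = np.random.default_rng(99)
        res = poisson_detect_power(PowerQuery(depth=39.5, vaf=0.28, min_vaf=0.10))
        n = 10_000
        detected = 0
        for _ in range(n):
            _, ad_alt, _ = sample_allele_depths(11.0 / 39.5, 39.5, rng)
            if ad_alt >= res.min_alt_reads:
                detected += 1
        p = res.detect_probability
        se = np.sqrt(p * (1 - p) / n)
        assert abs(detected / n - p) <= 3 * se + 1e-12


class TestEdits:
    def _setup(self, n_embryos, seed=8):
        config = SimConfig(chrom_len=60_000, dnm_count_mean=0.0,
                           inherited_het_rate=0.0, parental_mosaic_count=0,
                           artifact_indel_count=0, repeat_fraction=0.0,
                           embryo_count_per_group=n_embryos, seed=seed)
        genome, repeats, micro = simulate_reference(config)
        guide = GuideSpec("GCTCCCATCTTCAGCAGATG", ("NGG",), "Tyr2R")
        rng = np.random.default_rng(seed)
        embed_guide_targets(genome, {"Tyr2R": guide}, rng)
        ped = build_pedigree(config, groups=("tyr2r",), shared_parents={})
        variants, truth = simulate_trio_genotypes(genome, config, ped, rng)
        sites = enumerate_offtargets(genome, guide, 0, 0, False)
        return genome, guide, sites, ped, variants, truth, rng

    def test_zero_efficiency_no_edits(self):
        genome, guide, sites, ped, variants, truth, rng = self._setup(3)
        plant_crispr_edits(variants, truth, genome, guide, sites,
                           embryos=ped.embryos, rng=rng, on_target_efficiency=0.0)
        assert truth.edits == []

    def test_degenerate_mosaic_dist(self):
        genome, guide, sites, ped, variants, truth, rng = self._setup(4)
        plant_crispr_edits(variants, truth, genome, guide, sites,
                           embryos=ped.embryos, rng=rng,
                           on_target_efficiency=1.0, mosaic_allele_dist={2: 1.0})
        per_embryo = {}
        for e in truth.edits:
            per_embryo[e["embryo"]] = per_embryo.get(e["embryo"], 0) + 1
        assert per_embryo == {e: 2 for e in ped.embryos}
        # distinct alleles at one cut position
        keys = {(e["chrom"], e["pos"], e["alt"]) for e in truth.edits}
        assert len(keys) == len(truth.edits)

    def test_efficiency_binomial(self):
        genome, guide, sites, ped, variants, truth, rng = self._setup(324)
        plant_crispr_edits(variants, truth, genome, guide, sites,
                           embryos=ped.embryos, rng=rng, on_target_efficiency=0.70)
        edited = len({e["embryo"] for e in truth.edits})
        n = 324
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(edited / n - 0.70) <= 3 * se

    def test_requires_on_target_site(self):
        genome, guide, sites, ped, variants, truth, rng = self._setup(2)
        off_only = [dataclasses.replace(s, is_on_target=False) for s in sites]
        with pytest.raises(ValueError):
            plant_crispr_edits(variants, truth, genome, guide, off_only,
                               embryos=ped.embryos, rng=rng)


class TestEmission:
    def test_emitted_vcf_round_trips(self, tmp_path, base_cohort):
        cohort, records = base_cohort
        paths = emit_cohort(cohort, records, tmp_path)
        again, samples = read_joint_vcf(paths["vcf"])
        assert samples == cohort.pedigree.samples  # parents then embryos
        assert len(again) == len(records)
        by_key = {r.key: r for r in records}
        for rec in again:
            orig = by_key[rec.key]
            for s in samples:
                assert rec.samples[s].ad_alt == orig.samples[s].ad_alt
                assert rec.samples[s].depth == orig.samples[s].depth

    def test_cohort_determinism(self, tmp_path):
        config = SimConfig(chrom_len=60_000, seed=21)
        out = []
        for sub in ("a", "b"):
            cohort, records = simulate_cohort(config)
            paths = emit_cohort(cohort, records, tmp_path / sub)
            out.append({k: p.read_bytes() for k, p in paths.items()})
        assert out[0] == out[1]

    def test_truth_json_round_trip(self, tmp_path, base_cohort):
        cohort, _ = base_cohort
        path = tmp_path / "truth.json"
        cohort.truth.to_json(path)
        from trioaudit import TruthSet

        again = TruthSet.from_json(path)
        assert again == cohort.truth
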