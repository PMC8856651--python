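"""VCF reading, dominant-model filtering, population filter and concordance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from famseg import (
    Affection,
    GenotypeMatrix,
    VariantRecord,
    WES_SAMPLE_IDS,
    dominant_filter,
    population_absence_filter,
    read_vcf,
    write_vcf,
)
from famseg.errors import ConfigurationError
from famseg.segregation import HET, HOM_ALT, HOM_REF, MISSING, validation_concordance

VCF_SMALL = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
2\t200\t.\tC\tA,T\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2
3\t300\t.\tG\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
"""


@pytest.fixture()
def small_vcf(tmp_path):
    p = tmp_path / "small.vcf"
    p.write_text(VCF_SMALL)
    return p


class TestReadVcf:
    def test_gt_decoding(self, small_vcf):
        gm = read_vcf(small_vcf)
        assert gm.sample_ids == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(gm.calls[0], [HOM_REF, HET, HOM_ALT])

    def test_multiallelic_decomposition(self, small_vcf):
        gm = read_vcf(small_vcf)
        site2 = [v for v in gm.variants if v.pos == 200]
        assert [(v.ref, v.alt) for v in site2] == [("C", "A"), ("C", "T")]
        # 0/1, 1/2, 2/2 w.r.t. alt A then alt T
        np.testing.assert_array_equal(
            gm.calls[gm.variant_index(site2[0])], [HET, HET, HOM_REF])
        np.testing.assert_array_equal(
            gm.calls[gm.variant_index(site2[1])], [HOM_REF, HET, HOM_ALT])

    def test_missing_genotype(self, small_vcf):
        gm = read_vcf(small_vcf)
        v300 = next(v for v in gm.variants if v.pos == 300)
        assert gm.calls_for(v300)["s1"] == MISSING

    def test_generator_roundtrip(self, family_sim, tmp_path):
        gm, ped, _ = family_sim
        out = tmp_path / "family.vcf"
        write_vcf(gm, out)
        again = read_vcf(out)
        assert again.sample_ids == gm.sample_ids
        assert len(again) == len(gm) and len(gm.sample_ids) == 23
        np.testing.assert_array_equal(again.calls, gm.calls)


class TestDominantFilter:
    def test_planted_variant_segregates_in_10_and_23(self, family_sim):
        gm, ped, truth = family_sim
        causal = gm.variants[0]
        full = dominant_filter(gm, ped)[0]
        assert full.segregates and not full.violations
        assert full.n_affected_carrier == 12
        assert full.n_unaffected_noncarrier == 11
        wes = gm.subset_samples(list(WES_SAMPLE_IDS))
        sub = dominant_filter(wes, ped)[0]
        assert sub.segregates and not sub.violations

    def test_single_violation_listed(self, family_sim):
        gm, ped, _ = family_sim
        calls = gm.calls[:1].copy()
        # engineer one unaffected member carrying the variant
        unaffected = next(s for s in gm.sample_ids
                          if ped.get(s).affected is Affection.UNAFFECTED)
        calls[0, gm.sample_ids.index(unaffected)] = HET
        bad = GenotypeMatrix(gm.variants[:1], gm.sample_ids, calls)
        verdict = dominant_filter(bad, ped)[0]
        assert not verdict.segregates
        assert [s for s, _ in verdict.violations] == [unaffected]

    def test_planted_recovered_among_background(self, family_sim):
        """Exactly the planted co-segregating variants pass on a 10-sample
        exome cohort (chance co-segregators checked against a direct mask)."""
        gm, ped, _ = family_sim
        # plant three perfectly co-segregating variants by cloning the causal
        causal_row = gm.calls[0]
        planted = []
        rows = [gm.calls]
        for i in range(2):
            planted.append(VariantRecord(chrom="20", pos=10 + i, ref="A", alt="C"))
            rows.append(causal_row[None, :])
        big = GenotypeMatrix(gm.variants + planted, gm.sample_ids,
                             np.vstack(rows))
        wes = big.subset_samples(list(WES_SAMPLE_IDS))
        verdicts = dominant_filter(wes, ped)
        passing = {str(v.variant) for v in verdicts if v.segregates}
        # direct-mask oracle for what must pass on these 10 samples
        aff = np.array([ped.get(s).affected is Affection.AFFECTED
                        for s in wes.sample_ids])
        expect = {
            str(v) for v, row in zip(wes.variants, wes.calls)
            if (row[aff] >= 1).all() and (row[~aff] == 0).all()
        }
        assert passing == expect
        assert {str(gm.variants[0])} | {str(p) for p in planted} <= passing

    def test_superset_stricter_than_subset(self, family_sim):
        gm, ped, _ = family_sim
        wes = gm.subset_samples(list(WES_SAMPLE_IDS))
        pass_full = {str(v.variant) for v in dominant_filter(gm, ped) if v.segregates}
        pass_sub = {str(v.variant) for v in dominant_filter(wes, ped) if v.segregates}
        assert pass_full <= pass_sub

    def test_missing_compatible_but_counted(self, family_ped, family_sim):
        gm, ped, _ = family_sim
        calls = gm.calls[:1].copy()
        calls[0, 0] = MISSING
        m = GenotypeMatrix(gm.variants[:1], gm.sample_ids, calls)
        lenient = dominant_filter(m, ped)[0]
        assert lenient.segregates and lenient.n_missing == 1
        strict = dominant_filter(m, ped, strict_missing=True)[0]
        assert not strict.segregates

    def test_no_overlap_is_config_error(self, family_ped):
        gm = GenotypeMatrix(
            [VariantRecord(chrom="1", pos=1, ref="A", alt="G")],
            ["nobody"], np.zeros((1, 1), dtype=np.int8))
        with pytest.raises(ConfigurationError):
            dominant_filter(gm, family_ped)

    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rnd):
        """Verdicts are invariant to variant and sample order."""
        from famseg import FamilySimConfig, simulate_family
        gm, ped, _ = simulate_family(FamilySimConfig(seed=3, n_background_variants=30))
        v_order = list(range(len(gm)))
        s_order = list(range(len(gm.sample_ids)))
        rnd.shuffle(v_order)
        rnd.shuffle(s_order)
        shuffled = GenotypeMatrix(
            [gm.variants[i] for i in v_order],
            [gm.sample_ids[j] for j in s_order],
            gm.calls[np.ix_(v_order, s_order)],
        )
        base = {str(v.variant): v.segregates for v in dominant_filter(gm, ped)}
        perm = {str(v.variant): v.segregates for v in dominant_filter(shuffled, ped)}
        assert base == perm


class TestPopulationFilter:
    def _verdict(self, pop_af):
        from famseg.segregation import SegregationVerdict
        v = VariantRecord(chrom="1", pos=5, ref="A", alt="G", pop_af=pop_af)
        return SegregationVerdict(v, True, 1, 1, 0)

    def test_absent_kept(self):
        kept = population_absence_filter([self._verdict({"gnomAD": 0.0})], max_af=0.0)
        assert len(kept) == 1

    def test_observed_removed(self):
        assert population_absence_filter([self._verdict({"gnomAD": 0.01})],
                                         max_af=0.0) == []

    def test_unobserved_kept_and_flagged(self):
        kept = population_absence_filter([self._verdict({})], max_af=0.0)
        assert len(kept) == 1
        assert any("unobserved" in n for n in kept[0].notes)

    def test_unknown_panel_errors(self):
        with pytest.raises(ConfigurationError, match="panel"):
            population_absence_filter([self._verdict({})],
                                      require_panels=["NoSuchPanel"])


class TestConcordance:
    def test_identical_and_flipped(self, family_sim):
        gm, ped, _ = family_sim
        causal = gm.variants[0]
        wes = gm.subset_samples(list(WES_SAMPLE_IDS))
        rep = validation_concordance(wes, gm, causal, ped)
        assert rep.n_discordant == 0
        assert rep.full_family_segregates

        flipped_calls = wes.calls.copy()
        flipped_calls[0, 0] = HET if flipped_calls[0, 0] == HOM_REF else HOM_REF
        flipped = GenotypeMatrix(wes.variants, wes.sample_ids, flipped_calls)
        rep2 = validation_concordance(flipped, gm, causal, ped)
        assert rep2.discordant_ids == [wes.sample_ids[0]]
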