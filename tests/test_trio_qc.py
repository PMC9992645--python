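"""Unit tests for the hard-filter QC cascade and de novo calling."""

import dataclasses

import pytest

from denovoprio import (ConfigurationError, DataError, MemberGenotype,
                        QCThresholds, SchemaError, SiteRecord, TrioGenotype,
                        call_denovo, classify_vcf, genotype_pass,
                        rare_and_consequence_pass, run_qc_pipeline, site_pass)
from denovoprio.trio_qc import consequence_pass, rare_pass


def _site(**kw):
    base = dict(chrom="chr5", pos=100, ref="A", alt="G", mq=60.0, qd=20.0,
                fs=5.0, sor=1.0, mq_rank_sum=0.0, read_pos_rank_sum=0.0,
                af_nonneuro=None, consequence_class="missense", cadd=30.0)
    base.update(kw)
    return SiteRecord(**base)


def _member(gt=(0, 1), ad=(15, 15), dp=30, gq=99):
    return MemberGenotype(gt=gt, dp=dp, gq=gq, ad=ad)


class TestSitePass:
    @pytest.mark.parametrize(
        "field,value,expected",
        [
            ("mq", 35.0, True),     # removal is strictly MQ < 35
            ("mq", 34.9, False),
            ("qd", 2.0, False),     # QD <= 2 removed
            ("qd", 2.1, True),
            ("fs", 60.0, True),     # kept while FS <= 60
            ("fs", 60.1, False),
            ("sor", 3.0, True),     # SOR > 3 removed
            ("sor", 3.1, False),
            ("mq_rank_sum", -12.5, True),
            ("mq_rank_sum", -12.6, False),
            ("read_pos_rank_sum", -8.0, False),  # <= -8 removed
            ("read_pos_rank_sum", -7.9, True),
        ],
    )
    def test_boundaries(self, thresholds, field, value, expected):
        assert site_pass(_site(**{field: value}), thresholds) is expected

    def test_missing_metric_passes(self, thresholds):
        assert site_pass(_site(mq_rank_sum=None, read_pos_rank_sum=None), thresholds)

    def test_all_metrics_missing_passes(self, thresholds):
        rec = _site(mq=None, qd=None, fs=None, sor=None,
                    mq_rank_sum=None, read_pos_rank_sum=None)
        assert site_pass(rec, thresholds)


class TestGenotypePass:
    def test_nominal_het_passes(self, thresholds):
        assert genotype_pass(_member(), thresholds)

    @pytest.mark.parametrize(
        "ad,expected",
        [((15, 5), False),   # AB exactly 0.25: strict window
         ((12, 8), True),    # AB 0.4
         ((5, 15), False),   # AB exactly 0.75
         ((4, 16), False)],  # AB 0.8
    )
    def test_het_ab_window(self, thresholds, ad, expected):
        g = _member(ad=ad, dp=sum(ad))
        assert genotype_pass(g, thresholds) is expected

    @pytest.mark.parametrize("dp,expected", [(10, False), (11, True)])
    def test_depth_strict(self, thresholds, dp, expected):
        g = _member(ad=(dp - dp // 2, dp // 2), dp=dp)
        assert genotype_pass(g, thresholds) is expected

    @pytest.mark.parametrize("gq,expected", [(25, False), (26, True)])
    def test_gq_strict(self, thresholds, gq, expected):
        assert genotype_pass(_member(gq=gq), thresholds) is expected

    def test_homref_uses_purity_rule(self, thresholds):
        clean = _member(gt=(0, 0), ad=(30, 0))
        dirty = _member(gt=(0, 0), ad=(22, 8))  # AB 0.27 > 0.25
        assert genotype_pass(clean, thresholds)
        assert not genotype_pass(dirty, thresholds)

    def test_zero_coverage_fails(self, thresholds):
        assert not genotype_pass(_member(ad=(0, 0), dp=0), thresholds)


class TestRareAndConsequence:
    def test_study_variant_survives(self, thresholds):
        # a missense variant with CADD 22.9 and no population frequency
        rec = _site(pos=66438324, ref="T", alt="C", cadd=22.9, af_nonneuro=None)
        assert rare_and_consequence_pass(rec, thresholds)

    @pytest.mark.parametrize("cadd,expected", [(20.0, False), (20.1, True)])
    def test_cadd_strict(self, thresholds, cadd, expected):
        assert consequence_pass(_site(cadd=cadd), thresholds) is expected

    def test_lof_kept_without_cadd(self, thresholds):
        for csq in ("stop_gain", "frameshift", "splice"):
            assert consequence_pass(_site(consequence_class=csq, cadd=None), thresholds)

    def test_synonymous_dropped(self, thresholds):
        assert not consequence_pass(_site(consequence_class="synonymous"), thresholds)

    @pytest.mark.parametrize("af,expected", [(0.0009, True), (0.001, False)])
    def test_af_strict(self, thresholds, af, expected):
        assert rare_pass(_site(af_nonneuro=af), thresholds) is expected

    def test_missing_af_is_rare(self, thresholds):
        assert rare_pass(_site(af_nonneuro=None), thresholds)


class TestCallDenovo:
    def _trio(self, child=None, father=None, mother=None):
        return TrioGenotype(
            proband=child or _member(),
            father=father or _member(gt=(0, 0), ad=(30, 0)),
            mother=mother or _member(gt=(0, 0), ad=(30, 0)),
        )

    def test_clean_trio_is_denovo(self, thresholds):
        assert call_denovo(self._trio(), thresholds)

    def test_het_father_blocks(self, thresholds):
        trio = self._trio(father=_member(gt=(0, 1)))
        assert not call_denovo(trio, thresholds)

    def test_missing_parent_blocks(self, thresholds):
        trio = self._trio(mother=_member(gt=(None, None), ad=(0, 0)))
        assert not call_denovo(trio, thresholds)

    def test_impure_parent_blocks(self, thresholds):
        trio = self._trio(father=_member(gt=(0, 0), ad=(22, 8)))
        assert not call_denovo(trio, thresholds)


class TestPipeline:
    def test_truth_equivalence(self, trio_vcf, thresholds):
        path, truth = trio_vcf
        labels = classify_vcf(path, thresholds)
        assert set(labels.index) == set(truth.index)
        for col in truth.columns:
            assert (labels.loc[truth.index, col] == truth[col]).all(), col

    def test_funnel_conservation(self, trio_vcf, thresholds):
        path, truth = trio_vcf
        table, funnel = run_qc_pipeline(path, thresholds)
        assert funnel["records_in"] == len(truth)
        assert funnel["records_in"] == funnel["records_out"] + sum(
            funnel["removed"].values()
        )
        assert funnel["records_out"] == int(truth.all(axis=1).sum())

    def test_loosening_thresholds_never_shrinks_survivors(self, trio_vcf):
        path, _ = trio_vcf
        strict, _ = run_qc_pipeline(path, QCThresholds())
        loose = QCThresholds(mq_min=30, qd_min=1, fs_max=70, sor_max=4,
                             mq_rank_sum_min=-14, read_pos_rank_sum_min=-9,
                             ab_low=0.2, ab_high=0.8, dp_min=8, gq_min=20,
                             cadd_min=15, af_max=0.01, parent_ab_max=0.3)
        relaxed, _ = run_qc_pipeline(path, loose)
        key = ["chrom", "pos", "ref", "alt"]
        strict_keys = set(map(tuple, strict[key].itertuples(index=False)))
        relaxed_keys = set(map(tuple, relaxed[key].itertuples(index=False)))
        assert strict_keys <= relaxed_keys

    def test_missing_sample_is_schema_error(self, trio_vcf):
        path, _ = trio_vcf
        with pytest.raises(SchemaError, match="sample"):
            run_qc_pipeline(path, proband="nonexistent")

    def test_missing_info_field_is_schema_error(self, tmp_path, trio_vcf):
        path, _ = trio_vcf
        text = path.read_text().replace(
            '##INFO=<ID=CADD,Number=1,Type=Float,Description="Scaled CADD score">\n', ""
        )
        bad = tmp_path / "bad.vcf"
        bad.write_text("\n".join(
            line for line in text.splitlines() if ";CADD=" not in line.replace("=", "=")
        ) + "\n")
        # strip CADD entries from INFO column too
        import re
        bad.write_text(re.sub(r";?CADD=[^;\t]+", "", text) + "")
        with pytest.raises(SchemaError, match="CADD"):
            run_qc_pipeline(bad)

    def test_multiallelic_rejected(self, tmp_path, trio_vcf):
        path, _ = trio_vcf
        lines = path.read_text().splitlines()
        body = [l for l in lines if not l.startswith("#")]
        first = body[0].split("\t")
        first[4] = first[4] + ",T" if first[4] != "T" else "A,C"
        bad = tmp_path / "multi.vcf"
        header = [l for l in lines if l.startswith("#")]
        bad.write_text("\n".join(header + ["\t".join(first)]) + "\n")
        with pytest.raises(DataError, match="multi-allelic"):
            run_qc_pipeline(bad)


class TestThresholdValidation:
    def test_inverted_ab_window_rejected(self):
        with pytest.raises(ConfigurationError):
            QCThresholds(ab_low=0.8, ab_high=0.2)

    def test_bad_af_rejected(self):
        with pytest.raises(ConfigurationError):
            QCThresholds(af_max=0.0)

    def test_roundtrip_dict(self):
        t = QCThresholds(mq_min=40)
        assert QCThresholds.from_dict(t.to_dict()) == t
        with pytest.raises(ConfigurationError):
            QCThresholds.from_dict({"bogus": 1})
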