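"""VPI/GPI assignment, filtering and report ordering."""

import itertools
import random

import pytest

from varcurate.obsdb import ObservationStore
from varcurate.prioritise import (
    PriorityDecision,
    apply_filters,
    assign_gpi,
    assign_vpi,
    chromosome_sort_key,
    sort_for_report,
)
from varcurate.profiles import AnalysisProfile
from varcurate.variant_ingest import ConsequenceClass, VariantRecord


def make_record(
    consequence=ConsequenceClass.MISSENSE,
    af=None,
    condel=None,
    gene="BRCA1",
    depth=100,
    qual=500.0,
    **kw,
):
    return VariantRecord(
        "s1", kw.pop("chrom", "chr1"), kw.pop("pos", 1000),
        kw.pop("ref", "A"), kw.pop("alt", "G"),
        gene=gene, consequence=consequence,
        af_evs=af, af_1000g=af, af_exac=af,
        condel=condel, depth=depth, qual=qual, **kw,
    )


# Independent restatement of the tier rules, written directly from their
# definition (bands, not record fields), used as the enumeration oracle.
def vpi_oracle(consequence, af_band, condel_band):
    if consequence in ("FRAMESHIFT", "TRUNCATING", "SPLICE"):
        return 4
    if consequence not in ("MISSENSE", "INFRAME_INDEL"):
        return 0
    if af_band in ("absent", "very_rare"):
        return 3 if condel_band == "high" else 2
    if af_band == "rare":
        return 1
    return 0


AF_BANDS = {"absent": None, "very_rare": 0.0001, "rare": 0.005, "common": 0.05}
CONDEL_BANDS = {"absent": None, "low": 0.07, "high": 0.071}


class TestAssignVpi:
    @pytest.mark.parametrize(
        "consequence,af_band,condel_band",
        list(
            itertools.product(
                [c.value for c in ConsequenceClass], AF_BANDS, CONDEL_BANDS
            )
        ),
    )
    def test_exhaustive_decision_table(self, consequence, af_band, condel_band):
        """Every consequence x AF-band x Condel-band cell matches the
        printed tier rules (strict inequalities at 0.01 / 0.0005 / 0.07)."""
        rec = make_record(
            consequence=ConsequenceClass(consequence),
            af=AF_BANDS[af_band],
            condel=CONDEL_BANDS[condel_band],
        )
        profile = AnalysisProfile(name="X")
        assert assign_vpi(rec, profile) == vpi_oracle(consequence, af_band, condel_band)

    def test_rare_missense_is_tier_one(self):
        rec = VariantRecord(
            "s", "chr1", 10, "A", "G", gene="G",
            consequence=ConsequenceClass.MISSENSE,
            af_evs=0.005, af_1000g=0.004, af_exac=0.008, condel=0.9,
        )
        assert assign_vpi(rec, AnalysisProfile(name="X")) == 1

    def test_novel_conserved_missense_is_tier_three(self):
        rec = make_record(af=None, condel=0.9)
        assert assign_vpi(rec, AnalysisProfile(name="X")) == 3

    def test_very_rare_unconserved_is_tier_two(self):
        rec = make_record(af=0.0001, condel=0.05)
        assert assign_vpi(rec, AnalysisProfile(name="X")) == 2

    def test_common_frameshift_still_tier_four(self):
        rec = make_record(consequence=ConsequenceClass.FRAMESHIFT, af=0.3)
        assert assign_vpi(rec, AnalysisProfile(name="X")) == 4

    def test_synonymous_never_tiered(self):
        rec = make_record(consequence=ConsequenceClass.SYNONYMOUS, af=None)
        assert assign_vpi(rec, AnalysisProfile(name="X")) == 0

    def test_splice_window_position_promotes_to_four(self):
        rec = make_record(consequence=ConsequenceClass.OTHER)
        assert assign_vpi(rec, AnalysisProfile(name="X"), is_splice=True) == 4

    def test_profile_switch_applies_af_cut_to_tier_four(self):
        rec = make_record(consequence=ConsequenceClass.FRAMESHIFT, af=0.3)
        prof = AnalysisProfile(name="X", apply_af_filter_to_vpi4=True)
        assert assign_vpi(rec, prof) == 0
        rare = make_record(consequence=ConsequenceClass.FRAMESHIFT, af=0.001)
        assert assign_vpi(rare, prof) == 4

    def test_tier_nesting_for_missense_cells(self):
        """VPI>=2 implies VPI>=1 and VPI=3 implies VPI>=2 predicates:
        lowering a variant's evidence can only lower its tier."""
        profile = AnalysisProfile(name="X")
        for af in AF_BANDS.values():
            for condel in CONDEL_BANDS.values():
                rec = make_record(af=af, condel=condel)
                tier = assign_vpi(rec, profile)
                if tier >= 2:
                    weaker = make_record(af=0.005, condel=condel)
                    assert assign_vpi(weaker, profile) >= 1
                if tier == 3:
                    unconserved = make_record(af=af, condel=None)
                    assert assign_vpi(unconserved, profile) == 2

    def test_lowering_very_rare_threshold_never_raises_vpi(self):
        base = AnalysisProfile(name="X")
        tighter = AnalysisProfile(name="X", very_rare_af_threshold=0.0001)
        for af in (None, 0.00005, 0.0003, 0.005, 0.05):
            for condel in (None, 0.5):
                rec = make_record(af=af, condel=condel)
                assert assign_vpi(rec, tighter) <= assign_vpi(rec, base)


class TestAssignGpi:
    def test_known_causal_gene_scores_two(self, profile):
        assert assign_gpi(make_record(gene="MYH7"), profile) == 2

    def test_off_target_gene_scores_zero(self, profile):
        assert assign_gpi(make_record(gene="NOTONPANEL"), profile) == 0

    def test_insilico_and_clinician_takes_max(self):
        prof = AnalysisProfile(
            name="X",
            target_genes=frozenset({"G"}),
            insilico_genes=frozenset({"G"}),
            clinician_genes=frozenset({"G"}),
        )
        assert assign_gpi(make_record(gene="G"), prof) == 4

    def test_absent_gene_scores_zero(self, profile):
        assert assign_gpi(make_record(gene=None), profile) == 0


class TestApplyFilters:
    def run(self, records, profile, **kw):
        retained, removed = apply_filters(records, profile, **kw)
        # partition property checked on every call
        assert len(retained) + len(removed) == len(records)
        return retained, removed

    def test_clean_variant_retained(self, profile):
        rec = make_record(af=0.0001, gene="BRCA1", depth=50, qual=500)
        rec.vpi, rec.gpi = 2, 1
        retained, removed = self.run([rec], profile)
        assert retained == [rec] and not removed

    def test_vpi_zero_hidden(self, profile):
        rec = make_record(af=0.5, gene="BRCA1")
        rec.vpi, rec.gpi = 0, 1
        _, removed = self.run([rec], profile)
        assert removed[0][1].filter_reasons == ["HIDDEN_BELOW_VPI1"]

    def test_excluded_vs_off_target_reasons_distinguished(self, profile):
        excluded = make_record(gene="BAD1")
        excluded.vpi, excluded.gpi = 3, 0
        off = make_record(gene="NOPE", pos=2000)
        off.vpi, off.gpi = 3, 0
        _, removed = self.run([excluded, off], profile)
        reasons = {r.gene: d.filter_reasons for r, d in removed}
        assert reasons == {"BAD1": ["GENE_EXCLUDED"], "NOPE": ["GENE_OFF_TARGET"]}

    def test_depth_and_qual_gates(self, profile):
        shallow = make_record(depth=profile.min_variant_coverage - 1)
        shallow.vpi = shallow.gpi = 1
        noisy = make_record(qual=profile.min_variant_qual - 1, pos=2000)
        noisy.vpi = noisy.gpi = 1
        _, removed = self.run([shallow, noisy], profile)
        assert [d.filter_reasons for _, d in removed] == [["LOW_DEPTH"], ["LOW_QUAL"]]

    def test_internal_db_exclusion_matches_brute_force(self, tmp_path, profile):
        """A variant seen in 5 prior samples across 3 other cohorts is
        excluded under min_other_cohort_samples=3; the brute-force count
        over the constructed store agrees."""
        store = ObservationStore(tmp_path / "obs.db")
        rec = make_record(gene="BRCA1", af=None, condel=0.9)
        rec.vpi, rec.gpi = 4, 1
        placements = [
            ("p1", "COHA"), ("p2", "COHA"), ("p3", "COHB"),
            ("p4", "COHC"), ("p5", "QUERY"),
        ]
        for sid, cohort in placements:
            store.register_sample(sid, cohort, [rec.key])
        _, removed = self.run(
            [rec], profile, store=store, querying_cohort="QUERY"
        )
        assert removed[0][1].filter_reasons == ["INTERNAL_DB_COMMON"]
        brute_other = sum(1 for _, c in placements if c != "QUERY")
        assert brute_other >= profile.internal_db_policy.min_other_cohort_samples
        assert rec.internal_count == len(placements)
        store.close()

    def test_own_prior_registration_never_filters_itself(self, tmp_path, profile):
        store = ObservationStore(tmp_path / "obs.db")
        rec = make_record(gene="BRCA1")
        rec.vpi, rec.gpi = 2, 1
        # the only observations are this sample's own earlier analyses
        store.register_sample("s1", "COHA", [rec.key])
        store.register_sample("other", "COHB", [])
        retained, _ = self.run([rec], profile, store=store, querying_cohort="COHA")
        assert retained == [rec]
        store.close()

    def test_shrinking_rare_threshold_never_grows_retained_set(self, profile):
        records = []
        for i, af in enumerate((None, 0.0001, 0.004, 0.008, 0.02)):
            records.append(make_record(af=af, condel=0.5, pos=1000 + i, gene="BRCA1"))
        import dataclasses

        tight = dataclasses.replace(profile, rare_af_threshold=0.005)
        from varcurate.prioritise import annotate_priorities

        loose_retained, _ = self.run(
            annotate_priorities([dataclasses.replace(r) for r in records], profile),
            profile,
        )
        tight_retained, _ = self.run(
            annotate_priorities([dataclasses.replace(r) for r in records], tight),
            tight,
        )
        loose_keys = {r.key for r in loose_retained}
        assert {r.key for r in tight_retained} <= loose_keys


class TestSortForReport:
    def rec(self, vpi, gpi, chrom="chr1", pos=100, alt="G"):
        r = make_record(chrom=chrom, pos=pos, ref="C", alt=alt)
        r.vpi, r.gpi = vpi, gpi
        return r

    def test_most_promising_first(self):
        a, b, c = self.rec(4, 4), self.rec(4, 1), self.rec(1, 4)
        assert sort_for_report([c, b, a]) == [a, b, c]

    def test_single_record_identity(self):
        r = self.rec(2, 2)
        assert sort_for_report([r]) == [r]

    def test_alt_tie_break_lexicographic(self):
        a = self.rec(2, 2, alt="T")
        b = self.rec(2, 2, alt="A")
        assert sort_for_report([a, b]) == [b, a]

    def test_karyotype_chromosome_order(self):
        order = ["chr2", "chr10", "chrX", "chrY", "chrMT", "chrUn_gl000220"]
        recs = [self.rec(1, 1, chrom=c) for c in reversed(order)]
        assert [r.chrom for r in sort_for_report(recs)] == order

    def test_permutation_invariance(self):
        rng = random.Random(7)
        records = [
            self.rec(vpi, gpi, chrom=chrom, pos=pos, alt=alt)
            for vpi in (1, 4)
            for gpi in (1, 3)
            for chrom in ("chr1", "chrX")
            for pos in (5, 500)
            for alt in ("A", "T")
        ]
        reference = sort_for_report(records)
        for _ in range(20):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert sort_for_report(shuffled) == reference


def test_chromosome_sort_key_handles_prefixes():
    assert chromosome_sort_key("chr1") < chromosome_sort_key("2")
    assert chromosome_sort_key("22") < chromosome_sort_key("X")
    assert chromosome_sort_key("MT") < chromosome_sort_key("weird_contig")


def test_priority_decision_consistency_enforced():
    with pytest.raises(ValueError):
        PriorityDecision(1, 1, True, ["LOW_DEPTH"])
    with pytest.raises(ValueError):
        PriorityDecision(1, 1, False, [])
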