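"""Allele calling: collapse, chimera rule, confirmation, summaries."""

from collections import defaultdict

import numpy as np
import pytest

from mhcrep import calling, seqio, simlib
from mhcrep.seqio import Allele, CloneRead

from conftest import call_pipeline, reads_from_libraries


def _read(clone, seq, ind="I1", tpl="gDNA", rep="1"):
    return CloneRead(clone, ind, tpl, rep, seq)


class TestCollapse:
    def test_identical_reads_collapse(self):
        reads = [_read(f"c{i}", "ACGTACGT") for i in range(3)]
        (variant,) = calling.collapse_identical(reads)
        assert variant.total_copies == 3
        assert variant.support[("I1", "gDNA", "1")] == 3

    def test_nested_lengths_merge_to_longest(self):
        # a 231 bp read that is an exact prefix of a 273 bp read: one allele,
        # consensus is the long form
        rng = np.random.default_rng(0)
        long = "".join(rng.choice(list("ACGT"), 273))
        reads = [_read("c1", long), _read("c2", long[:231], rep="2")]
        (variant,) = calling.collapse_identical(reads)
        assert variant.sequence == long
        assert len(variant.sequence) == 273
        assert variant.total_copies == 2

    def test_single_mismatch_keeps_variants_apart(self):
        a = "ACGTACGTACGT"
        b = "ACGTACGTACGA"
        variants = calling.collapse_identical([_read("c1", a), _read("c2", b)])
        assert len(variants) == 2

    def test_reverse_complement_reorientation(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 120))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        variants = calling.collapse_identical(
            [_read("c1", seq), _read("c2", rc)], reference=seq[:60]
        )
        assert len(variants) == 1 and variants[0].total_copies == 2


class TestChimeraRule:
    def _variants(self, triples):
        """triples: (sequence, reaction, count)"""
        out = []
        for seq, reactions in triples:
            v = calling.CandidateVariant(sequence=seq)
            for rx, n in reactions:
                v.support[rx] = n
            out.append(v)
        return out

    def test_recombinant_in_one_reaction_is_flagged(self):
        rx = ("I1", "gDNA", "1")
        p1 = "AAAAAAAAAA"
        p2 = "CCCCCCCCCC"
        chim = "AAAACCCCCC"
        variants = self._variants(
            [(p1, [(rx, 5), (("I1", "gDNA", "2"), 4)]),
             (p2, [(rx, 6), (("I1", "gDNA", "2"), 2)]),
             (chim, [(rx, 1)])]
        )
        clean, calls = calling.detect_chimeras(variants)
        assert [c.variant_sequence for c in calls] == [chim]
        lo, hi = calls[0].breakpoint_window
        assert lo <= 4 < hi  # true breakpoint inside the reported window
        assert chim not in {v.sequence for v in clean}

    def test_chimera_seen_in_two_reactions_is_not_flagged(self):
        # the rule demands "only existing in one PCR product"
        rx1, rx2 = ("I1", "gDNA", "1"), ("I1", "gDNA", "2")
        variants = self._variants(
            [("AAAAAAAAAA", [(rx1, 5), (rx2, 5)]),
             ("CCCCCCCCCC", [(rx1, 5), (rx2, 5)]),
             ("AAAACCCCCC", [(rx1, 1), (rx2, 1)])]
        )
        clean, calls = calling.detect_chimeras(variants)
        assert calls == []
        assert len(clean) == 3

    def test_parents_must_cooccur_in_the_reaction(self):
        rx1, rx2 = ("I1", "gDNA", "1"), ("I2", "gDNA", "1")
        variants = self._variants(
            [("AAAAAAAAAA", [(rx2, 5)]),
             ("CCCCCCCCCC", [(rx2, 5)]),
             ("AAAACCCCCC", [(rx1, 1)])]  # parents live elsewhere
        )
        _, calls = calling.detect_chimeras(variants)
        assert calls == []

    def test_unrelated_variants_produce_no_calls(self):
        rx = ("I1", "gDNA", "1")
        variants = self._variants(
            [("AAAAAAAAAA", [(rx, 3)]),
             ("CCCCCCCCCC", [(rx, 3)]),
             ("GGGGGGGGGG", [(rx, 1)])]
        )
        _, calls = calling.detect_chimeras(variants)
        assert calls == []

    def test_simulated_chimeras_recovered_with_true_breakpoint(self, chimeric_library):
        cfg, libraries, truth = chimeric_library
        reads = reads_from_libraries(libraries)
        variants = calling.collapse_identical(reads)
        _, calls = calling.detect_chimeras(variants)
        flagged = {c.variant_sequence: c for c in calls}
        seq_of_clone = {r.clone_id: r.sequence for r in reads}
        reactions_of_seq = defaultdict(set)
        for r in reads:
            reactions_of_seq[r.sequence].add(r.reaction)
        checked = 0
        for clone, pa, pb, bp in truth.chimera_registry:
            seq = seq_of_clone[clone]
            if len(reactions_of_seq[seq]) != 1:
                continue
            (rx,) = reactions_of_seq[seq]
            present = {r.sequence for r in reads if r.reaction == rx}
            if truth.true_alleles[pa] in present and truth.true_alleles[pb] in present:
                checked += 1
                assert seq in flagged  # completeness
                lo, hi = flagged[seq].breakpoint_window
                assert lo <= bp < hi or lo <= bp <= hi  # window covers truth
        assert checked > 10


class TestConfirmation:
    def test_two_reactions_confirm(self):
        v = calling.CandidateVariant("ACGACG")
        v.support = {("I1", "gDNA", "1"): 1, ("I1", "gDNA", "2"): 1}
        (allele,) = calling.confirm_alleles([v])
        assert allele.status == "confirmed"

    def test_singleton_kept_as_provisional(self):
        v = calling.CandidateVariant("ACGACG")
        v.support = {("I1", "gDNA", "1"): 1}
        (allele,) = calling.confirm_alleles([v])
        assert allele.status == "provisional"

    def test_empty_input(self):
        assert calling.confirm_alleles([]) == []

    def test_monotonicity_adding_a_replicate_never_unconfirms(self, clean_library):
        cfg, libraries, truth = clean_library
        reads = reads_from_libraries(libraries)
        subset = [r for r in reads if r.pcr_replicate == "1"]
        for pool in (subset, reads):
            variants = calling.collapse_identical(pool)
            clean, _ = calling.detect_chimeras(variants)
            confirmed = {
                a.sequence for a in calling.confirm_alleles(clean) if a.status == "confirmed"
            }
            if pool is subset:
                before = confirmed
        assert before <= confirmed


class TestPerfectRecovery:
    def test_no_noise_confirmed_equals_truth(self, clean_library):
        cfg, libraries, truth = clean_library
        reads, variants, clean, chimera_calls, alleles = call_pipeline(libraries)
        assert chimera_calls == []
        confirmed = {a.sequence for a in alleles if a.status == "confirmed"}
        reactions_of = defaultdict(set)
        for r in reads:
            reactions_of[truth.clone_truth[r.clone_id]].add(r.reaction)
        expected = {
            truth.true_alleles[aid]
            for aid, rxs in reactions_of.items()
            if len(rxs) >= 2
        }
        assert confirmed == expected

    def test_chimera_soundness_no_chimera_survives(self, chimeric_library):
        cfg, libraries, truth = chimeric_library
        _, _, _, _, alleles = call_pipeline(libraries)
        true_seqs = set(truth.true_alleles.values())
        for allele in alleles:
            if allele.status == "confirmed":
                assert allele.sequence in true_seqs


class TestExpressionFlags:
    def test_internal_stop_flags_pseudogene(self):
        allele = Allele("x", "ATG" + "TAA" + "ACGACG", {("I1", "gDNA", "1"): 2})
        calling.classify_expression([allele])
        assert "putative_pseudogene" in allele.flags

    def test_gdna_only_flags_nonclassical_when_cdna_was_surveyed(self):
        a = Allele("x", "ATGACGACG", {("I1", "gDNA", "1"): 2})
        b = Allele("y", "ATGACGACT", {("I1", "cDNA", "1"): 2})
        calling.classify_expression([a, b])
        assert "putative_nonclassical" in a.flags
        assert not b.flags

    def test_gdna_only_not_flagged_without_cdna_survey(self):
        a = Allele("x", "ATGACGACG", {("I1", "gDNA", "1"): 2})
        calling.classify_expression([a], individuals_with_cdna=set())
        assert "putative_nonclassical" not in a.flags

    def test_both_templates_no_flags(self):
        a = Allele(
            "x", "ATGACGACG", {("I1", "gDNA", "1"): 2, ("I1", "cDNA", "1"): 1}
        )
        calling.classify_expression([a])
        assert a.flags == set()

    def test_unexpressed_simulated_locus_flagged(self, clean_library):
        cfg, libraries, truth = clean_library
        _, _, _, _, alleles = call_pipeline(libraries)
        calling.classify_expression(alleles)
        seq_to_locus = {seq: aid.split("_")[0] for aid, seq in truth.true_alleles.items()}
        cdna_inds = set(cfg.cdna_individuals)
        for allele in alleles:
            locus = seq_to_locus.get(allele.sequence)
            if locus is None or truth.expression_mask[locus]:
                continue
            if allele.individuals & cdna_inds:
                assert "putative_nonclassical" in allele.flags


class TestSummaries:
    def test_locus_lower_bound_from_max(self):
        counts = {"A": 25, "B": 10}
        out = calling.summarize_counts(counts)
        assert out["max"] == 25 and out["locus_lower_bound"] == 13

    def test_max_two_gives_bound_one(self):
        assert calling.summarize_counts({"A": 2})["locus_lower_bound"] == 1

    def test_constant_counts(self):
        out = calling.summarize_counts({"A": 4, "B": 4, "C": 4})
        assert out["mean"] == 4 and out["sd"] == 0 and out["locus_lower_bound"] == 2

    def test_bound_always_covers_max(self, clean_library):
        cfg, libraries, truth = clean_library
        _, _, _, _, alleles = call_pipeline(libraries)
        out = calling.summarize_individuals(alleles)
        assert 2 * out["locus_lower_bound"] >= out["max"]


def test_artifact_filter_separates_error_singletons():
    good = Allele("a", "ACGT" * 10, {("I1", "gDNA", "1"): 3, ("I1", "gDNA", "2"): 2})
    err = Allele("b", "TCGT" + "ACGT" * 9, {("I1", "gDNA", "1"): 1})
    novel = Allele("c", "".join(np.random.default_rng(3).choice(list("ACGT"), 40)),
                   {("I2", "gDNA", "1"): 1})
    kept, dropped = calling.filter_artifacts([good, err, novel])
    assert [a.name for a in dropped] == ["b"]
    assert {a.name for a in kept} == {"a", "c"}
    assert "probable_artifact" in err.flags
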