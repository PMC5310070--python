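"""Simulator contracts: determinism, conservation, truth bookkeeping."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from mhcrep import simlib
from mhcrep.simlib import SimConfig


class TestConfigValidation:
    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            SimConfig(ancestral_length_bp=100)

    @pytest.mark.parametrize("field", ["error_rate", "chimera_rate", "expressed_fraction"])
    def test_rates_in_unit_interval(self, field):
        with pytest.raises(ValueError, match=field):
            SimConfig(**{field: 1.5})

    def test_replicates_minimum(self):
        with pytest.raises(ValueError, match="n_replicates"):
            SimConfig(n_replicates=1)

    def test_unknown_omega_class_rejected(self):
        with pytest.raises(ValueError, match="omega classes"):
            SimConfig(omega_by_class={"classical": 1.0, "weird": 2.0})


def _dir_hash(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_seeded_runs_are_byte_identical(tmp_path):
    cfg = SimConfig(n_loci=3, n_individuals=3, depth_per_replicate=8, seed=42)
    hashes = []
    for sub in ("a", "b"):
        alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
        libraries, truth = simlib.simulate_clone_library(alleles, genotypes, expression, cfg)
        out = tmp_path / sub
        simlib.write_library(libraries, truth, cfg, out)
        hashes.append(_dir_hash(out))
    assert hashes[0] == hashes[1]


def test_adding_an_individual_does_not_perturb_others():
    base = SimConfig(n_loci=3, n_individuals=3, depth_per_replicate=8, seed=5)
    bigger = SimConfig(n_loci=3, n_individuals=4, depth_per_replicate=8, seed=5)
    lib_a, truth_a = simlib.simulate_clone_library(*simlib.simulate_repertoire(base), base)
    lib_b, truth_b = simlib.simulate_clone_library(*simlib.simulate_repertoire(bigger), bigger)
    shared = set(truth_a.genotype)
    assert all(truth_a.genotype[i] == truth_b.genotype[i] for i in shared)
    for key, records in lib_a.items():
        assert [s for _, s in records] == [s for _, s in lib_b[key]]


def test_clone_count_conservation(clean_library):
    cfg, libraries, truth = clean_library
    for key, records in libraries.items():
        assert len(records) == cfg.depth_per_replicate
    assert sum(len(r) for r in libraries.values()) == len(libraries) * cfg.depth_per_replicate


def test_every_clone_explained_by_exactly_one_truth_path(chimeric_library):
    cfg, libraries, truth = chimeric_library
    chimera_clones = {c for c, *_ in truth.chimera_registry}
    errored = {c for c, *_ in truth.error_registry}
    for key, records in libraries.items():
        for header, seq in records:
            clone = header.split("|")[0]
            source = truth.clone_truth[clone]
            if source == "chimera":
                assert clone in chimera_clones
            else:
                assert truth.true_alleles[source] == seq or clone in errored


def test_no_noise_clones_are_exact_allele_copies(clean_library):
    cfg, libraries, truth = clean_library
    true_seqs = set(truth.true_alleles.values())
    assert all(seq in true_seqs for recs in libraries.values() for _, seq in recs)
    assert truth.chimera_registry == [] and truth.error_registry == []


def test_cdna_purity(clean_library):
    cfg, libraries, truth = clean_library
    for (ind, tpl, rep), records in libraries.items():
        if tpl != "cDNA":
            continue
        for header, seq in records:
            source = truth.clone_truth[header.split("|")[0]]
            locus = truth.locus_of(source)
            assert truth.expression_mask[locus]
            assert truth.locus_class[locus] == "classical"


def test_chimeras_confined_to_single_reaction(chimeric_library):
    cfg, libraries, truth = chimeric_library
    location: dict[str, set] = {}
    for key, records in libraries.items():
        for header, seq in records:
            location.setdefault(seq, set()).add(key)
    chimera_seqs = {
        seq
        for key, records in libraries.items()
        for header, seq in records
        if truth.clone_truth[header.split("|")[0]] == "chimera"
    }
    assert chimera_seqs  # the scenario does produce chimeras
    for seq in chimera_seqs:
        assert len(location[seq]) == 1


def test_forced_chimeras_fill_registry():
    cfg = SimConfig(
        n_loci=1,
        alleles_per_locus=2,
        n_individuals=1,
        chimera_rate=1.0,
        error_rate=0.0,
        depth_per_replicate=6,
        locus_retention=1.0,
        n_cdna_individuals=0,
        seed=11,
    )
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    # force heterozygosity so every clone has two templates to recombine
    genotypes["I01"] = sorted(alleles)[:2]
    libraries, truth = simlib.simulate_clone_library(alleles, genotypes, expression, cfg)
    n_clones = sum(len(r) for r in libraries.values())
    assert len(truth.chimera_registry) == n_clones
    for clone, pa, pb, bp in truth.chimera_registry:
        assert pa != pb and 0 < bp < cfg.ancestral_length_bp


def test_error_count_matches_binomial_expectation():
    # depth 48, 300 bp, per-base rate 1e-3: clones carrying >=1 error are
    # Binomial(n_clones, 1 - 0.999^300); pool seeds and check the 99% band
    cfg_kwargs = dict(
        n_loci=1,
        alleles_per_locus=1,
        n_individuals=1,
        ancestral_length_bp=300,
        error_rate=1e-3,
        chimera_rate=0.0,
        depth_per_replicate=48,
        n_replicates=2,
        locus_retention=1.0,
        n_cdna_individuals=0,
    )
    p_err = 1 - (1 - 1e-3) ** 300
    total_clones = 0
    total_errored = 0
    for seed in range(10):
        cfg = SimConfig(seed=seed, **cfg_kwargs)
        libraries, truth = simlib.simulate_clone_library(*simlib.simulate_repertoire(cfg), cfg)
        errored_clones = {c for c, *_ in truth.error_registry}
        total_clones += sum(len(r) for r in libraries.values())
        total_errored += len(errored_clones)
    lo, hi = stats.binom.ppf([0.005, 0.995], total_clones, p_err)
    assert lo <= total_errored <= hi


def test_diploid_upper_bound_on_distinct_alleles():
    cfg = SimConfig(n_loci=13, seed=2, locus_retention=1.0)
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    for ind, genotype in genotypes.items():
        assert len(set(genotype)) <= 2 * cfg.n_loci


def test_degenerate_single_locus_single_allele():
    cfg = SimConfig(
        n_loci=1, alleles_per_locus=1, n_individuals=3, locus_retention=1.0, seed=0
    )
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    assert len(alleles) == 1
    (only,) = alleles
    assert all(set(g) == {only} for g in genotypes.values())


def test_depth_zero_warns_and_emits_truth():
    cfg = SimConfig(
        n_loci=1, n_individuals=1, depth_per_replicate=0, locus_retention=1.0, seed=0
    )
    with pytest.warns(UserWarning, match="depth 0"):
        libraries, truth = simlib.simulate_clone_library(*simlib.simulate_repertoire(cfg), cfg)
    assert all(records == [] for records in libraries.values())
    assert truth.true_alleles


def test_genotypes_must_reference_known_alleles():
    cfg = SimConfig(n_loci=1, n_individuals=1, locus_retention=1.0, seed=0)
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    genotypes["I01"] = ["L99_A9"]
    with pytest.raises(ValueError, match="unknown alleles"):
        simlib.simulate_clone_library(alleles, genotypes, expression, cfg)


def test_nonclassical_class_has_no_synonymous_variation():
    cfg = SimConfig(seed=4)
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    classes = simlib._locus_class_map(cfg)
    nc = [a for a in alleles if classes[a.split("_")[0]] == "nonclassical"]
    assert len(nc) >= 4
    # unexpressed by construction
    assert all(not expression[a.split("_")[0]] for a in nc)


def test_pseudogene_loci_carry_internal_stops_and_stay_out_of_cdna():
    cfg = SimConfig(seed=4)
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    classes = simlib._locus_class_map(cfg)
    pseudo = [a for a, seq in alleles.items() if classes[a.split("_")[0]] == "pseudogene"]
    assert pseudo
    for aid in pseudo:
        assert simlib._has_internal_stop(alleles[aid])
        assert not expression[aid.split("_")[0]]


class TestFullGene:
    def test_segment_coordinates_are_contiguous(self, gene_model):
        seq, coords = simlib.simulate_full_gene(gene_model, intron2_length=702, seed=1)
        pos = 0
        for name in ("E1", "I1", "E2", "I2", "E3", "I3", "E4", "I4", "E5", "I5", "E6"):
            start, end = coords[name]
            assert start == pos
            pos = end
        assert pos == len(seq)
        assert coords["I2"][1] - coords["I2"][0] == 702

    def test_introns_carry_splice_signals(self, gene_model):
        seq, coords = simlib.simulate_full_gene(gene_model, seed=2)
        for name in ("I1", "I2", "I3", "I4", "I5"):
            s, e = coords[name]
            assert seq[s : s + 2] == "GT" and seq[e - 2 : e] == "AG"
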