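"""dN/dS estimators against independent oracles; Z-test behaviour.

The oracles here are written independently of the package's table-driven
implementation: plain per-codon Python using Biopython's translation, with
explicit pathway enumeration.  They share only the documented conventions
(stop-excluded site denominators, stop-avoiding pathway averaging).
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mhcrep import selection, seqio, simlib
from mhcrep.selection import (
    distance_from_counts,
    group_selection_test,
    ng86_pair,
    pbl_pair,
)

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# independent NG86 oracle
# ---------------------------------------------------------------------------

def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mutant) == "*":
                continue
            valid += 1
            if _aa(mutant) == _aa(codon):
                syn += 1
        if valid:
            total += syn / valid
    return total


def oracle_pathways(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in itertools.permutations(diff):
        cur, syn, non, hit_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                hit_stop = True
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        (blocked if hit_stop else clean).append((syn, non))
    chosen = clean or blocked
    return (
        sum(s for s, _ in chosen) / len(chosen),
        sum(n for _, n in chosen) / len(chosen),
    )


def oracle_ng86(seq_a: str, seq_b: str):
    S = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (set(ca) <= set(BASES) and set(cb) <= set(BASES)):
            continue
        n_codons += 1
        S += (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        sd, nd = oracle_pathways(ca, cb)
        Sd += sd
        Nd += nd
    return S, 3 * n_codons - S, Sd, Nd


def random_codon_pair_alignment(rng, n_codons, p_sub=0.15):
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), 3))
        if c not in stops:
            codons.append(c)
    a = "".join(codons)
    b = list(a)
    for i in range(len(b)):
        if rng.random() < p_sub:
            b[i] = BASES[rng.integers(4)]
    # repair stop codons introduced by mutation
    for c in range(n_codons):
        if "".join(b[3 * c : 3 * c + 3]) in stops:
            b[3 * c : 3 * c + 3] = a[3 * c : 3 * c + 3]
    return a, "".join(b)


class TestNG86:
    def test_identical_codons_no_differences(self):
        counts = ng86_pair("TTTAAAGGG", "TTTAAAGGG")
        assert counts.Nd == 0 and counts.Sd == 0
        assert counts.codons_compared == 3

    def test_phe_to_leu_single_nonsynonymous(self):
        counts = ng86_pair("TTT", "TTA")
        assert counts.Sd == 0 and counts.Nd == 1

    def test_fourfold_third_position_synonymous(self):
        counts = ng86_pair("GGA", "GGG")
        assert counts.Sd == 1 and counts.Nd == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            a, b = random_codon_pair_alignment(rng, 50)
            counts = ng86_pair(a, b)
            S, N, Sd, Nd = oracle_ng86(a, b)
            assert counts.S_sites == pytest.approx(S, abs=1e-9)
            assert counts.N_sites == pytest.approx(N, abs=1e-9)
            assert counts.Sd == pytest.approx(Sd, abs=1e-9)
            assert counts.Nd == pytest.approx(Nd, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_site_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_codon_pair_alignment(rng, 40)
        ab, ba = ng86_pair(a, b), ng86_pair(b, a)
        assert ab == ba
        assert ab.N_sites + ab.S_sites == pytest.approx(3 * ab.codons_compared)

    def test_ambiguous_codons_skipped_pairwise(self):
        counts = ng86_pair("TTTNNN", "TTTAAA")
        assert counts.codons_compared == 1

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            ng86_pair("TTT", "TTTAAA")
        with pytest.raises(ValueError, match="stop"):
            ng86_pair("TAAGGGCCC", "TAAGGGCCC")


class TestJukesCantor:
    def test_zero_proportion(self):
        counts = selection.CodonPairCounts(100, 50, 0.0, 6.0, 50)
        dS, dN = distance_from_counts(counts)
        assert dN == 0.0

    def test_known_value(self):
        # pS = 0.12 -> JC distance -(3/4) ln(1 - 0.16) = 0.130765
        counts = selection.CodonPairCounts(100, 50, 10.0, 6.0, 50)
        dS, dN = distance_from_counts(counts)
        assert dS == pytest.approx(-0.75 * math.log(1 - 4 * 0.12 / 3), abs=1e-9)
        assert dS == pytest.approx(0.130765, abs=1e-5)

    def test_zero_sites_gives_nan(self):
        counts = selection.CodonPairCounts(150, 0, 10.0, 0.0, 50)
        dS, dN = distance_from_counts(counts)
        assert math.isnan(dS) and not math.isnan(dN)

    def test_saturation_warns(self):
        counts = selection.CodonPairCounts(100, 50, 10.0, 40.0, 50)
        with pytest.warns(UserWarning, match="0.75"):
            dS, _ = distance_from_counts(counts)
        assert math.isnan(dS)


# ---------------------------------------------------------------------------
# independent PBL oracle
# ---------------------------------------------------------------------------

def oracle_degeneracy(codon: str, pos: int) -> int:
    syn = sum(
        1
        for b in BASES
        if b != codon[pos] and _aa(codon[:pos] + b + codon[pos + 1 :]) == _aa(codon)
    )
    return 4 if syn == 3 else (2 if syn >= 1 else 0)


def oracle_pbl(seq_a: str, seq_b: str):
    is_purine = {"A": True, "G": True, "C": False, "T": False}
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    ts = {0: 0.0, 2: 0.0, 4: 0.0}
    tv = {0: 0.0, 2: 0.0, 4: 0.0}
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (set(ca) <= set(BASES) and set(cb) <= set(BASES)):
            continue
        for pos in range(3):
            da, db = oracle_degeneracy(ca, pos), oracle_degeneracy(cb, pos)
            L[da] += 0.5
            L[db] += 0.5
            x, y = ca[pos], cb[pos]
            if x != y:
                bucket = ts if is_purine[x] == is_purine[y] else tv
                bucket[da] += 0.5
                bucket[db] += 0.5

    def AB(i):
        P, Q = ts[i] / L[i], tv[i] / L[i]
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        return (
            0.5 * math.log(1 / w1) - 0.25 * math.log(1 / w2),
            0.5 * math.log(1 / w2),
        )

    A = {}
    B = {}
    for i in (0, 2, 4):
        A[i], B[i] = AB(i)
    dS = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    dN = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    return dS, dN


class TestPBL:
    def test_identical_sequences(self):
        assert pbl_pair("TTTAAAGGG", "TTTAAAGGG") == (0.0, 0.0)

    def test_fourfold_transitions_only_touch_ds(self):
        # a few GGA vs GGG differences (fourfold third position, transition)
        # among conserved fourfold sites -> dN = 0, dS > 0
        a = "GGA" * 3 + "GGG" * 27 + "TTT" * 30
        b = "GGG" * 30 + "TTT" * 30
        dS, dN = pbl_pair(a, b)
        assert dN == 0.0 and dS > 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b = random_codon_pair_alignment(rng, 100, p_sub=0.08)
        dS, dN = pbl_pair(a, b)
        oS, oN = oracle_pbl(a, b)
        assert dS == pytest.approx(oS, abs=1e-12)
        assert dN == pytest.approx(oN, abs=1e-12)


# ---------------------------------------------------------------------------
# group-level Z-test
# ---------------------------------------------------------------------------

def _alignment(seqs, beta1=None):
    names = [f"a{i}" for i in range(len(seqs))]
    beta1 = beta1 if beta1 is not None else len(seqs[0]) // 6
    return seqio.make_codon_alignment(names, seqs, beta1_codons=beta1)


class TestGroupSelectionTest:
    def test_identical_sequences_no_selection_call(self):
        aln = _alignment(["ATGAAACCCGGGTTTACGATCGCAACGCTTAAACCCGGGTTTACGATCGCAACGCTTCCC"] * 5)
        res = group_selection_test(aln, n_bootstrap=200, seed=0, min_shared_codons=5)
        assert res.dN == 0 and res.dS == 0
        assert res.p_positive > 0.4 and res.p_purifying > 0.4

    def test_seeded_bootstrap_reproducible(self):
        seqs = simlib.simulate_codon_alignment(8, 60, 0.05, 0.5, seed=3)
        aln = _alignment(seqs)
        r1 = group_selection_test(aln, n_bootstrap=300, seed=5)
        r2 = group_selection_test(aln, n_bootstrap=300, seed=5)
        assert (r1.dN, r1.dS, r1.z, r1.p_purifying) == (r2.dN, r2.dS, r2.z, r2.p_purifying)

    def test_se_shrinks_with_codon_count(self):
        ses = []
        for n_codons in (100, 1000):
            seqs = simlib.simulate_codon_alignment(10, n_codons, 0.05, 1.0, seed=9)
            aln = _alignment(seqs)
            res = group_selection_test(aln, n_bootstrap=300, seed=1)
            ses.append(res.dN_se)
        assert ses[1] < ses[0]

    def test_omega_recovered_within_band(self):
        # deep alignments with known omega: estimate within +/- 0.15
        for target in (0.3, 0.8):
            seqs = simlib.simulate_codon_alignment(12, 500, 0.08, target, seed=21)
            aln = _alignment(seqs)
            res = group_selection_test(aln, n_bootstrap=200, seed=2)
            assert abs(res.omega - target) <= 0.15, (target, res.omega)

    def test_synonymous_only_divergence_keeps_dn_zero(self):
        base = "GGATTTCTTAAACCAGTT" * 10
        variant = base.replace("GGA", "GGG")  # fourfold positions only
        aln = _alignment([base, variant])
        res = group_selection_test(aln, n_bootstrap=200, seed=0)
        assert res.dN == 0.0 and res.dS > 0
        assert math.isnan(res.omega) or res.omega == 0.0

    def test_ds_zero_makes_omega_undefined(self):
        base = "ATGAAACCCGGGTTTACG" * 5
        # one nonsynonymous substitution (Met -> Ile), zero synonymous
        variant = "ATA" + base[3:]
        aln = _alignment([base, variant])
        res = group_selection_test(aln, n_bootstrap=100, seed=0)
        assert res.dS == 0.0 and math.isnan(res.omega)

    def test_pairwise_deletion_lets_partial_alleles_in(self):
        rng = np.random.default_rng(4)
        full = simlib.simulate_codon_alignment(6, 80, 0.05, 0.6, seed=11)
        partial = full[0][: 40 * 3] + "-" * (40 * 3)
        aln = _alignment(full + [partial])
        res = group_selection_test(aln, n_bootstrap=100, seed=0, min_shared_codons=30)
        assert res.n_pairs == 6 * 7 // 2  # every pair shares >= 30 codons

    def test_insufficient_coverage_raises(self):
        aln = _alignment(["ATGAAACCC" + "-" * 51, "-" * 51 + "ATGAAACCC"], beta1=10)
        with pytest.raises(ValueError, match="shares"):
            group_selection_test(aln, min_shared_codons=3)

    def test_internal_stop_rejected(self):
        aln = _alignment(["ATGTAACCCTTTAAACCCATGACGACGTTT"] * 3)
        with pytest.raises(ValueError, match="stop"):
            group_selection_test(aln, n_bootstrap=50, seed=0, min_shared_codons=2)
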