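"""Synthetic clone-library generator with known ground truth.

The generator emulates the data-generating process of a replicated
clone-and-Sanger survey of a multigene MHC class IIB family:

* a multi-locus diploid repertoire (around 13 loci), with locus founders
  diverged from a common ancestral coding sequence and a small pool of
  alleles per locus;
* locus classes — *classical* loci (expressed, with elevated
  nonsynonymous variation at peptide-binding-like codons), *nonclassical*
  loci (unexpressed, low polymorphism, and essentially no synonymous
  variation, the Group-I-like pattern), and *pseudogenes* (premature stop
  codon, unexpressed);
* per-clone PCR point errors, single-breakpoint PCR chimeras confined to
  one reaction, and amplification bias (Dirichlet-weighted template
  sampling, drawn once per individual x replicate);
* cDNA libraries that draw only from expressed, stop-free loci.

Every emitted clone is explained by exactly one truth record: a faithful
copy, an erred copy, or a registered chimera.  Randomness is split into
named substreams keyed on (individual, template, replicate), so adding an
individual or toggling a library does not perturb the others, and a fixed
seed reproduces output byte for byte.

Amplicons cover the exon-2/exon-3 region (the region allele calling
targets); full-gene sequences with introns are produced separately by
:func:`simulate_full_gene` for annotation fixtures.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import GeneModel, Segment, DEFAULT_SEGMENT_LENGTHS, translate
from . import seqio

logger = logging.getLogger("mhcrep")

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_repertoire",
    "simulate_clone_library",
    "simulate_codon_alignment",
    "simulate_full_gene",
    "default_gene_model",
    "write_library",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the survey the pipeline is designed for: 13 individuals,
    up to ~13 loci, duplicated PCRs, 16-48 clones sequenced per
    amplification, cDNA available for 7 of the 13 individuals, and intron-2
    length classes at 248/702/1500 bp.  The amplicon is 552 bp (184 codons:
    91 beta-1-like, 93 beta-2-like).
    """

    n_loci: int = 13
    alleles_per_locus: int = 6
    n_individuals: int = 13
    ancestral_length_bp: int = 552
    locus_divergence: float = 0.15
    allele_divergence: float = 0.03
    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {"classical": 3.0, "nonclassical": float("inf")}
    )
    expressed_fraction: float = 0.7
    pseudogene_fraction: float = 0.1
    chimera_rate: float = 0.03
    error_rate: float = 0.0005
    depth_per_replicate: int = 24
    n_replicates: int = 2
    amplification_bias_concentration: float = 1.0
    intron2_length_choices: tuple[int, ...] = (248, 702, 1500)
    locus_retention: float = 0.6
    n_cdna_individuals: int | None = 7
    kappa: float = 2.0
    framework_omega: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestral_length_bp % 3:
            raise ValueError("ancestral_length_bp must be a multiple of 3")
        for name in (
            "locus_divergence",
            "allele_divergence",
            "expressed_fraction",
            "pseudogene_fraction",
            "chimera_rate",
            "error_rate",
            "locus_retention",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (replicate confirmation needs it)")
        unknown = set(self.omega_by_class) - {"classical", "nonclassical"}
        if unknown:
            raise ValueError(f"unknown omega classes: {sorted(unknown)}")

    @property
    def individuals(self) -> list[str]:
        return [f"I{i + 1:02d}" for i in range(self.n_individuals)]

    @property
    def cdna_individuals(self) -> list[str]:
        n = self.n_cdna_individuals
        inds = self.individuals
        return inds if n is None else inds[: min(n, len(inds))]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


@dataclass
class SimTruth:
    """Ground truth for a simulated clone library."""

    true_alleles: dict[str, str]
    genotype: dict[str, list[str]]
    chimera_registry: list[tuple[str, str, str, int]]  # clone, parent_a, parent_b, breakpoint
    error_registry: list[tuple[str, int, str]]  # clone, position, new base
    expression_mask: dict[str, bool]
    locus_class: dict[str, str]
    clone_truth: dict[str, str] = field(default_factory=dict)  # clone -> source allele/"chimera"

    def locus_of(self, allele_id: str) -> str:
        return allele_id.split("_")[0]


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------

def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), 3))
        if codon not in _STOPS:
            codons.append(codon)
    # anchor the frame with a start codon
    codons[0] = "ATG"
    return "".join(codons)


def _propose(seq: list[str], pos: int, rng: np.random.Generator, kappa: float) -> str:
    """One proposed substitution at ``pos``: transition with weight kappa,
    each transversion with weight 1."""
    base = seq[pos]
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    choices = [b for b in _BASES if b != base and b != _TRANSITION[base]]
    return choices[rng.integers(len(choices))]


def _is_synonymous(seq: list[str], pos: int, new: str) -> tuple[bool, bool]:
    """(synonymous?, creates_stop?) for substituting ``new`` at ``pos``."""
    c0 = pos - pos % 3
    old_codon = "".join(seq[c0 : c0 + 3])
    new_codon = old_codon[: pos - c0] + new + old_codon[pos - c0 + 1 :]
    if new_codon in _STOPS:
        return False, True
    return translate(old_codon) == translate(new_codon), False


#: dN/dS of within-locus variation outside PBR-like codons in classical
#: loci: framework regions of functional MHC genes are conserved.
BACKGROUND_OMEGA = 0.3


def pbr_codon_mask(n_codons: int, beta1_codons: int = 91) -> np.ndarray:
    """Deterministic PBR-like codon layout: every 4th codon of the beta-1
    region (roughly the density of peptide-contact residues there)."""
    mask = np.zeros(n_codons, dtype=bool)
    upper = min(beta1_codons, n_codons)
    mask[1:upper:4] = True
    return mask


def mutate(
    sequence: str,
    divergence: float,
    rng: np.random.Generator,
    omega: float | np.ndarray = 1.0,
    kappa: float = 2.0,
    allow_stops: bool = False,
) -> str:
    """Return a mutated copy at roughly ``divergence`` substitutions/site.

    Proposals are per-site with transition:transversion weight ``kappa``;
    acceptance shapes dN/dS: a nonsynonymous proposal at position i is
    accepted with probability min(1, omega_i), a synonymous one with
    min(1, 1/omega_i), so the realised nonsynonymous/synonymous rate ratio
    tracks omega.  ``omega`` may be a scalar or a per-site array (how
    classical loci get omega > 1 at PBR-like sites over a purifying
    background).  Large omega yields essentially nonsynonymous-only
    variation — the dS = 0 pattern of nonclassical groups.  Stop-creating
    proposals are rejected unless ``allow_stops``.
    """
    seq = list(sequence)
    n = len(seq)
    omega_arr = np.broadcast_to(np.asarray(omega, dtype=float), (n,))
    p_nonsyn = np.minimum(1.0, omega_arr)
    with np.errstate(divide="ignore"):
        p_syn = np.where(omega_arr > 0, np.minimum(1.0, 1.0 / omega_arr), 1.0)
    # inflate the proposal rate so accepted density ~ divergence
    mean_accept = float(np.mean(0.75 * p_nonsyn + 0.25 * p_syn))
    rate = min(1.0, divergence / max(mean_accept, 1e-9))
    hits = np.flatnonzero(rng.random(n) < rate)
    for pos in hits:
        new = _propose(seq, int(pos), rng, kappa)
        syn, makes_stop = _is_synonymous(seq, int(pos), new)
        if makes_stop and not allow_stops:
            continue
        p = p_syn[pos] if syn else p_nonsyn[pos]
        if rng.random() < p:
            seq[int(pos)] = new
    return "".join(seq)


def _insert_premature_stop(sequence: str, rng: np.random.Generator) -> str:
    """Place an in-frame stop in the first half of the coding sequence."""
    n_codons = len(sequence) // 3
    c = int(rng.integers(2, max(3, n_codons // 2)))
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    return sequence[: 3 * c] + stop + sequence[3 * c + 3 :]


# ---------------------------------------------------------------------------
# repertoire
# ---------------------------------------------------------------------------

def _locus_classes(cfg: SimConfig) -> list[str]:
    """Deterministic class layout: unexpressed nonclassical loci first, then
    pseudogenes, then expressed classical loci."""
    n_nonclass = int(round((1.0 - cfg.expressed_fraction) * cfg.n_loci))
    n_pseudo = int(round(cfg.pseudogene_fraction * cfg.n_loci))
    n_nonclass = min(n_nonclass, cfg.n_loci)
    n_pseudo = min(n_pseudo, cfg.n_loci - n_nonclass)
    return (
        ["nonclassical"] * n_nonclass
        + ["pseudogene"] * n_pseudo
        + ["classical"] * (cfg.n_loci - n_nonclass - n_pseudo)
    )


def simulate_repertoire(
    cfg: SimConfig,
) -> tuple[dict[str, str], dict[str, list[str]], dict[str, bool]]:
    """Draw the true allele repertoire and diploid genotypes.

    Returns ``(allele_set, genotypes, expression_mask)``: allele id ->
    sequence; individual -> list of allele ids (two per retained locus,
    possibly identical = homozygous); locus id -> expressed flag.  Allele
    ids encode their locus (``L03_A2``), which is how tests recover truth
    labels.
    """
    classes = _locus_classes(cfg)
    rng_rep = np.random.default_rng([cfg.seed, 0])
    ancestral = _random_coding(rng_rep, cfg.ancestral_length_bp // 3)

    alleles: dict[str, str] = {}
    expression: dict[str, bool] = {}
    pools: dict[str, list[str]] = {}
    pbr = pbr_codon_mask(cfg.ancestral_length_bp // 3)
    pbr_sites = np.repeat(pbr, 3)
    # nonclassical loci descend from one recent class founder: the class
    # forms a single tight cluster (the Group-I-like pattern), and all of
    # its internal divergence is nonsynonymous-only
    rng_class = np.random.default_rng([cfg.seed, 7])
    nonclassical_founder = mutate(
        ancestral, cfg.locus_divergence, rng_class,
        omega=cfg.framework_omega, kappa=cfg.kappa,
    )
    for li in range(cfg.n_loci):
        locus = f"L{li + 1:02d}"
        cls = classes[li]
        if cls == "nonclassical":
            # nonsynonymous-only, dS ~ 0 within the class
            omega: float | np.ndarray = cfg.omega_by_class["nonclassical"]
        else:
            # elevated omega at PBR-like sites over a purifying background
            omega = np.where(
                pbr_sites, cfg.omega_by_class["classical"], BACKGROUND_OMEGA
            )
        rng_locus = np.random.default_rng([cfg.seed, 1, li])
        if cls == "nonclassical":
            founder = mutate(
                nonclassical_founder, 0.25 * cfg.allele_divergence, rng_locus,
                omega=omega, kappa=cfg.kappa,
            )
        else:
            founder = mutate(
                ancestral, cfg.locus_divergence, rng_locus,
                omega=cfg.framework_omega, kappa=cfg.kappa,
            )
        if cls == "pseudogene":
            founder = _insert_premature_stop(founder, rng_locus)
        # nonclassical loci: very low within-locus polymorphism
        div = cfg.allele_divergence * (0.25 if cls == "nonclassical" else 1.0)
        pool: list[str] = []
        seen: set[str] = set()
        for ai in range(cfg.alleles_per_locus):
            if ai == 0:
                seq = founder
            else:
                seq = mutate(
                    founder, div, rng_locus, omega=omega, kappa=cfg.kappa,
                    allow_stops=(cls == "pseudogene"),
                )
            aid = f"{locus}_A{ai + 1}"
            if seq in seen:
                continue  # collapsed duplicate: smaller pool, more sharing
            seen.add(seq)
            alleles[aid] = seq
            pool.append(aid)
        pools[locus] = pool
        has_stop = any(
            founder[3 * c : 3 * c + 3] in _STOPS for c in range(len(founder) // 3 - 1)
        )
        expression[locus] = cls == "classical" and not has_stop

    genotypes: dict[str, list[str]] = {}
    for ii, ind in enumerate(cfg.individuals):
        rng_ind = np.random.default_rng([cfg.seed, 2, ii])
        # per-individual recovery rate: amplification success varies a lot
        # between individuals (template quality, primer-allele mismatches),
        # which is what spreads per-individual allele counts so widely
        if cfg.locus_retention >= 1.0:
            retention = 1.0
        elif cfg.locus_retention <= 0.0:
            retention = 0.0
        else:
            retention = float(
                rng_ind.beta(3.0 * cfg.locus_retention, 3.0 * (1.0 - cfg.locus_retention))
            )
        genotype: list[str] = []
        for li in range(cfg.n_loci):
            locus = f"L{li + 1:02d}"
            if rng_ind.random() > retention:
                continue  # locus absent/unamplifiable in this individual
            pool = pools[locus]
            picks = rng_ind.integers(0, len(pool), size=2)
            genotype.extend(pool[p] for p in picks)
        genotypes[ind] = genotype

    self_check = {aid for g in genotypes.values() for aid in g}
    unused = set(alleles) - self_check
    if unused:
        logger.debug("%d repertoire alleles not drawn by any individual", len(unused))
    return alleles, genotypes, expression


def _locus_class_map(cfg: SimConfig) -> dict[str, str]:
    return {f"L{li + 1:02d}": c for li, c in enumerate(_locus_classes(cfg))}


# ---------------------------------------------------------------------------
# clone libraries
# ---------------------------------------------------------------------------

def _has_internal_stop(seq: str) -> bool:
    return any(seq[3 * c : 3 * c + 3] in _STOPS for c in range(len(seq) // 3 - 1))


def simulate_clone_library(
    alleles: Mapping[str, str],
    genotypes: Mapping[str, list[str]],
    expression_mask: Mapping[str, bool],
    cfg: SimConfig,
) -> tuple[dict[tuple[str, str, str], list[tuple[str, str]]], SimTruth]:
    """Emit clone reads per individual x template x replicate.

    Returns ``(libraries, truth)`` where ``libraries`` maps
    (individual, template, replicate) to a list of (header, sequence)
    FASTA records in the ``>cloneNNN|ind=..|tpl=..|rep=..`` dialect.

    Each clone is a faithful template copy with iid base errors, or — with
    probability ``chimera_rate`` when the reaction holds at least two
    distinct templates — a single-breakpoint concatenation of two templates
    from the same reaction.  A chimeric sequence is never allowed to recur
    in a second replicate of the same individual (redrawn if it would),
    matching the assumption the one-reaction chimera filter relies on.
    """
    for ind, genotype in genotypes.items():
        missing = [a for a in genotype if a not in alleles]
        if missing:
            raise ValueError(f"genotype of {ind} references unknown alleles: {missing}")

    truth = SimTruth(
        true_alleles=dict(alleles),
        genotype={k: list(v) for k, v in genotypes.items()},
        chimera_registry=[],
        error_registry=[],
        expression_mask=dict(expression_mask),
        locus_class=_locus_class_map(cfg),
    )
    libraries: dict[tuple[str, str, str], list[tuple[str, str]]] = {}
    clone_counter = 0
    # chimeric sequence -> the one PCR product it is allowed to occur in;
    # recurrence anywhere else is redrawn so every chimera stays confined to
    # a single reaction (the property the downstream filter relies on)
    emitted_chimeras: dict[str, tuple[str, str, str]] = {}
    allele_sequences = set(alleles.values())

    for ii, ind in enumerate(cfg.individuals):
        if ind not in genotypes:
            continue
        genotype = genotypes[ind]
        for rep in range(1, cfg.n_replicates + 1):
            rng_weights = np.random.default_rng([cfg.seed, 3, ii, rep])
            templates_g = sorted(set(genotype))
            copy_number = {a: genotype.count(a) for a in templates_g}
            if templates_g:
                conc = cfg.amplification_bias_concentration
                raw = rng_weights.dirichlet([conc] * len(templates_g))
                weights_g = raw * np.array([copy_number[a] for a in templates_g])
                weights_g = weights_g / weights_g.sum()
            for tpl in ("gDNA", "cDNA"):
                if tpl == "cDNA" and ind not in cfg.cdna_individuals:
                    continue
                if tpl == "cDNA":
                    templates = [
                        a
                        for a in templates_g
                        if expression_mask.get(a.split("_")[0], False)
                        and not _has_internal_stop(alleles[a])
                    ]
                    if templates:
                        w = np.array(
                            [weights_g[templates_g.index(a)] for a in templates]
                        )
                        weights = w / w.sum()
                else:
                    templates, weights = templates_g, weights_g
                key = (ind, tpl, str(rep))
                records: list[tuple[str, str]] = []
                if cfg.depth_per_replicate == 0:
                    warnings.warn(f"depth 0 for {key}: empty library emitted")
                    libraries[key] = records
                    continue
                if not templates:
                    libraries[key] = records
                    continue
                rng = np.random.default_rng(
                    [cfg.seed, 4, ii, rep, 0 if tpl == "gDNA" else 1]
                )
                for _ in range(cfg.depth_per_replicate):
                    clone_counter += 1
                    clone_id = f"clone{clone_counter:05d}"
                    is_chimera = (
                        len(templates) >= 2 and rng.random() < cfg.chimera_rate
                    )
                    if is_chimera:
                        forbidden = allele_sequences | {
                            s for s, k in emitted_chimeras.items() if k != key
                        }
                        seq, meta = _draw_chimera(
                            alleles, templates, weights, rng, forbidden=forbidden
                        )
                        if seq is None:
                            is_chimera = False
                        else:
                            pa, pb, bp = meta
                            truth.chimera_registry.append((clone_id, pa, pb, bp))
                            truth.clone_truth[clone_id] = "chimera"
                            emitted_chimeras[seq] = key
                    if not is_chimera:
                        aid = templates[
                            int(rng.choice(len(templates), p=weights))
                        ]
                        seq = alleles[aid]
                        truth.clone_truth[clone_id] = aid
                    seq = _apply_errors(seq, cfg.error_rate, rng, clone_id, truth)
                    header = f"{clone_id}|ind={ind}|tpl={tpl}|rep={rep}"
                    records.append((header, seq))
                libraries[key] = records
    return libraries, truth


def _draw_chimera(
    alleles: Mapping[str, str],
    templates: Sequence[str],
    weights: np.ndarray,
    rng: np.random.Generator,
    forbidden: set[str],
    max_tries: int = 20,
):
    for _ in range(max_tries):
        i, j = rng.choice(len(templates), size=2, replace=False, p=weights)
        pa, pb = templates[int(i)], templates[int(j)]
        sa, sb = alleles[pa], alleles[pb]
        length = min(len(sa), len(sb))
        bp = int(rng.integers(1, length))
        seq = sa[:bp] + sb[bp:length]
        if seq in forbidden or seq == sa[:length] or seq == sb[:length]:
            continue
        return seq, (pa, pb, bp)
    return None, None


def _apply_errors(
    seq: str, rate: float, rng: np.random.Generator, clone_id: str, truth: SimTruth
) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits) == 0:
        return seq
    out = list(seq)
    for pos in hits:
        new = _BASES[int(rng.integers(3))]
        if new == out[pos]:
            new = _BASES[3]
        out[int(pos)] = new
        truth.error_registry.append((clone_id, int(pos), new))
    return "".join(out)


# ---------------------------------------------------------------------------
# flat codon alignments (selection-test calibration)
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    n_sequences: int,
    n_codons: int,
    divergence: float,
    omega: float,
    seed: int,
    kappa: float = 1.0,
) -> list[str]:
    """Star-phylogeny codon alignment for selection-test calibration.

    Each sequence is an independent mutant of a common ancestor at the given
    divergence and dN/dS target.  ``kappa`` defaults to 1 here: with a
    transition bias, synonymous sites genuinely evolve faster than
    nonsynonymous ones even at omega = 1, so the equal-rates null that the
    Z-test's type-I error is defined against requires unbiased proposals.
    """
    rng = np.random.default_rng([seed, 10])
    ancestor = _random_coding(rng, n_codons)
    out = []
    for i in range(n_sequences):
        rng_i = np.random.default_rng([seed, 11, i])
        out.append(mutate(ancestor, divergence, rng_i, omega=omega, kappa=kappa))
    return out


# ---------------------------------------------------------------------------
# full-gene sequences (annotation fixtures)
# ---------------------------------------------------------------------------

def default_gene_model(seed: int = 0) -> GeneModel:
    """A synthetic six-exon reference gene model.

    Reference exon sequences are generated, not taken from any database:
    they serve as an alignment anchor with the documented exon lengths
    (55, 273, 214, 69, 114, 120 bp) and a clean reading frame across the
    concatenated exons.
    """
    rng = np.random.default_rng([seed, 20])
    exon_lengths = {"E1": 55, "E2": 273, "E3": 214, "E4": 69, "E5": 114, "E6": 120}
    total = sum(exon_lengths.values())
    n_codons = -(-total // 3)
    coding = _random_coding(rng, n_codons)[:total]
    refs: dict[str, str] = {}
    offset = 0
    for name in ("E1", "E2", "E3", "E4", "E5", "E6"):
        refs[name] = coding[offset : offset + exon_lengths[name]]
        offset += exon_lengths[name]
    segments = [Segment(n, DEFAULT_SEGMENT_LENGTHS[n]) for n in
                ("E1", "I1", "E2", "I2", "E3", "I3", "E4", "I4", "E5", "I5", "E6")]
    return GeneModel(segments, refs)


def _random_intron(rng: np.random.Generator, length: int) -> str:
    if length < 4:
        raise ValueError("introns must be at least 4 bp (GT...AG)")
    inner = "".join(rng.choice(list(_BASES), length - 4))
    return "GT" + inner + "AG"


#: motifs observed to expand intron 2: a 42-mer, a 21-mer and a 127-mer.
REPEAT_MOTIF_LENGTHS = (42, 21, 127)


def simulate_full_gene(
    model: GeneModel,
    intron2_length: int = 702,
    seed: int = 0,
    intron2_repeat: tuple[int, float] | None = None,
    exon5_extension: int = 0,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Build a full-gene sequence from the model with known segment
    coordinates (the annotation truth).

    ``intron2_repeat`` = (motif_length, copies) embeds a tandem-repeat
    expansion in intron 2 (e.g. ``(42, 6.4)``); ``exon5_extension`` adds
    that many coding bases at the 5' end of exon 5, reproducing the known
    length variant.
    """
    rng = np.random.default_rng([seed, 21])
    intron_lengths = {"I1": 180, "I2": intron2_length, "I3": 405, "I4": 150, "I5": 160}
    parts: list[str] = []
    coords: dict[str, tuple[int, int]] = {}
    pos = 0
    for seg in model.segments:
        if seg.is_exon:
            seq = model.exon_refs[seg.name]
            if seg.name == "E5" and exon5_extension:
                # extension chosen G-free so it cannot mimic a splice acceptor
                ext = ("CTTCTACTTCTA" * 3)[:exon5_extension]
                seq = ext + seq
        else:
            length = intron_lengths[seg.name]
            if seg.name == "I2" and intron2_repeat is not None:
                motif_len, copies = intron2_repeat
                motif = "".join(rng.choice(list(_BASES), motif_len))
                unit = int(round(motif_len * copies))
                repeat = (motif * int(np.ceil(copies)))[:unit]
                flank = length - 4 - len(repeat)
                if flank < 2:
                    raise ValueError("intron2_length too short for requested repeat")
                left = "".join(rng.choice(list(_BASES), flank // 2))
                right = "".join(rng.choice(list(_BASES), flank - flank // 2))
                seq = "GT" + left + repeat + right + "AG"
            else:
                seq = _random_intron(rng, length)
        coords[seg.name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)
    return "".join(parts), coords


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_library(
    libraries: Mapping[tuple[str, str, str], list[tuple[str, str]]],
    truth: SimTruth,
    cfg: SimConfig,
    out_dir: str | Path,
) -> None:
    """One FASTA per individual x template x replicate, plus truth tables
    (TSV), the true-allele FASTA and the config (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (ind, tpl, rep), records in sorted(libraries.items()):
        seqio.write_fasta(records, out / f"{ind}_{tpl}_rep{rep}.fasta")
    seqio.write_fasta(sorted(truth.true_alleles.items()), out / "true_alleles.fasta")
    with open(out / "genotypes.tsv", "w") as fh:
        fh.write("individual\tallele_ids\n")
        for ind, g in sorted(truth.genotype.items()):
            fh.write(f"{ind}\t{','.join(g)}\n")
    with open(out / "chimeras.tsv", "w") as fh:
        fh.write("clone_id\tparent_a\tparent_b\tbreakpoint\n")
        for row in truth.chimera_registry:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(out / "errors.tsv", "w") as fh:
        fh.write("clone_id\tposition\tbase\n")
        for row in truth.error_registry:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(out / "expression.tsv", "w") as fh:
        fh.write("locus\texpressed\tclass\n")
        for locus in sorted(truth.expression_mask):
            fh.write(
                f"{locus}\t{int(truth.expression_mask[locus])}\t{truth.locus_class[locus]}\n"
            )
    cfg.to_json(out / "config.json")
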