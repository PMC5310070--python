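"""Allele calling from replicated clone libraries.

The logic is deliberately simple and exact, the way careful clone-library
studies validate multigene amplicons by hand:

1. :func:`collapse_identical` — clones that are exactly identical over the
   comparable region (allowing nested reads of different lengths) collapse
   into one candidate variant whose consensus is the longest member.
2. :func:`detect_chimeras` — a candidate is a PCR chimera when it is seen in
   exactly one PCR product and splits at some breakpoint into a prefix
   identical to one co-occurring variant and a suffix identical to another.
   Chimeras are removed from everything downstream.
3. :func:`confirm_alleles` — a variant recovered from at least two
   independent PCR-and-cloning events is a confirmed allele; singletons are
   kept as provisional (flagged, never silently dropped).
4. :func:`classify_expression` — gDNA-only alleles (among individuals with
   cDNA libraries) are putative non-classical genes; in-frame stop codons
   mark putative pseudogenes.
5. :func:`summarize_individuals` — per-individual distinct-allele counts
   and the diploid lower bound on locus number, ceil(max/2).

No error-model denoising is attempted: exact identity plus replication is
the whole filter, with near-miss singletons reported in a separate artifact
table for inspection.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import find_stop_codons
from .seqio import Allele, CloneRead, name_allele

logger = logging.getLogger("mhcrep")

__all__ = [
    "CandidateVariant",
    "ChimeraCall",
    "collapse_identical",
    "detect_chimeras",
    "confirm_alleles",
    "classify_expression",
    "summarize_individuals",
    "summarize_counts",
    "artifact_table",
]


@dataclass
class CandidateVariant:
    """A set of exactly identical clones (up to nesting of read lengths)."""

    sequence: str  # consensus = longest member
    clone_ids: list[str] = field(default_factory=list)
    support: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def reactions(self) -> set[tuple[str, str, str]]:
        """PCR products (individual x template x replicate) containing it."""
        return set(self.support)

    @property
    def total_copies(self) -> int:
        return sum(self.support.values())


@dataclass
class ChimeraCall:
    variant_sequence: str
    parents: tuple[str, str]  # parent variant sequences (prefix, suffix)
    breakpoint_window: tuple[int, int]  # 0-based half-open interval of valid breakpoints
    reaction: tuple[str, str, str]
    n_reactions: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.breakpoint_window
        if not (0 < lo <= hi <= len(self.variant_sequence)):
            raise ValueError("breakpoint window outside sequence bounds")
        if self.variant_sequence in self.parents:
            raise ValueError("a chimera cannot equal one of its parents")


# ---------------------------------------------------------------------------
# 1. collapse identical reads
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def _orient(seq: str, reference: str) -> str:
    """Return seq or its reverse complement, whichever shares more k-mers
    with the reference exon-2 anchor."""
    k = 11
    ref_kmers = {reference[i : i + k] for i in range(len(reference) - k + 1)}

    def score(s: str) -> int:
        return sum(1 for i in range(0, len(s) - k + 1, k) if s[i : i + k] in ref_kmers)

    rc = seq.translate(_RC)[::-1]
    return seq if score(seq) >= score(rc) else rc


def collapse_identical(
    reads: Sequence[CloneRead],
    reference: str | None = None,
    region: tuple[int, int] | None = None,
) -> list[CandidateVariant]:
    """Partition clones into candidate variants by exact identity.

    Two reads of different lengths merge exactly when the shorter is a
    prefix of the longer over the comparable region (reads share a common
    5' anchor, so nesting means prefix containment); the consensus is the
    longest member.  A shorter read consistent with two distinct longer
    variants is assigned to the better-supported one (ties broken by
    sequence order) — ambiguity at that level cannot be resolved without an
    error model, which this filter deliberately does not have.

    ``reference`` (an exon-2 anchor) enables reverse-complement detection;
    ``region`` restricts comparison to a sub-interval (default: full reads).
    """
    prepared: list[tuple[str, CloneRead]] = []
    for read in reads:
        seq = _orient(read.sequence, reference) if reference else read.sequence
        if region is not None:
            seq = seq[region[0] : region[1]]
        prepared.append((seq, read))

    by_seq: dict[str, list[CloneRead]] = defaultdict(list)
    for seq, read in prepared:
        by_seq[seq].append(read)

    # merge nested lengths: map each sequence to its longest superstring rep
    uniq = sorted(by_seq, key=lambda s: (-len(s), s))
    rep_of: dict[str, str] = {}
    for seq in uniq:
        containers = [
            r for r in rep_of.values() if len(r) > len(seq) and r.startswith(seq)
        ]
        if containers:
            best = max(
                set(containers),
                key=lambda r: (sum(len(by_seq[s]) for s in by_seq if rep_of.get(s) == r), r),
            )
            rep_of[seq] = best
        else:
            rep_of[seq] = seq

    variants: dict[str, CandidateVariant] = {}
    for seq, members in by_seq.items():
        rep = rep_of[seq]
        var = variants.setdefault(rep, CandidateVariant(sequence=rep))
        for read in members:
            var.clone_ids.append(read.clone_id)
            var.support[read.reaction] = var.support.get(read.reaction, 0) + 1
    return sorted(variants.values(), key=lambda v: (-v.total_copies, v.sequence))


# ---------------------------------------------------------------------------
# 2. chimera filter
# ---------------------------------------------------------------------------

def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def detect_chimeras(
    variants: Sequence[CandidateVariant],
) -> tuple[list[CandidateVariant], list[ChimeraCall]]:
    """Flag single-reaction variants explainable as one-breakpoint
    recombinants of two co-occurring variants.

    A variant is a chimera iff (a) it occurs in exactly one PCR product,
    and (b) some breakpoint b splits it into a prefix identical to another
    variant P1 and a suffix identical to a different variant P2, both
    present in that same PCR product, with the variant differing from each
    parent alone.  When several parent pairs fit, the pair with maximal
    combined copy support is reported.  Flagged variants are removed from
    all downstream analyses.
    """
    by_reaction: dict[tuple[str, str, str], list[CandidateVariant]] = defaultdict(list)
    for var in variants:
        for reaction in var.reactions:
            by_reaction[reaction].append(var)

    calls: list[ChimeraCall] = []
    flagged: set[str] = set()
    for var in variants:
        if len(var.reactions) != 1:
            continue
        (reaction,) = var.reactions
        mates = [m for m in by_reaction[reaction] if m.sequence != var.sequence]
        best: tuple[int, ChimeraCall] | None = None
        length = len(var.sequence)
        for p1 in mates:
            lcp = min(_lcp(var.sequence, p1.sequence), length - 1)
            if lcp == 0:
                continue  # p1 cannot donate a non-empty prefix
            for p2 in mates:
                if p2.sequence == p1.sequence:
                    continue
                lcs = _lcs(var.sequence, p2.sequence)
                if lcs == 0:
                    continue
                lo = length - lcs  # smallest valid breakpoint
                hi = lcp  # largest valid breakpoint
                if lo > hi or hi < 1 or lo > length - 1:
                    continue
                window = (max(lo, 1), min(hi, length - 1) + 1)
                if window[0] >= window[1]:
                    continue
                support = p1.total_copies + p2.total_copies
                call = ChimeraCall(
                    variant_sequence=var.sequence,
                    parents=(p1.sequence, p2.sequence),
                    breakpoint_window=window,
                    reaction=reaction,
                )
                if best is None or support > best[0]:
                    best = (support, call)
        if best is not None:
            calls.append(best[1])
            flagged.add(var.sequence)
    clean = [v for v in variants if v.sequence not in flagged]
    return clean, calls


# ---------------------------------------------------------------------------
# 3. replicate-PCR confirmation
# ---------------------------------------------------------------------------

def confirm_alleles(
    variants: Sequence[CandidateVariant],
    taxon_prefix: str = "Amci",
    family_tag: str = "DXB",
) -> list[Allele]:
    """Promote variants to alleles with hierarchical names.

    Variants recovered from >= 2 independent PCR products are confirmed;
    the rest stay provisional but are kept (their status property reflects
    the support).  Naming order is descending copy support (sequence as
    tie-break), so the best-supported lineages take the low major numbers —
    deterministic for a fixed input set.
    """
    alleles: list[Allele] = []
    named: dict[str, str] = {}
    order = sorted(variants, key=lambda v: (-v.total_copies, v.sequence))
    for var in order:
        name = name_allele(var.sequence, named, taxon_prefix, family_tag)
        named[name] = var.sequence
        allele = Allele(name=name, sequence=var.sequence, support=dict(var.support))
        if "N" in var.sequence:
            allele.flags.add("contains_N")
        alleles.append(allele)
    return alleles


# ---------------------------------------------------------------------------
# 4. expression / pseudogene flags
# ---------------------------------------------------------------------------

def classify_expression(
    alleles: Iterable[Allele],
    frame: int = 0,
    individuals_with_cdna: set[str] | None = None,
) -> list[Allele]:
    """Attach putative_pseudogene / putative_nonclassical flags in place.

    An allele carrying an in-frame stop codon is a putative pseudogene.  An
    allele never seen in cDNA, while at least one of its carriers has cDNA
    libraries, is putatively non-classical (or pseudogenised) — absence of
    expression can only be asserted for individuals whose transcripts were
    actually surveyed.  ``frame`` is the codon offset of the amplicon; use
    the annotation stage to establish it for non-default layouts.
    """
    if frame is None:
        raise ValueError(
            "reading frame unknown: annotate the alleles first (annotate module)"
        )
    alleles = list(alleles)
    if individuals_with_cdna is None:
        individuals_with_cdna = {
            ind
            for a in alleles
            for (ind, tpl, _) in a.support
            if tpl == "cDNA"
        }
    for allele in alleles:
        if find_stop_codons(allele.sequence, frame):
            allele.flags.add("putative_pseudogene")
        sources = {tpl for (_, tpl, _) in allele.support}
        if sources == {"gDNA"} and allele.individuals & individuals_with_cdna:
            allele.flags.add("putative_nonclassical")
    return alleles


# ---------------------------------------------------------------------------
# 5. per-individual summary and locus bound
# ---------------------------------------------------------------------------

def summarize_counts(per_individual: Mapping[str, int]) -> dict:
    counts = list(per_individual.values())
    mean = float(np.mean(counts)) if counts else 0.0
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    mx = max(counts) if counts else 0
    return {
        "per_individual": dict(per_individual),
        "n_individuals": len(counts),
        "mean": mean,
        "sd": sd,
        "max": mx,
        "locus_lower_bound": math.ceil(mx / 2),
    }


def summarize_individuals(alleles: Iterable[Allele]) -> dict:
    """Distinct alleles per individual (gDNA and cDNA combined), their mean,
    sample SD and maximum, and the diploid locus lower bound ceil(max/2):
    an individual with k distinct alleles must carry at least k/2 loci."""
    per_individual: Counter[str] = Counter()
    for allele in alleles:
        for ind in allele.individuals:
            per_individual[ind] += 1
    return summarize_counts(dict(sorted(per_individual.items())))


def summarize_report(matrix: pd.DataFrame) -> dict:
    """Summary straight from an allele x (individual, template) count
    matrix: totals by template plus the per-individual statistics."""
    by_template = {
        tpl: int(matrix.loc[:, matrix.columns.get_level_values("template") == tpl].to_numpy().sum())
        for tpl in sorted(set(matrix.columns.get_level_values("template")))
    }
    per_individual: dict[str, int] = {}
    for ind in sorted(set(matrix.columns.get_level_values("individual"))):
        block = matrix.loc[:, matrix.columns.get_level_values("individual") == ind]
        per_individual[ind] = int((block.sum(axis=1) > 0).sum())
    out = summarize_counts(per_individual)
    out["n_alleles"] = int((matrix.sum(axis=1) > 0).sum())
    out["sequences_by_template"] = by_template
    out["total_sequences"] = int(matrix.to_numpy().sum())
    return out


# ---------------------------------------------------------------------------
# artifact table
# ---------------------------------------------------------------------------

def artifact_table(
    variants: Sequence[CandidateVariant],
    confirmed: Sequence[Allele],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Probable PCR point errors: single-reaction singleton variants within
    ``max_mismatches`` substitutions of a confirmed allele.  Reported for
    inspection, never merged into the alleles (the replication rule already
    keeps them out of the confirmed set)."""
    rows = []
    confirmed_seqs = [a for a in confirmed if a.status == "confirmed"]
    for var in variants:
        if len(var.reactions) != 1 or var.total_copies != 1:
            continue
        for allele in confirmed_seqs:
            if len(allele.sequence) != len(var.sequence):
                continue
            mism = sum(1 for x, y in zip(var.sequence, allele.sequence) if x != y)
            if 0 < mism <= max_mismatches:
                rows.append(
                    {
                        "variant": var.sequence,
                        "nearest_allele": allele.name,
                        "mismatches": mism,
                        "reaction": "|".join(next(iter(var.reactions))),
                    }
                )
                break
    return pd.DataFrame(rows, columns=["variant", "nearest_allele", "mismatches", "reaction"])


def filter_artifacts(
    alleles: Sequence[Allele], max_mismatches: int = 2
) -> tuple[list[Allele], list[Allele]]:
    """Split alleles into (kept, probable_artifacts).

    A provisional allele is a probable PCR point artifact when it is a
    single-copy, single-reaction variant within ``max_mismatches``
    substitutions of a confirmed allele of the same length — the curation
    step that keeps error singletons out of per-individual counts while
    genuinely novel provisional alleles (not near-duplicates of anything
    confirmed) stay in.  Artifacts are returned, not discarded: report them.
    """
    confirmed = [a for a in alleles if a.status == "confirmed"]
    kept: list[Allele] = []
    dropped: list[Allele] = []
    for allele in alleles:
        is_artifact = False
        if allele.status == "provisional" and allele.total_copies == 1:
            for ref in confirmed:
                if len(ref.sequence) != len(allele.sequence):
                    continue
                mism = sum(
                    1 for x, y in zip(allele.sequence, ref.sequence) if x != y
                )
                if 0 < mism <= max_mismatches:
                    is_artifact = True
                    break
        if is_artifact:
            allele.flags.add("probable_artifact")
            dropped.append(allele)
        else:
            kept.append(allele)
    return kept, dropped
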