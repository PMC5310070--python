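"""Gene-structure annotation for MHC class IIB sequences.

Teleost MHC class IIB genes carry six exons and five introns.  Exon 1
(55 bp) encodes the leader peptide, exon 2 (273 bp) the polymorphic beta-1
peptide-binding domain, exon 3 (214 bp) the immunoglobulin-like beta-2
domain, exon 4 (69 bp) the connecting peptide, exon 5 (114 bp, with a known
12 bp-extended variant) the transmembrane region, and exon 6 the cytoplasmic
tail.  Intron 2 is wildly length-variable (roughly 200-2500 bp) because of
tandem-repeat expansions, which is why amplicon designs anchor in the exons.

This module maps sequences onto that template (:func:`annotate_sequence`),
scans introns for tandem repeats with a transparent period-k self-match scan
(:func:`find_tandem_repeats`), and locates the conserved cysteine landmarks
of the translated protein (:func:`scan_cysteines`): a leader cysteine near
alignment position 7, the beta-1 disulfide pair at 29/94, and the beta-2
pair at 132/188; extra unpaired cysteines are characteristic of particular
allele groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np

logger = logging.getLogger("mhcrep")

__all__ = [
    "GeneModel",
    "Segment",
    "AnnotationResult",
    "RepeatCall",
    "annotate_sequence",
    "find_tandem_repeats",
    "scan_cysteines",
    "translate",
    "find_stop_codons",
    "write_gff3",
    "CANONICAL_CYSTEINES",
]

SEGMENT_ORDER = ["E1", "I1", "E2", "I2", "E3", "I3", "E4", "I4", "E5", "I5", "E6"]

#: Expected landmark cysteine positions (1-based, alignment coordinates
#: anchored at the first residue of the translated gene including the leader
#: peptide).  29/94 stabilise beta-1, 132/188 stabilise beta-2.
CANONICAL_CYSTEINES = {
    "leader": (7,),
    "canonical_pair_beta1": (29, 94),
    "canonical_pair_beta2": (132, 188),
}

#: Default expected segment lengths (bp).  Introns are ranges because of the
#: extreme observed length variation; exon 5 has a documented +12 bp variant.
DEFAULT_SEGMENT_LENGTHS: dict[str, tuple[int, int]] = {
    "E1": (55, 55),
    "I1": (100, 3000),
    "E2": (273, 273),
    "I2": (200, 2500),
    "E3": (214, 214),
    "I3": (150, 5000),
    "E4": (69, 69),
    "I4": (80, 2000),
    "E5": (114, 126),
    "I5": (80, 2000),
    "E6": (60, 300),
}


@dataclass(frozen=True)
class Segment:
    name: str
    length_range: tuple[int, int]

    @property
    def is_exon(self) -> bool:
        return self.name.startswith("E")


@dataclass
class GeneModel:
    """Exon/intron template plus reference exon sequences.

    ``exon_refs`` maps exon names to reference nucleotide sequences used to
    locate exons in a query by alignment.  Exon 6 is annotated when found but
    never used for allele identity (it carries no allele-specific
    polymorphism).
    """

    segments: list[Segment]
    exon_refs: dict[str, str]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if names != SEGMENT_ORDER[: len(names)]:
            raise ValueError("segments must follow the E1,I1,...,E6 order")

    @property
    def exons(self) -> list[Segment]:
        return [s for s in self.segments if s.is_exon]

    def coding_sequence(self) -> str:
        """Concatenated reference exons = the reading frame of the gene."""
        return "".join(self.exon_refs[e.name] for e in self.exons if e.name in self.exon_refs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "segments": [
                {"name": s.name, "length_range": list(s.length_range)}
                for s in self.segments
            ],
            "exon_refs": self.exon_refs,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            [Segment(d["name"], tuple(d["length_range"])) for d in payload["segments"]],
            payload["exon_refs"],
        )


@dataclass
class RepeatCall:
    period: int
    copies: float
    start: int  # 0-based half-open interval
    end: int
    motif: str


@dataclass
class AnnotationResult:
    segments: dict[str, tuple[int, int]]  # name -> 0-based half-open coords
    absent: list[str]
    frame_offset: int
    stop_codons: list[int]  # codon indices in the exonic reading frame
    repeats: list[RepeatCall]
    length_variants: dict[str, int] = field(default_factory=dict)

    def segment_length(self, name: str) -> int | None:
        if name not in self.segments:
            return None
        s, e = self.segments[name]
        return e - s


# ---------------------------------------------------------------------------
# translation helpers
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


def translate(seq: str, frame: int = 0) -> str:
    """Translate with the standard code; codons with N/gaps become 'X'."""
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def find_stop_codons(seq: str, frame: int = 0) -> list[int]:
    """Codon indices of in-frame stops, excluding a terminal stop."""
    protein = translate(seq, frame)
    stops = [i for i, aa in enumerate(protein) if aa == "*"]
    return [i for i in stops if i < len(protein) - 1]


# ---------------------------------------------------------------------------
# exon location
# ---------------------------------------------------------------------------

#: acceptance rule for an exon hit: >=80% identity over >=80% of the
#: reference exon length; below this the segment is reported absent.
MIN_EXON_IDENTITY = 0.8
MIN_EXON_COVERAGE = 0.8


def _locate(query: str, ref: str) -> tuple[int, int, float] | None:
    """Best infix alignment of ``ref`` inside ``query``.

    Returns (start, end, identity) in query coordinates or None if below the
    acceptance rule.
    """
    max_dist = int(len(ref) * (1 - MIN_EXON_IDENTITY * MIN_EXON_COVERAGE))
    aln = edlib.align(ref, query, mode="HW", task="locations", k=max_dist)
    if aln["editDistance"] < 0 or not aln["locations"]:
        return None
    start, end = aln["locations"][0]
    end += 1  # edlib reports inclusive end
    span = end - start
    if span < MIN_EXON_COVERAGE * len(ref):
        return None
    identity = 1 - aln["editDistance"] / max(span, len(ref))
    if identity < MIN_EXON_IDENTITY:
        return None
    return start, end, identity


def _refine_five_prime(seq: str, start: int, floor: int, window: int = 24) -> int:
    """Pull an exon's 5' boundary back to the nearest upstream splice
    acceptor (introns end with the canonical AG dinucleotide).

    Reference-guided location finds the conserved exon core; alleles with
    extra coding bases at the 5' end (a known exon-5 variant) place the true
    splice boundary upstream of the core.  The nearest AG whose end lies in
    ``[start - window, start]`` marks that boundary.
    """
    lo = max(floor, start - window)
    for j in range(start, lo - 1, -1):
        if j >= 2 and seq[j - 2 : j] == "AG":
            return j
    return start


def annotate_sequence(seq: str, model: GeneModel) -> AnnotationResult:
    """Map ``seq`` onto the exon/intron template of ``model``.

    Exons are located by best infix alignment of each reference exon, in
    order; introns are the gaps between located exons.  Partial coverage is
    normal (amplicons rarely span the whole gene): missing segments are
    reported absent.  Exons found out of order raise — that is a structural
    anomaly, not a parsing problem.
    """
    seq = seq.upper()
    found: dict[str, tuple[int, int]] = {}
    last_end = -1
    last_exon = None
    for exon in model.exons:
        ref = model.exon_refs.get(exon.name)
        if ref is None:
            continue
        hit = _locate(seq, ref)
        if hit is None:
            continue
        start, end, _ = hit
        if start < last_end:
            raise ValueError(
                f"structural anomaly: {exon.name} found at {start} before end "
                f"of {last_exon} ({last_end})"
            )
        if exon.name != "E1" and start - last_end >= 2:
            start = _refine_five_prime(seq, start, floor=max(last_end, 0))
        found[exon.name] = (start, end)
        last_end, last_exon = end, exon.name

    segments: dict[str, tuple[int, int]] = dict(found)
    exon_names = [e.name for e in model.exons]
    for i in range(len(exon_names) - 1):
        a, b = exon_names[i], exon_names[i + 1]
        if a in found and b in found:
            ia = f"I{i + 1}"
            segments[ia] = (found[a][1], found[b][0])
    absent = [s.name for s in model.segments if s.name not in segments]

    length_variants: dict[str, int] = {}
    for name, (s, e) in found.items():
        lo, hi = dict(DEFAULT_SEGMENT_LENGTHS).get(name, (0, 10**9))
        expected = len(model.exon_refs.get(name, ""))
        if expected and (e - s) != expected:
            length_variants[name] = (e - s) - expected
        elif not (lo <= e - s <= hi):
            length_variants[name] = e - s

    # reading frame: anchor on the first located exon's offset within the
    # concatenated coding sequence of the model
    frame_offset = 0
    coding_before = 0
    for exon in model.exons:
        if exon.name in found:
            frame_offset = (3 - coding_before % 3) % 3
            break
        coding_before += len(model.exon_refs.get(exon.name, ""))

    exonic = "".join(seq[s:e] for name, (s, e) in sorted(found.items(), key=lambda kv: kv[1][0]))
    stops = find_stop_codons(exonic, frame_offset)

    repeats: list[RepeatCall] = []
    for name, (s, e) in segments.items():
        if name.startswith("I") and e - s >= 40:
            for call in find_tandem_repeats(seq[s:e]):
                repeats.append(
                    RepeatCall(call.period, call.copies, call.start + s, call.end + s, call.motif)
                )

    return AnnotationResult(
        segments=segments,
        absent=absent,
        frame_offset=frame_offset,
        stop_codons=stops,
        repeats=repeats,
        length_variants=length_variants,
    )


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def find_tandem_repeats(
    seq: str,
    min_period: int = 2,
    max_period: int = 150,
    min_copies: float = 1.9,
    max_mismatch_frac: float = 0.2,
) -> list[RepeatCall]:
    """Period-k self-match scan for tandem repeats.

    For each candidate period k the sequence is compared against itself
    shifted by k; maximal runs whose mismatch fraction stays at or below
    ``max_mismatch_frac`` and whose implied copy number reaches
    ``min_copies`` are reported.  Fractional copy numbers (run length + k
    over k) are natural here — a 42-mer repeated 6.4 times ends mid-motif.
    Overlapping calls with different periods are all reported, longest span
    first; same-period overlaps are merged.
    """
    seq = seq.upper()
    n = len(seq)
    calls: list[RepeatCall] = []
    for k in range(min_period, min(max_period, n // 2) + 1):
        match = np.frombuffer(seq.encode(), dtype=np.uint8)
        m = match[k:] == match[:-k]  # m[i]: seq[i+k] == seq[i]
        runs = _mismatch_tolerant_runs(m, max_mismatch_frac, min_len=max(k, 4))
        period_calls: list[tuple[int, int]] = []
        for start, end in runs:
            total = end - start + k  # full repeated interval in seq coords
            copies = total / k
            if copies < min_copies:
                continue
            period_calls.append((start, start + total))
        for start, end in _merge_intervals(period_calls):
            copies = (end - start) / k
            if copies < min_copies:
                continue
            motif = seq[start : start + k]
            calls.append(RepeatCall(k, round(copies, 2), start, end, motif))
    # drop harmonics: a call whose period is a multiple of a smaller-period
    # call covering the same interval adds nothing
    kept: list[RepeatCall] = []
    for call in sorted(calls, key=lambda c: (-(c.end - c.start), c.period)):
        redundant = any(
            call.period % other.period == 0
            and other.start <= call.start
            and call.end <= other.end
            for other in kept
        )
        if not redundant:
            kept.append(call)
    return kept


def _mismatch_tolerant_runs(
    m: np.ndarray, max_mismatch_frac: float, min_len: int
) -> list[tuple[int, int]]:
    """Maximal-scoring segments of the boolean match array.

    A match scores +1 and a mismatch -(1-f)/f where f is the tolerated
    mismatch fraction, so any segment with non-negative score has mismatch
    fraction <= f, random sequence (~25% chance matches) scores negative on
    average, and segments end exactly on matches — no greedy drift into the
    flanks.  Classic linear-time maximal-segment scanning.
    """
    penalty = (1.0 - max_mismatch_frac) / max_mismatch_frac
    scores = np.where(m, 1.0, -penalty)
    runs: list[tuple[int, int]] = []
    cur = 0.0
    start = 0
    best = 0.0
    best_end = -1
    for i, s in enumerate(scores):
        if cur <= 0:
            if best_end >= 0 and best_end - start >= min_len:
                runs.append((start, best_end))
            cur, start, best, best_end = 0.0, i, 0.0, -1
        cur += s
        if cur > best:
            best, best_end = cur, i + 1
    if best_end >= 0 and best_end - start >= min_len:
        runs.append((start, best_end))
    return runs


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# cysteine landmarks
# ---------------------------------------------------------------------------

def scan_cysteines(
    proteins: Mapping[str, str], tolerance: int = 0
) -> dict[str, dict]:
    """Locate cysteine landmarks in aligned translated alleles.

    ``proteins`` maps allele name to an aligned amino-acid string whose
    position 1 is the first residue of the alignment consensus including the
    leader peptide.  Returns, per allele, the cysteine positions (1-based),
    their classification, and whether each canonical disulfide pair is
    complete; alleles missing a pair are flagged as a structural-stability
    concern.  Untranslatable entries (containing '*') are skipped with a
    warning.
    """
    landmark_of: dict[int, str] = {}
    for label, positions in CANONICAL_CYSTEINES.items():
        for pos in positions:
            landmark_of[pos] = label
    table: dict[str, dict] = {}
    for name, protein in proteins.items():
        if "*" in protein:
            logger.warning("allele %s: untranslatable (internal stop); skipped", name)
            continue
        positions = [i + 1 for i, aa in enumerate(protein) if aa == "C"]
        classified: dict[int, str] = {}
        for pos in positions:
            label = "extra"
            for anchor, lab in landmark_of.items():
                if abs(pos - anchor) <= tolerance:
                    label = lab
                    break
            classified[pos] = label
        missing = []
        for label in ("canonical_pair_beta1", "canonical_pair_beta2"):
            anchors = [p for p in CANONICAL_CYSTEINES[label] if p <= len(protein)]
            if not anchors:
                continue  # domain not covered by this (partial) allele
            satisfied = all(
                any(abs(pos - anchor) <= tolerance for pos in positions)
                for anchor in anchors
            )
            if not satisfied or len(anchors) < len(CANONICAL_CYSTEINES[label]):
                missing.append(label)
        extras = [p for p, lab in classified.items() if lab == "extra"]
        table[name] = {
            "cys_positions": positions,
            "classification": classified,
            "extra": extras,
            "missing_pairs": missing,
            "stability_concern": bool(missing),
        }
    return table


# ---------------------------------------------------------------------------
# GFF3 output
# ---------------------------------------------------------------------------

def write_gff3(
    annotations: Mapping[str, AnnotationResult], path: str | Path
) -> None:
    """Segments and repeat calls as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ann in annotations.items():
            for name, (s, e) in sorted(ann.segments.items(), key=lambda kv: kv[1][0]):
                ftype = "exon" if name.startswith("E") else "intron"
                fh.write(
                    f"{seqid}\tmhcrep\t{ftype}\t{s + 1}\t{e}\t.\t+\t.\tID={seqid}.{name};Name={name}\n"
                )
            for i, rep in enumerate(ann.repeats):
                fh.write(
                    f"{seqid}\tmhcrep\ttandem_repeat\t{rep.start + 1}\t{rep.end}\t.\t+\t.\t"
                    f"ID={seqid}.TR{i};period={rep.period};copies={rep.copies}\n"
                )


def read_gff3_segments(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    """Inverse of :func:`write_gff3` for exon/intron features (0-based
    half-open), used to round-trip annotation coordinates."""
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        seqid, _, ftype, start, end, *rest = line.split("\t")
        if ftype not in ("exon", "intron"):
            continue
        attrs = dict(kv.split("=", 1) for kv in rest[-1].split(";"))
        out.setdefault(seqid, {})[attrs["Name"]] = (int(start) - 1, int(end))
    return out
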