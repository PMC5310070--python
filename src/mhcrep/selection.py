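"""Codon-based dN/dS estimation and Z-tests of overall selection.

Two pairwise estimators are provided:

* **NG86** (:func:`ng86_pair`) — Nei-Gojobori counting.  Each codon
  contributes potential synonymous/nonsynonymous site counts (the fraction
  of its nine one-step mutations that are synonymous, with stop-producing
  mutations excluded from the denominator), and observed differences are
  averaged over all minimal mutational pathways between the two codons,
  excluding pathways that pass through stop codons.  Proportions are
  corrected with Jukes-Cantor (:func:`distance_from_counts`).
* **PBL** (:func:`pbl_pair`) — Pamilo-Bianchi-Li.  Sites are classified by
  degeneracy (nondegenerate L0, twofold L2, fourfold L4, averaged over the
  pair); Kimura 2-parameter transition (A_i) and transversion (B_i)
  components are estimated per class, and
  dS = (L2 A2 + L4 A4)/(L2 + L4) + B4,
  dN = A0 + (L0 B0 + L2 B2)/(L0 + L2).

:func:`group_selection_test` applies either estimator pairwise over all
alleles in scope ("compare two sequences at a time and average over all
possible comparisons" — which lets incompletely sequenced alleles enter),
and assesses overall selection with a codon-bootstrap Z-test: codon columns
are resampled with replacement, dN - dS recomputed per replicate, and
one-tailed p-values read off the bootstrap distribution (a normal
approximation Z is reported alongside).  dN/dS is undefined (NaN) when
dS = 0 — low-polymorphism nonclassical groups routinely have no synonymous
substitutions at all.

Everything is table-driven: per-codon site counts and per-codon-pair
pathway-averaged difference counts are precomputed over the 64 codons, so
alignments reduce to integer lookups and the bootstrap is a matrix product.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import CodonAlignment

logger = logging.getLogger("mhcrep")

__all__ = [
    "CodonPairCounts",
    "SelectionResult",
    "ng86_pair",
    "pbl_pair",
    "distance_from_counts",
    "group_selection_test",
    "GENETIC_CODE",
]

_BASES = "TCAG"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE = dict(zip(_CODONS, _AA))
_STOP_IDX = {i for i, aa in enumerate(_AA) if aa == "*"}
_PURINE = {"A": True, "G": True, "C": False, "T": False}


def _is_transition(x: str, y: str) -> bool:
    return x != y and _PURINE[x] == _PURINE[y]


# ---------------------------------------------------------------------------
# precomputed NG86 tables
# ---------------------------------------------------------------------------

def _syn_sites_per_codon() -> np.ndarray:
    """s[i] = potential synonymous sites of codon i (0..3).  Mutations to
    stop codons are excluded from the per-position denominator, so the
    per-codon total of synonymous + nonsynonymous sites stays exactly 3."""
    s = np.zeros(64)
    for idx, codon in enumerate(_CODONS):
        if idx in _STOP_IDX:
            s[idx] = np.nan
            continue
        total = 0.0
        for pos in range(3):
            syn = nonstop = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if GENETIC_CODE[mut] == "*":
                    continue
                nonstop += 1
                if GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                    syn += 1
            total += syn / nonstop if nonstop else 0.0
        s[idx] = total
    return s


def _pathway_counts() -> tuple[np.ndarray, np.ndarray]:
    """(sd, nd)[i, j]: synonymous and nonsynonymous differences between
    codons i and j, averaged over all minimal mutational pathways that avoid
    stop codons (all pathways if every one passes through a stop)."""
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, a in enumerate(_CODONS):
        for j, b in enumerate(_CODONS):
            if i in _STOP_IDX or j in _STOP_IDX:
                sd[i, j] = nd[i, j] = np.nan
                continue
            diff_pos = [p for p in range(3) if a[p] != b[p]]
            if not diff_pos:
                continue
            path_syn: list[int] = []
            path_non: list[int] = []
            blocked_syn: list[int] = []
            blocked_non: list[int] = []
            for order in itertools.permutations(diff_pos):
                cur = a
                syn = non = 0
                through_stop = False
                for pos in order:
                    nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                    if GENETIC_CODE[nxt] == "*":
                        through_stop = True
                    if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                (blocked_syn if through_stop else path_syn).append(syn)
                (blocked_non if through_stop else path_non).append(non)
            if path_syn:
                sd[i, j] = float(np.mean(path_syn))
                nd[i, j] = float(np.mean(path_non))
            else:  # every pathway crosses a stop; fall back to all pathways
                sd[i, j] = float(np.mean(blocked_syn))
                nd[i, j] = float(np.mean(blocked_non))
    return sd, nd


_SYN_SITES = _syn_sites_per_codon()
_SD_TABLE, _ND_TABLE = _pathway_counts()


# ---------------------------------------------------------------------------
# precomputed PBL tables
# ---------------------------------------------------------------------------

def _degeneracy_classes() -> np.ndarray:
    """deg[codon, pos] in {0, 2, 4}: number class of the site.  Fourfold =
    all three changes synonymous; twofold = one or two synonymous changes
    (threefold sites fold into twofold, the standard convention);
    nondegenerate = none."""
    deg = np.zeros((64, 3), dtype=int)
    for idx, codon in enumerate(_CODONS):
        if idx in _STOP_IDX:
            deg[idx] = -1
            continue
        for pos in range(3):
            syn = sum(
                1
                for b in _BASES
                if b != codon[pos]
                and GENETIC_CODE[codon[:pos] + b + codon[pos + 1 :]]
                == GENETIC_CODE[codon]
            )
            deg[idx, pos] = 4 if syn == 3 else (2 if syn >= 1 else 0)
    return deg


_DEG = _degeneracy_classes()
_CLASS_OF = {0: 0, 2: 1, 4: 2}

# per codon: site counts per degeneracy class, shape (64, 3) = (L0, L2, L4)
_L_TABLE = np.full((64, 3), np.nan)
for _i in range(64):
    if _i not in _STOP_IDX:
        _L_TABLE[_i] = [np.sum(_DEG[_i] == d) for d in (0, 2, 4)]

# per codon pair: transition and transversion difference counts per class,
# classes averaged over the two codons (half weight to each codon's class)
_TS_TABLE = np.full((64, 64, 3), np.nan)
_TV_TABLE = np.full((64, 64, 3), np.nan)
for _i, _a in enumerate(_CODONS):
    if _i in _STOP_IDX:
        continue
    for _j, _b in enumerate(_CODONS):
        if _j in _STOP_IDX:
            continue
        ts = np.zeros(3)
        tv = np.zeros(3)
        for _pos in range(3):
            if _a[_pos] == _b[_pos]:
                continue
            target = ts if _is_transition(_a[_pos], _b[_pos]) else tv
            target[_CLASS_OF[_DEG[_i, _pos]]] += 0.5
            target[_CLASS_OF[_DEG[_j, _pos]]] += 0.5
        _TS_TABLE[_i, _j] = ts
        _TV_TABLE[_i, _j] = tv


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CodonPairCounts:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    codons_compared: int

    def __post_init__(self) -> None:
        if self.codons_compared:
            assert abs(self.N_sites + self.S_sites - 3 * self.codons_compared) < 1e-9
        if self.Nd > self.N_sites + 1e-9 or self.Sd > self.S_sites + 1e-9:
            raise ValueError("difference counts exceed site counts")


@dataclass
class SelectionResult:
    scope: str
    domain: str
    n_alleles: int
    aa_length: int
    dN: float
    dS: float
    dN_se: float
    dS_se: float
    dN_count: float
    dS_count: float
    dN_count_se: float
    dS_count_se: float
    omega: float
    z: float
    p_positive: float
    p_purifying: float
    n_bootstrap: int
    method: str
    n_pairs: int

    def as_row(self) -> dict:
        return {
            "scope": self.scope,
            "domain": self.domain,
            "n": self.n_alleles,
            "length_aa": self.aa_length,
            "dN": self.dN,
            "dN_SE": self.dN_se,
            "dN_number": self.dN_count,
            "dS": self.dS,
            "dS_SE": self.dS_se,
            "dS_number": self.dS_count,
            "dN/dS": self.omega,
            "Z": self.z,
            "p_purifying": self.p_purifying,
            "p_positive": self.p_positive,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_codons(seq: str) -> np.ndarray:
    """Codon indices (0..63), -1 for codons with gaps or ambiguity."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    out = np.full(len(seq) // 3, -1, dtype=np.int64)
    for c in range(len(out)):
        codon = seq[3 * c : 3 * c + 3]
        out[c] = _CODON_INDEX.get(codon, -1)
    return out


def _validate_pair(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    if len(ca) != len(cb):
        raise ValueError("codon vectors differ in length")
    shared = (ca >= 0) & (cb >= 0)
    for name, vec in (("first", ca), ("second", cb)):
        stops = [
            int(i)
            for i in np.flatnonzero(shared)
            if int(vec[i]) in _STOP_IDX and i < len(vec) - 1
        ]
        if stops:
            raise ValueError(
                f"internal stop codon(s) in {name} sequence at codon(s) "
                f"{[s + 1 for s in stops]}; screen pseudogenes out upstream"
            )
    return shared


# ---------------------------------------------------------------------------
# pairwise estimators
# ---------------------------------------------------------------------------

def ng86_pair(
    codons_a: str | np.ndarray,
    codons_b: str | np.ndarray,
    genetic_code: dict | None = None,
) -> CodonPairCounts:
    """Nei-Gojobori counts for one aligned pair.

    Codons with a gap or ambiguity in either sequence are skipped pairwise.
    Only the standard genetic code is supported (``genetic_code`` is
    accepted for signature stability and must be None or the standard code).
    """
    if genetic_code is not None and genetic_code != GENETIC_CODE:
        raise NotImplementedError("only the standard genetic code is supported")
    ca = encode_codons(codons_a) if isinstance(codons_a, str) else np.asarray(codons_a)
    cb = encode_codons(codons_b) if isinstance(codons_b, str) else np.asarray(codons_b)
    shared = _validate_pair(ca, cb)
    ia, ib = ca[shared], cb[shared]
    n_codons = int(shared.sum())
    if n_codons == 0:
        return CodonPairCounts(0.0, 0.0, 0.0, 0.0, 0)
    s_sites = float((_SYN_SITES[ia] + _SYN_SITES[ib]).sum() / 2.0)
    n_sites = 3.0 * n_codons - s_sites
    sd = float(_SD_TABLE[ia, ib].sum())
    nd = float(_ND_TABLE[ia, ib].sum())
    return CodonPairCounts(n_sites, s_sites, nd, sd, n_codons)


def distance_from_counts(
    counts: CodonPairCounts, correction: str = "JC"
) -> tuple[float, float]:
    """(dS, dN) from NG86 counts; ``correction`` is "JC" or "none".

    Returns NaN for a rate whose site count is zero or whose proportion is
    at/beyond the Jukes-Cantor saturation point p >= 3/4 (with a warning).
    """
    if correction not in ("JC", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    def one(d: float, sites: float) -> float:
        if sites <= 0:
            return float("nan")
        p = d / sites
        if correction == "none":
            return p
        if p >= 0.75:
            warnings.warn("proportion >= 0.75: JC distance undefined")
            return float("nan")
        return float(-0.75 * np.log(1 - 4 * p / 3))

    return one(counts.Sd, counts.S_sites), one(counts.Nd, counts.N_sites)


def _k2p_components(P: float, Q: float) -> tuple[float, float]:
    """Kimura transition component A and transversion component B; NaN when
    a logarithm argument is non-positive."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan"), float("nan")
    A = 0.5 * np.log(1.0 / w1) - 0.25 * np.log(1.0 / w2)
    B = 0.5 * np.log(1.0 / w2)
    return float(A), float(B)


def pbl_pair(
    codons_a: str | np.ndarray, codons_b: str | np.ndarray
) -> tuple[float, float]:
    """Pamilo-Bianchi-Li (dS, dN) with Kimura 2-parameter correction."""
    ca = encode_codons(codons_a) if isinstance(codons_a, str) else np.asarray(codons_a)
    cb = encode_codons(codons_b) if isinstance(codons_b, str) else np.asarray(codons_b)
    shared = _validate_pair(ca, cb)
    ia, ib = ca[shared], cb[shared]
    if len(ia) == 0:
        return float("nan"), float("nan")
    L = (_L_TABLE[ia] + _L_TABLE[ib]).sum(axis=0) / 2.0
    ts = _TS_TABLE[ia, ib].sum(axis=0)
    tv = _TV_TABLE[ia, ib].sum(axis=0)
    return _pbl_from_class_counts(L, ts, tv)


def _pbl_from_class_counts(
    L: np.ndarray, ts: np.ndarray, tv: np.ndarray
) -> tuple[float, float]:
    A = np.full(3, np.nan)
    B = np.full(3, np.nan)
    for i in range(3):
        if L[i] > 0:
            A[i], B[i] = _k2p_components(ts[i] / L[i], tv[i] / L[i])
        elif ts[i] == 0 and tv[i] == 0:
            A[i], B[i] = 0.0, 0.0
    if np.isnan(A).any() or np.isnan(B).any():
        warnings.warn("PBL distance undefined (saturated class); NaN returned")
        return float("nan"), float("nan")
    L0, L2, L4 = L
    dS = (L2 * A[1] + L4 * A[2]) / (L2 + L4) + B[2] if (L2 + L4) > 0 else float("nan")
    dN = A[0] + (L0 * B[0] + L2 * B[1]) / (L0 + L2) if (L0 + L2) > 0 else float("nan")
    return float(dS), float(dN)


# ---------------------------------------------------------------------------
# group-level Z-test
# ---------------------------------------------------------------------------

def group_selection_test(
    alignment: CodonAlignment,
    names: Sequence[str] | None = None,
    domain: str | Sequence[str] = ("LP", "beta1", "beta2"),
    method: str = "ng86",
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_shared_codons: int = 30,
    scope_label: str = "",
) -> SelectionResult:
    """Overall-selection Z-test for a set of alleles over a domain.

    dN and dS are means over all unordered pairs; a pair enters the average
    only if the two sequences share at least ``min_shared_codons`` fully
    resolved codons in the domain (incompletely sequenced alleles are kept,
    they just contribute fewer pairs).  Standard errors come from a codon
    bootstrap: domain codon columns are resampled with replacement and the
    pairwise-mean dN and dS recomputed per replicate (pair inclusion is
    fixed at the point estimate).  One-tailed p-values are read from the
    bootstrap distribution of dN - dS:
    p_positive = (1 + #{replicates with dN - dS <= 0}) / (n_bootstrap + 1),
    and symmetrically for purifying selection; Z = (dN - dS)/SE(dN - dS) is
    reported for comparability with the normal approximation.

    ``method`` is "ng86" (Jukes-Cantor-corrected Nei-Gojobori) or "pbl";
    difference *numbers* (dN_count/dS_count) always come from NG86 counting,
    which is the counting scheme defined for them.
    """
    if names is None:
        names = alignment.names
    idx = [alignment.names.index(n) for n in names]
    if len(idx) < 2:
        raise ValueError("need at least two alleles in scope")
    cols = alignment.domain_codons(domain)
    if len(cols) == 0:
        raise ValueError(f"domain {domain!r} has no codons in this alignment")
    codes = np.stack([encode_codons(alignment.sequences[i]) for i in idx])[:, cols]
    # pseudogene guard: internal stops are upstream errors
    for row, n in zip(codes, names):
        interior = row[:-1] if cols[-1] == alignment.n_codons - 1 else row
        if any(int(c) in _STOP_IDX for c in interior if c >= 0):
            raise ValueError(f"internal stop codon in {n}; exclude pseudogenes upstream")

    n_seq, n_col = codes.shape
    pairs = [(i, j) for i in range(n_seq) for j in range(i + 1, n_seq)]
    shared = (codes[:, None, :] >= 0) & (codes[None, :, :] >= 0)

    kept_pairs = []
    for i, j in pairs:
        if int(shared[i, j].sum()) >= min_shared_codons:
            kept_pairs.append((i, j))
    if not kept_pairs:
        raise ValueError(
            f"no allele pair shares {min_shared_codons} codons in domain {domain!r}"
        )
    n_pairs = len(kept_pairs)

    # per-pair, per-column contribution matrices (zero where not shared)
    if method == "ng86":
        mats = {k: np.zeros((n_pairs, n_col)) for k in ("nd", "sd", "ns", "ss")}
        for p, (i, j) in enumerate(kept_pairs):
            m = shared[i, j]
            ia, ib = codes[i, m], codes[j, m]
            mats["sd"][p, m] = _SD_TABLE[ia, ib]
            mats["nd"][p, m] = _ND_TABLE[ia, ib]
            ss = (_SYN_SITES[ia] + _SYN_SITES[ib]) / 2.0
            mats["ss"][p, m] = ss
            mats["ns"][p, m] = 3.0 - ss
        point = _ng86_summarise(mats, np.ones(n_col))
    elif method == "pbl":
        mats = {
            "L": np.zeros((n_pairs, n_col, 3)),
            "ts": np.zeros((n_pairs, n_col, 3)),
            "tv": np.zeros((n_pairs, n_col, 3)),
            "nd": np.zeros((n_pairs, n_col)),
            "sd": np.zeros((n_pairs, n_col)),
            "ns": np.zeros((n_pairs, n_col)),
            "ss": np.zeros((n_pairs, n_col)),
        }
        for p, (i, j) in enumerate(kept_pairs):
            m = shared[i, j]
            ia, ib = codes[i, m], codes[j, m]
            mats["L"][p, m] = (_L_TABLE[ia] + _L_TABLE[ib]) / 2.0
            mats["ts"][p, m] = _TS_TABLE[ia, ib]
            mats["tv"][p, m] = _TV_TABLE[ia, ib]
            mats["sd"][p, m] = _SD_TABLE[ia, ib]
            mats["nd"][p, m] = _ND_TABLE[ia, ib]
            ss = (_SYN_SITES[ia] + _SYN_SITES[ib]) / 2.0
            mats["ss"][p, m] = ss
            mats["ns"][p, m] = 3.0 - ss
        point = _pbl_summarise(mats, np.ones(n_col))
    else:
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng([seed, 6])
    boots = np.empty((n_bootstrap, 4))  # dN, dS, Nd, Sd per replicate
    summarise = _ng86_summarise if method == "ng86" else _pbl_summarise
    for b in range(n_bootstrap):
        draw = rng.integers(0, n_col, size=n_col)
        w = np.bincount(draw, minlength=n_col).astype(float)
        boots[b] = summarise(mats, w)

    dN, dS, nd_count, sd_count = point
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dn_b, ds_b = boots[:, 0], boots[:, 1]
        diff_b = dn_b - ds_b
        valid = ~np.isnan(diff_b)
        se = float(np.nanstd(diff_b, ddof=1)) if valid.sum() > 1 else float("nan")
        diff = dN - dS
        z = diff / se if se and se > 0 else float("nan")
        nb = int(valid.sum())
        p_pos = float((1 + np.sum(diff_b[valid] <= 0)) / (nb + 1)) if nb else float("nan")
        p_pur = float((1 + np.sum(diff_b[valid] >= 0)) / (nb + 1)) if nb else float("nan")
        dn_se = float(np.nanstd(dn_b, ddof=1))
        ds_se = float(np.nanstd(ds_b, ddof=1))
        ndc_se = float(np.nanstd(boots[:, 2], ddof=1))
        sdc_se = float(np.nanstd(boots[:, 3], ddof=1))

    omega = dN / dS if dS and not np.isnan(dS) and dS > 0 else float("nan")
    if np.isnan(omega):
        logger.info(
            "%s/%s: dS = 0 or undefined; dN/dS not calculable", scope_label, domain
        )
    return SelectionResult(
        scope=scope_label or ",".join(map(str, names[:3])) + ("..." if len(names) > 3 else ""),
        domain=domain if isinstance(domain, str) else "+".join(domain),
        n_alleles=len(names),
        aa_length=int(n_col),
        dN=dN,
        dS=dS,
        dN_se=dn_se,
        dS_se=ds_se,
        dN_count=nd_count,
        dS_count=sd_count,
        dN_count_se=ndc_se,
        dS_count_se=sdc_se,
        omega=omega,
        z=float(z),
        p_positive=p_pos,
        p_purifying=p_pur,
        n_bootstrap=n_bootstrap,
        method=method,
        n_pairs=n_pairs,
    )


def _ng86_summarise(mats: dict, w: np.ndarray) -> tuple[float, float, float, float]:
    """Column-weighted pairwise means (dN, dS, Nd, Sd) under NG86 + JC."""
    nd = mats["nd"] @ w
    sd = mats["sd"] @ w
    ns = mats["ns"] @ w
    ss = mats["ss"] @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        pn = np.where(ns > 0, nd / ns, np.nan)
        ps = np.where(ss > 0, sd / ss, np.nan)
        dn = np.where(pn < 0.75, -0.75 * np.log(1 - 4 * pn / 3), np.nan)
        ds = np.where(ps < 0.75, -0.75 * np.log(1 - 4 * ps / 3), np.nan)
    return (
        float(np.nanmean(dn)) if not np.isnan(dn).all() else float("nan"),
        float(np.nanmean(ds)) if not np.isnan(ds).all() else float("nan"),
        float(np.nanmean(nd)),
        float(np.nanmean(sd)),
    )


def _pbl_summarise(mats: dict, w: np.ndarray) -> tuple[float, float, float, float]:
    """Column-weighted pairwise means (dN, dS) under PBL + K2P; difference
    numbers from NG86 counting (the convention for 'absolute' numbers)."""
    L = np.einsum("pck,c->pk", mats["L"], w)
    ts = np.einsum("pck,c->pk", mats["ts"], w)
    tv = np.einsum("pck,c->pk", mats["tv"], w)
    n_pairs = L.shape[0]
    dn = np.empty(n_pairs)
    ds = np.empty(n_pairs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(n_pairs):
            ds[p], dn[p] = _pbl_from_class_counts(L[p], ts[p], tv[p])
    nd = mats["nd"] @ w
    sd = mats["sd"] @ w
    return (
        float(np.nanmean(dn)) if not np.isnan(dn).all() else float("nan"),
        float(np.nanmean(ds)) if not np.isnan(ds).all() else float("nan"),
        float(np.nanmean(nd)),
        float(np.nanmean(sd)),
    )
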