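"""End-to-end orchestration: simulate -> call -> annotate -> group ->
selection -> tree/TSP, with one config, deterministic seeding and a
checksummed output manifest.

A run is driven by a :class:`PipelineConfig` (YAML/JSON on disk).  Each
stage draws its randomness from a named substream of the root seed, so
toggling one stage never perturbs another, and two runs with the same
config produce byte-identical outputs (the manifest records SHA-256 of
every file).  Fidelity modes trade bootstrap/permutation depth:
``test`` uses 1000 bootstrap replicates, ``full`` 10000 (permutations are
999 in both).

Instead of simulating, a run may start from user data: clone FASTA files
plus a sample sheet (calling stages), or an allele FASTA (grouping,
selection and TSP only) — e.g. a downloaded set of deposited alleles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, calling, grouping, phylo, selection, seqio, simlib

logger = logging.getLogger("mhcrep")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "call", "annotate", "group", "selection", "tree", "tsp")


@dataclass
class PipelineConfig:
    out_dir: str = "mhcrep_run"
    seed: int = 0
    fidelity: str = "test"  # "test" -> 1000 bootstraps, "full" -> 10000
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    sim: dict[str, Any] = field(default_factory=dict)
    input_clones: list[str] = field(default_factory=list)
    sample_sheet: str | None = None
    input_alleles: str | None = None
    species_fasta: str | None = None  # comparator alleles with species= tags
    min_pcr: int = 2
    drop_artifacts: bool = True
    distance_method: str = "k2p"
    deletion: str = "complete"
    cluster_cut: float | None = None
    min_group_size: int = 4
    n_perm: int = 999
    min_shared_codons: int = 30
    beta1_codons: int = 91
    exclude_provisional: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.fidelity not in ("test", "full"):
            raise ValueError("fidelity must be 'test' or 'full'")
        if "tsp" in self.stages and "simulate" not in self.stages and not self.species_fasta:
            # TSP against simulated second-species repertoires needs simulate;
            # real screens need comparator sequences
            if self.input_alleles:
                raise ValueError(
                    "tsp stage on user alleles requires species_fasta comparators"
                )
        if "selection" in self.stages and "group" not in self.stages:
            raise ValueError(
                "selection uses the group table (method choice per group); "
                "enable the group stage"
            )

    @property
    def n_bootstrap(self) -> int:
        return 10000 if self.fidelity == "full" else 1000

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where a run lands must not change what it computes
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, dict[str, str]] = {}
        self.warnings: list[str] = []

    def stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def record(self, stage: str, *paths: Path) -> None:
        bucket = self.manifest.setdefault(stage, {})
        for p in paths:
            bucket[str(p.relative_to(self.out))] = _sha256(p)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages in order; returns the report bundle dict
    (also written as ``manifest.json`` / ``report.json`` in the out dir).

    A failure inside a stage is re-raised tagged with the stage name.
    """
    run = _Run(cfg)
    state: dict[str, Any] = {}
    for stage in _STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FUNCS[stage](run, state)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "fidelity": cfg.fidelity,
        "stages_run": [s for s in _STAGES if s in cfg.stages],
        "summary": state.get("summary", {}),
        "warnings": run.warnings,
    }
    (run.out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    run.record("report", run.out / "report.json")
    (run.out / "manifest.json").write_text(json.dumps(run.manifest, indent=2))
    return {**report, "manifest": run.manifest, "state": state}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(run: _Run, state: dict) -> None:
    cfg = run.cfg
    sim_cfg = simlib.SimConfig(**{"seed": cfg.seed, **cfg.sim})
    alleles, genotypes, expression = simlib.simulate_repertoire(sim_cfg)
    libraries, truth = simlib.simulate_clone_library(
        alleles, genotypes, expression, sim_cfg
    )
    out = run.stage_dir("simulate")
    simlib.write_library(libraries, truth, sim_cfg, out)
    run.record("simulate", *sorted(out.glob("*")))
    state["sim_cfg"] = sim_cfg
    state["truth"] = truth
    state["libraries"] = libraries
    state.setdefault("summary", {})["simulate"] = {
        "n_true_alleles": len(truth.true_alleles),
        "n_clones": sum(len(v) for v in libraries.values()),
        "n_chimeras": len(truth.chimera_registry),
    }


def _stage_call(run: _Run, state: dict) -> None:
    cfg = run.cfg
    if "libraries" in state:
        reads = [
            seqio.CloneRead(h.split("|")[0], ind, tpl, rep, s)
            for (ind, tpl, rep), recs in sorted(state["libraries"].items())
            for h, s in recs
        ]
    elif cfg.input_clones:
        reads = seqio.read_clone_fasta(cfg.input_clones, cfg.sample_sheet)
    else:
        raise ValueError("no clone input: enable simulate or set input_clones")
    variants = calling.collapse_identical(reads)
    clean, chimera_calls = calling.detect_chimeras(variants)
    alleles = calling.confirm_alleles(clean)
    calling.classify_expression(alleles)
    artifacts: list[seqio.Allele] = []
    if cfg.drop_artifacts:
        alleles, artifacts = calling.filter_artifacts(alleles)
    if cfg.exclude_provisional:
        alleles = [a for a in alleles if a.status == "confirmed"]
    summary = calling.summarize_individuals(alleles)

    out = run.stage_dir("call")
    seqio.write_fasta([(a.name, a.sequence) for a in alleles], out / "alleles.fasta")
    seqio.write_allele_report(alleles, out / "allele_report.tsv", cfg.config_hash())
    with open(out / "chimeras.tsv", "w") as fh:
        fh.write("variant\tparent_prefix\tparent_suffix\twindow_lo\twindow_hi\treaction\n")
        for c in chimera_calls:
            fh.write(
                f"{c.variant_sequence}\t{c.parents[0]}\t{c.parents[1]}\t"
                f"{c.breakpoint_window[0]}\t{c.breakpoint_window[1]}\t{'|'.join(c.reaction)}\n"
            )
    calling.artifact_table(clean, alleles).to_csv(out / "artifacts.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    run.record("call", *sorted(out.glob("*")))
    state["alleles"] = alleles
    state.setdefault("summary", {})["call"] = {
        "n_alleles": len(alleles),
        "n_confirmed": sum(a.status == "confirmed" for a in alleles),
        "n_chimeras_flagged": len(chimera_calls),
        "n_probable_artifacts": len(artifacts),
        **{k: summary[k] for k in ("mean", "sd", "max", "locus_lower_bound")},
    }


def _stage_annotate(run: _Run, state: dict) -> None:
    cfg = run.cfg
    alleles = _require_alleles(cfg, state)
    model = simlib.default_gene_model(cfg.seed)
    out = run.stage_dir("annotate")
    results = {}
    proteins = {}
    for a in alleles:
        stops = annotate.find_stop_codons(a.sequence)
        results[a.name] = annotate.AnnotationResult(
            segments={}, absent=[], frame_offset=0, stop_codons=stops, repeats=[]
        )
        protein = annotate.translate(a.sequence)
        if "*" not in protein:
            proteins[a.name] = protein
    landmarks = annotate.scan_cysteines(proteins)
    with open(out / "cysteine_landmarks.tsv", "w") as fh:
        fh.write("allele\tcys_positions\textra\tmissing_pairs\n")
        for name, row in landmarks.items():
            fh.write(
                f"{name}\t{','.join(map(str, row['cys_positions']))}\t"
                f"{','.join(map(str, row['extra']))}\t{','.join(row['missing_pairs'])}\n"
            )
    model.to_json(out / "gene_model.json")
    run.record("annotate", *sorted(out.glob("*")))
    state["landmarks"] = landmarks
    state.setdefault("summary", {})["annotate"] = {
        "n_translated": len(proteins),
        "n_with_stops": sum(bool(r.stop_codons) for r in results.values()),
    }


def _stage_group(run: _Run, state: dict) -> None:
    cfg = run.cfg
    alleles = _require_alleles(cfg, state)
    names = [a.name for a in alleles]
    seqs = [a.sequence for a in alleles]
    dm = grouping.pairwise_distances(names, seqs, cfg.distance_method, cfg.deletion)
    assignment = grouping.cluster_alleles(dm, cfg.cluster_cut, cfg.min_group_size)
    grouping.validate_groups(dm, assignment, cfg.n_perm, cfg.seed)
    out = run.stage_dir("group")
    grouping.write_phylip(dm, out / "distances.phy")
    grouping.write_group_table(assignment, out / "groups.tsv")
    run.record("group", *sorted(out.glob("*")))
    state["dm"] = dm
    state["assignment"] = assignment
    state.setdefault("summary", {})["group"] = {
        "n_groups": len(assignment.groups),
        "group_sizes": {g: len(assignment.members(g)) for g in assignment.groups},
        "p_values": assignment.p_values,
    }


def _stage_selection(run: _Run, state: dict) -> None:
    cfg = run.cfg
    alleles = _require_alleles(cfg, state)
    assignment = state["assignment"]
    aln = seqio.make_codon_alignment(
        [a.name for a in alleles],
        [_pad_to_codons(a.sequence) for a in alleles],
        beta1_codons=cfg.beta1_codons,
    )
    nonpseudo = [
        a.name for a in alleles if "putative_pseudogene" not in a.flags
    ]
    scopes: list[tuple[str, list[str], str]] = [("all", nonpseudo, "ng86")]
    for g in assignment.groups:
        members = [n for n in assignment.members(g) if n in nonpseudo]
        if len(members) >= 2:
            # low-divergence first group follows the two-parameter model
            scopes.append((f"group_{g}", members, "pbl" if g == "I" else "ng86"))
    rows = []
    results = {}
    for label, members, method in scopes:
        for domain in (("beta1", "beta2"), ("beta1",), ("beta2",)):
            try:
                res = selection.group_selection_test(
                    aln,
                    names=members,
                    domain=domain,
                    method=method,
                    n_bootstrap=cfg.n_bootstrap,
                    seed=cfg.seed,
                    min_shared_codons=cfg.min_shared_codons,
                    scope_label=label,
                )
            except ValueError as exc:
                run.warnings.append(f"selection {label}/{'+'.join(domain)}: {exc}")
                continue
            rows.append(res.as_row())
            results[(label, res.domain)] = res
    out = run.stage_dir("selection")
    pd.DataFrame(rows).to_csv(out / "selection_tests.tsv", sep="\t", index=False)
    run.record("selection", *sorted(out.glob("*")))
    state["selection"] = results
    overall = results.get(("all", "beta1+beta2"))
    state.setdefault("summary", {})["selection"] = (
        {
            "overall_dN": overall.dN,
            "overall_dS": overall.dS,
            "overall_omega": overall.omega,
            "p_purifying": overall.p_purifying,
            "p_positive": overall.p_positive,
        }
        if overall
        else {}
    )


def _stage_tree(run: _Run, state: dict) -> None:
    dm = state.get("dm")
    if dm is None:
        raise ValueError("tree stage needs the group stage's distance matrix")
    tree = phylo.nj_tree(dm)
    out = run.stage_dir("tree")
    phylo.write_newick(tree, out / "nj_tree.nwk")
    run.record("tree", *sorted(out.glob("*")))
    state["tree"] = tree


def _stage_tsp(run: _Run, state: dict) -> None:
    cfg = run.cfg
    alleles = _require_alleles(cfg, state)
    species_map = {a.name: "focal" for a in alleles}
    names = [a.name for a in alleles]
    seqs = [a.sequence for a in alleles]
    if cfg.species_fasta:
        for header, seq in seqio.read_fasta(cfg.species_fasta):
            tags = dict(
                kv.split("=", 1) for kv in header.split("|")[1:] if "=" in kv
            )
            name = header.split("|")[0]
            species_map[name] = tags.get("species", "foreign")
            names.append(name)
            seqs.append(seq)
    else:
        raise ValueError("tsp stage requires species_fasta comparator alleles")
    length = min(len(s) for s in seqs)
    seqs = [s[:length] for s in seqs]
    dm = grouping.pairwise_distances(names, seqs, cfg.distance_method, "pairwise")
    groups = state["assignment"].labels if "assignment" in state else None
    calls, summary = phylo.tsp_screen(dm, species_map, groups)
    out = run.stage_dir("tsp")
    phylo.write_tsp_table(calls, out / "tsp.tsv")
    run.record("tsp", *sorted(out.glob("*")))
    state.setdefault("summary", {})["tsp"] = summary


def _require_alleles(cfg: PipelineConfig, state: dict) -> list[seqio.Allele]:
    if "alleles" in state:
        return state["alleles"]
    if cfg.input_alleles:
        alleles = [
            seqio.Allele(name=h.split("|")[0].split()[0], sequence=s)
            for h, s in seqio.read_fasta(cfg.input_alleles)
        ]
        state["alleles"] = alleles
        return alleles
    raise ValueError("no alleles available: enable the call stage or set input_alleles")


def _pad_to_codons(seq: str) -> str:
    pad = (-len(seq)) % 3
    return seq + "-" * pad


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "annotate": _stage_annotate,
    "group": _stage_group,
    "selection": _stage_selection,
    "tree": _stage_tree,
    "tsp": _stage_tsp,
}


def setup_logging(verbose: bool = False, log_file: str | Path | None = None) -> None:
    """One line per stage event to stderr (and optionally a file)."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
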