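"""End-to-end "discover a family" pipeline with a reproducibility manifest.

Chains generate -> iterative search -> consensus topology -> duplication
detection -> conservation/motif analysis -> tree, writing every stage output
under one directory together with a run manifest (config snapshot, seeds,
version, per-stage output hashes).  Re-running with the same config and
seeds reproduces hash-identical stage outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .analysis import (
    column_conservation,
    find_conserved_class_columns,
    find_motif,
    nj_tree,
    pairwise_distances,
)
from .duplication import detect_duplication
from .search import SearchConfig, hits_to_tsv, iterate_search
from .seq_io import write_fasta, write_msa
from .synthetic import FamilySpec, make_proteome
from .topology import consensus_topology, predict_tm, topology_to_gff3

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "run": {"out_dir": "pqloop_run", "seed": 11},
    "generate": {
        "n_members": 20, "divergence": 0.5, "family_seed": 0,
        "n_decoys": 200, "n_half_proteins": 10,
    },
    "search": {
        "e_accept": 1e-5, "e_seed_iterate": 1e-3, "min_segment_overlap": 5,
        "require_all_segments": True, "max_iterations": 10,
        "calibration_n": 200, "seed_alignment_size": 3,
    },
    "duplication": {"n_null": 300, "e_threshold": 1e-3},
    "analysis": {"motif": "PQ", "min_score": 2.0},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        try:
            with open(path, "rb") as fh:
                user = tomllib.load(fh)
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        for section, values in user.items():
            if section not in cfg:
                raise ConfigError(f"unknown config section [{section}]")
            if not isinstance(values, dict):
                raise ConfigError(f"section [{section}] must be a table")
            for key, val in values.items():
                if key not in cfg[section]:
                    raise ConfigError(f"unknown config key {section}.{key}")
                cfg[section][key] = val
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if cfg["search"]["e_accept"] <= 0:
        raise ConfigError("search.e_accept must be positive")
    if cfg["generate"]["n_members"] < 1:
        raise ConfigError("generate.n_members must be >= 1")
    if cfg["generate"]["divergence"] < 0:
        raise ConfigError("generate.divergence must be >= 0")
    if cfg["search"]["seed_alignment_size"] < 1:
        raise ConfigError("search.seed_alignment_size must be >= 1")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version, "config": self.config,
            "outputs": self.outputs, "metrics": self.metrics,
            "timings": self.timings,
        }, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path | None = None,
                 config: dict | None = None) -> RunManifest:
    """Execute the full pipeline; returns the manifest (also written to
    ``run_manifest.json`` in the output directory)."""
    cfg = config if config is not None else load_config(config_path)
    _validate(cfg)
    out_dir = Path(cfg["run"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["run"]["seed"])
    manifest = RunManifest(config=cfg)

    def record(stage: str, path: Path, t0: float) -> None:
        manifest.outputs[path.name] = _sha256(path)
        manifest.timings[stage] = manifest.timings.get(stage, 0.0) + time.perf_counter() - t0

    # --- generate ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        g = cfg["generate"]
        spec = FamilySpec(n_members=int(g["n_members"]),
                          divergence=float(g["divergence"]),
                          seed=int(g["family_seed"]))
        proteome, truth = make_proteome(
            [spec], n_decoys=int(g["n_decoys"]),
            n_half_proteins=int(g["n_half_proteins"]), seed=seed,
        )
        fasta = out_dir / "proteome.fasta"
        write_fasta(proteome, fasta)
        truth_json = out_dir / "truth.json"
        truth_json.write_text(json.dumps({
            "membership": truth.membership,
            "tm_spans": {fid: t.tm_spans for fid, t in truth.family_truths.items()},
        }, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise StageError("generate", exc) from exc
    record("generate", fasta, t0)
    record("generate", truth_json, t0)

    # --- search ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        s = cfg["search"]
        fam_truth = truth.family_truths["fam0"]
        members = truth.family_records["fam0"]
        seed_msa = fam_truth.induced_alignment(members[: int(s["seed_alignment_size"])])
        config_obj = SearchConfig(
            e_accept=float(s["e_accept"]), e_seed_iterate=float(s["e_seed_iterate"]),
            min_segment_overlap=int(s["min_segment_overlap"]),
            require_all_segments=bool(s["require_all_segments"]),
            max_iterations=int(s["max_iterations"]),
            calibration_n=int(s["calibration_n"]),
        )
        result = iterate_search(seed_msa, proteome, config_obj, seed=seed)
        hits_path = out_dir / "hits.tsv"
        hits_path.write_text(hits_to_tsv(result.hits))
        accepted = [r for r in proteome if r.id in result.accepted_ids]
        acc_path = out_dir / "accepted.fasta"
        write_fasta(accepted, acc_path)
        sto_path = out_dir / "final.sto"
        write_msa(result.alignment, sto_path, dialect="stockholm")
    except Exception as exc:  # noqa: BLE001
        raise StageError("search", exc) from exc
    for p in (hits_path, acc_path, sto_path):
        record("search", p, t0)

    # --- topology ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        per_seq = [predict_tm(r.ungapped()) for r in result.alignment.records]
        consensus = consensus_topology(result.alignment, per_seq)
        topo_json = out_dir / "topology.json"
        topo_json.write_text(json.dumps({
            "n_helices": consensus.n_helices,
            "segments": [list(s) for s in consensus.segments],
        }, indent=2))
        gff = out_dir / "topology.gff3"
        gff.write_text(topology_to_gff3(consensus, "consensus"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("topology", exc) from exc
    record("topology", topo_json, t0)
    record("topology", gff, t0)

    # --- duplication -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        d = cfg["duplication"]
        dup = detect_duplication(result.profile, n_null=int(d["n_null"]),
                                 seed=seed, e_threshold=float(d["e_threshold"]))
        dup_json = out_dir / "duplication.json"
        dup_json.write_text(json.dumps({
            "score_bits": dup["score_bits"], "evalue": dup["evalue"],
            "verdict": dup["verdict"], "n_covered": dup["n_covered"],
        }, indent=2))
    except Exception as exc:  # noqa: BLE001
        raise StageError("duplication", exc) from exc
    record("duplication", dup_json, t0)

    # --- analysis ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        a = cfg["analysis"]
        track = column_conservation(result.alignment)
        cons_path = out_dir / "conservation.tsv"
        lines = ["column\tscore_bits\tmajority\tmajority_fraction\tgap_fraction"]
        for j, sc in enumerate(track.scores):
            lines.append(f"{j}\t{sc:.4f}\t{track.majority[j] or '-'}\t"
                         f"{track.majority_fraction[j]:.3f}\t{track.gap_fraction[j]:.3f}")
        cons_path.write_text("\n".join(lines) + "\n")
        segs = result.alignment.tm_segments or []
        loops = []
        prev = 0
        ncols = result.alignment.column_count
        for s_, e_ in segs:
            if s_ > prev:
                loops.append((prev, s_))
            prev = e_
        if prev < ncols:
            loops.append((prev, ncols))
        motifs = find_motif(result.alignment, a["motif"], loop_regions=loops)
        classes = find_conserved_class_columns(track, result.alignment,
                                               min_score=float(a["min_score"]))
        motif_json = out_dir / "motifs.json"
        motif_json.write_text(json.dumps({
            "motif": a["motif"],
            "spans": [{"columns": list(sp), "fraction": fr} for sp, fr in motifs],
            "conserved_class_columns": classes,
        }, indent=2))
        ids, D = pairwise_distances(result.alignment)
        tree_path = out_dir / "tree.nwk"
        if len(ids) >= 2:
            tree = nj_tree(D, ids)
            tree_path.write_text(tree.newick() + "\n")
        else:
            tree_path.write_text(";\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("analysis", exc) from exc
    for p in (cons_path, motif_json, tree_path):
        record("analysis", p, t0)

    # --- metrics vs truth --------------------------------------------------
    family_ids = truth.ids_in("family:fam0")
    half_ids = truth.ids_in("half:half0")
    tp = len(result.accepted_ids & family_ids)
    fp = len(result.accepted_ids - family_ids)
    manifest.metrics = {
        "accepted": len(result.accepted_ids),
        "precision": tp / max(len(result.accepted_ids), 1),
        "recall": tp / max(len(family_ids), 1),
        "false_positives": fp,
        "half_proteins_accepted": len(result.accepted_ids & half_ids),
        "consensus_n_helices": consensus.n_helices,
        "duplication_verdict": dup["verdict"],
        "converged": result.converged,
    }
    (out_dir / "run_manifest.json").write_text(manifest.to_json())
    return manifest
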