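"""End-to-end pipeline: normalize -> filter -> reconstruct -> evaluate.

A single YAML config drives a reproducible run.  Recognized keys::

    matrix: path            # required (or synthetic: {...})
    matrix_format: dense    # dense | coo
    regions: path           # optional BED-like region table
    resolution: "1MB"       # parameter preset: 1MB | 200KB
    cutoff: 0.66
    n_models: 300
    seed: 17
    max_iterations: 10000
    parameters: {dc2: 7.0, ...}     # overrides on the preset
    use_correlation: true           # compartment PCA input
    outdir: run_out

``synthetic: {n, generator, if_model, noise, seed}`` generates the input
in place of ``matrix``.  Outputs (normalized matrix, constraints summary,
ensemble JSON, representative structure TSV/PDB, evaluation report,
compartment table, manifest) land in ``outdir``; re-running the same config
reproduces them bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compartments import assign_compartments
from .evaluate import pairwise_similarity, score_structure, select_representative
from .io import read_matrix, write_ensemble, write_matrix, write_structure
from .model import default_parameters
from .normalize import apply_cutoff, normalize_matrix
from .optimize import OptimizerOptions, build_ensemble
from .synthetic import make_instance

__all__ = ["RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # stage -> path
    seeds: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def run_pipeline(config: str | Path | dict) -> RunManifest:
    """Execute the full reconstruction pipeline described by a config."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    outdir = Path(cfg.get("outdir", "chromo3d_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    seed = int(cfg.get("seed", 0))
    manifest.seeds["base"] = seed

    # -- input ---------------------------------------------------------------
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", seed)
        inst = stage("input")(lambda: make_instance(**syn))
        raw = inst.matrix
        truth_path = outdir / "truth.tsv"
        write_structure(inst.truth, truth_path, format="tsv")
        manifest.outputs["truth"] = str(truth_path)
    elif "matrix" in cfg:
        raw = stage("input")(
            lambda: read_matrix(
                cfg["matrix"],
                format=cfg.get("matrix_format", "dense"),
                regions=cfg.get("regions"),
            )
        )
        manifest.inputs[str(cfg["matrix"])] = _sha256(Path(cfg["matrix"]))
        if cfg.get("regions"):
            manifest.inputs[str(cfg["regions"])] = _sha256(Path(cfg["regions"]))
    else:
        raise ValueError("config requires 'matrix' (path) or 'synthetic' (mapping)")

    # -- normalize -----------------------------------------------------------
    N = stage("normalize")(lambda: normalize_matrix(raw))
    norm_path = outdir / "normalized.tsv"
    write_matrix(N, norm_path, format="dense")
    manifest.outputs["normalize"] = str(norm_path)

    # -- filter --------------------------------------------------------------
    cutoff = float(cfg.get("cutoff", 0.66))
    CS = stage("filter")(lambda: apply_cutoff(N, cutoff))
    cs_path = outdir / "constraints.json"
    cs_path.write_text(
        json.dumps(
            {
                "n": CS.n,
                "cutoff": CS.cutoff,
                "n_contacts": CS.n_contacts,
                "n_noncontacts": CS.n_noncontacts,
                "n_adjacent": len(CS.adjacent),
            },
            indent=1,
        )
    )
    manifest.outputs["filter"] = str(cs_path)
    logger.info(
        "filter: %d contacts, %d non-contacts, %d adjacent",
        CS.n_contacts, CS.n_noncontacts, len(CS.adjacent),
    )

    # -- reconstruct ---------------------------------------------------------
    P = default_parameters(
        str(cfg.get("resolution", "1MB")), overrides=cfg.get("parameters")
    )
    opts = OptimizerOptions(
        max_iterations=int(cfg.get("max_iterations", 10_000)), seed=seed
    )
    m = int(cfg.get("n_models", 300))
    E = stage("reconstruct")(
        lambda: build_ensemble(CS, P, opts, m=m, chrom=N.chrom, resolution=N.resolution)
    )
    ens_path = outdir / "ensemble.json"
    write_ensemble(E, ens_path)
    manifest.outputs["reconstruct"] = str(ens_path)
    manifest.seeds["ensemble"] = list(range(seed, seed + m))

    # -- select representative -----------------------------------------------
    def _select():
        if len(E) >= 2:
            sim = pairwise_similarity(E)
            return select_representative(E, sim), sim.mean_offdiagonal
        return 0, None

    rep_idx, mean_sim = stage("select")(_select)
    rep = E.structures[rep_idx]
    rep_tsv = outdir / "representative.tsv"
    rep_pdb = outdir / "representative.pdb"
    write_structure(rep, rep_tsv, format="tsv")
    write_structure(rep, rep_pdb, format="pdb")
    manifest.outputs["select"] = str(rep_tsv)

    # -- evaluate ------------------------------------------------------------
    report = stage("evaluate")(lambda: score_structure(rep, CS, P))
    report_path = outdir / "report.json"
    payload = report.to_dict()
    payload.update(
        {"representative_index": rep_idx, "ensemble_mean_gdt_ha": mean_sim}
    )
    report_path.write_text(json.dumps(payload, indent=1))
    manifest.outputs["evaluate"] = str(report_path)

    # -- compartments ----------------------------------------------------------
    def _compartments():
        A = assign_compartments(N, use_correlation=bool(cfg.get("use_correlation", True)))
        comp_path = outdir / "compartments.tsv"
        with open(comp_path, "w") as fh:
            for i, (lab, load) in enumerate(zip(A.labels, A.pc1)):
                fh.write(f"{i}\t{lab}\t{load:.17g}\n")
        return comp_path

    manifest.outputs["compartments"] = str(stage("compartments")(_compartments))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest
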