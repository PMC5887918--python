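"""End-to-end orchestration: simulate -> seqproc -> dietcore -> nullmodels -> community.

A run is driven by a single YAML config (:class:`RunConfig`).  Every
stage writes its outputs under ``out/<stage>/`` together with a content
digest of its parameters and inputs; a rerun with an unchanged digest
reuses the cached outputs (the MOTU grid search is the slow stage, and
reruns of the downstream statistics are common).  A manifest records
package version, seeds, parameters and per-stage digests, so a run is
reproducible byte for byte from its manifest.
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

import pandas as pd
import yaml

from . import __version__
from .community import accumulation_curve, bray_curtis, nmds, permanova
from .dietcore import DietMatrix, build_diet_matrix, niche_statistics, utilization_vector
from .nullmodels import overlap_null_test, selection_from_diet
from .seqproc import DEFAULT_THRESHOLD_GRID, process_reads
from .synthdata import (
    BarcodeDB,
    ItemsPerGut,
    ReadBatch,
    default_scenario,
    guts_to_frame,
    simulate_community,
    simulate_guts,
    simulate_reads,
)

logger = logging.getLogger("dietlink")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 from the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 from the CLI)."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run; round-trips through YAML."""

    seed: int = 0
    #: simulation parameters; when absent, `inputs` paths must be given
    simulate: dict[str, Any] | None = None
    #: paths: reads, mids, db, abundance, metadata (used when not simulating)
    inputs: dict[str, str] | None = None
    seqproc: dict[str, Any] = field(default_factory=dict)
    nullmodels: dict[str, Any] = field(default_factory=dict)
    community: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ConfigError("config needs either a 'simulate' block or explicit 'inputs' paths")
        if self.simulate is None:
            required = {"reads", "mids", "db", "abundance", "metadata"}
            missing = required - set(self.inputs or {})
            if missing:
                raise ConfigError(f"inputs block is missing paths: {sorted(missing)}")
            for key, path in (self.inputs or {}).items():
                if not Path(path).exists():
                    raise ConfigError(f"input path for {key!r} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _digest(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Stage:
    """Digest-keyed caching of one stage's outputs."""

    def __init__(self, out_dir: Path, name: str, key: str):
        self.dir = out_dir / name
        self.name = name
        self.key = key
        self.dir.mkdir(parents=True, exist_ok=True)
        self.marker = self.dir / ".digest"

    def cached(self, outputs: list[str]) -> bool:
        return (
            self.marker.exists()
            and self.marker.read_text().strip() == self.key
            and all((self.dir / o).exists() for o in outputs)
        )

    def commit(self) -> None:
        self.marker.write_text(self.key + "\n")


def _simulate_stage(config: RunConfig, out: Path) -> dict[str, Path]:
    p = dict(config.simulate or {})
    seed = int(p.pop("seed", config.seed))
    stage = _Stage(out, "simulate", _digest({"params": p, "seed": seed, "v": __version__}))
    outputs = ["reads.fasta", "mids.tsv", "db.fasta", "abundance.tsv", "metadata.tsv", "truth.tsv"]
    paths = {name.split(".")[0]: stage.dir / name for name in outputs}
    if stage.cached(outputs):
        logger.info("simulate: cached")
        return paths

    from .synthdata import generate_reference_db

    db = generate_reference_db(
        n_prey_taxa=int(p.get("n_prey_taxa", 12)),
        haplotypes_per_taxon=int(p.get("haplotypes_per_taxon", 2)),
        seq_length=int(p.get("seq_length", 287)),
        between_taxon_divergence=float(p.get("between_taxon_divergence", 0.10)),
        within_taxon_divergence=float(p.get("within_taxon_divergence", 0.01)),
        seed=seed,
    )
    scenario = default_scenario(
        n_sites=int(p.get("n_sites", 10)),
        n_taxa=int(p.get("n_prey_taxa", 12)),
        seasons=tuple(p.get("seasons", ("spring", "autumn"))),
        seed=seed + 1,
    )
    abundance = simulate_community(scenario, noise_dispersion=float(p.get("noise_dispersion", 5.0)), seed=seed + 2)

    items = p.get("items_per_gut", {"kind": "ztpoisson", "mean": 4.5})
    items = ItemsPerGut(**items) if isinstance(items, dict) else ItemsPerGut(kind="fixed", mean=float(items))
    weights = {str(k): float(v) for k, v in (p.get("selection_weights") or {}).items()}
    predators = list(p.get("predators", ("predatorA", "predatorB")))
    n_per = int(p.get("individuals_per_site", 5))

    guts = []
    for s_idx, ((site, season), row) in enumerate(abundance.iterrows()):
        for sp_idx, species in enumerate(predators):
            guts.extend(
                simulate_guts(
                    row,
                    species,
                    n_per,
                    items_per_gut=items,
                    selection_weights=weights,
                    seed=seed + 1000 + 7 * s_idx + sp_idx,
                    site_id=site,
                    season=season,
                )
            )
    batch = simulate_reads(
        guts,
        db,
        mid_design=tuple(p.get("mid_design", (16, 15))),
        reads_per_gut=int(p.get("reads_per_gut", 100)),
        error_rate=float(p.get("error_rate", 0.0)),
        chimera_rate=float(p.get("chimera_rate", 0.0)),
        predator_dna_fraction=float(p.get("predator_dna_fraction", 0.03)),
        contaminant_fraction=float(p.get("contaminant_fraction", 0.01)),
        seed=seed + 3,
    )
    db.to_fasta(paths["db"])
    batch.to_fasta(paths["reads"])
    batch.write_mid_map(paths["mids"])
    batch.write_truth(paths["truth"])
    abundance.to_csv(paths["abundance"], sep="\t")
    meta = pd.DataFrame(
        {
            "individual_id": [g.individual_id for g in guts],
            "predator_species": [g.predator_species for g in guts],
            "site_id": [g.site_id for g in guts],
            "season": [g.season for g in guts],
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    guts_to_frame(guts).to_csv(stage.dir / "gut_truth.tsv", sep="\t", index=False)
    stage.commit()
    logger.info("simulate: %d guts, %d reads", len(guts), len(batch.reads))
    return paths


def load_reads(reads_path: str | Path, mids_path: str | Path) -> ReadBatch:
    """Load a FASTA read set and its MID-pair registry into a ReadBatch."""
    from Bio.SeqIO import parse

    reads = [(rec.id, str(rec.seq).upper()) for rec in parse(str(reads_path), "fasta")]
    mids = pd.read_csv(mids_path, sep="\t", dtype=str)
    pairs = {(r.forward_mid, r.reverse_mid): r.individual_id for r in mids.itertuples()}
    if len(pairs) != len(mids):
        raise ConfigError("duplicate MID pair in MID map")
    return ReadBatch(reads=reads, mid_pairs=pairs, truth=pd.DataFrame())


def _seqproc_stage(config: RunConfig, out: Path, inputs: dict[str, Path]) -> Path:
    p = dict(config.seqproc)
    key = _digest(
        {
            "params": p,
            "inputs": {k: _file_digest(Path(v)) for k, v in inputs.items() if k in ("reads", "mids", "db")},
            "v": __version__,
        }
    )
    stage = _Stage(out, "seqproc", key)
    det_path = stage.dir / "detections.tsv"
    if stage.cached(["detections.tsv", "diagnostics.tsv"]):
        logger.info("seqproc: cached")
        return det_path
    batch = load_reads(inputs["reads"], inputs["mids"])
    # predator/contaminant flags recovered from the header conventions
    # of synthdata-generated references; override via seqproc config
    probe = BarcodeDB.from_fasta(inputs["db"])
    predator_taxa = p.get("predator_taxa") or [t for t in probe.taxa if t.startswith("predator")]
    contaminant_taxa = p.get("contaminant_taxa") or [t for t in probe.taxa if t.startswith("contam")]
    db = BarcodeDB.from_fasta(inputs["db"], predator_taxa=predator_taxa, contaminant_taxa=contaminant_taxa)
    grid = p.get("grid", list(DEFAULT_THRESHOLD_GRID))
    detections, t_opt, diagnostics = process_reads(
        batch,
        db,
        grid=grid,
        min_copies=int(p.get("min_copies", 2)),
        min_len=int(p.get("min_len", 260)),
        max_len=int(p.get("max_len", 300)),
        min_identity=float(p.get("min_identity", 0.98)),
        max_mismatch=int(p.get("max_mismatch", 0)),
    )
    detections.to_csv(det_path, sep="\t", index=False)
    diagnostics.to_tsv(stage.dir / "diagnostics.tsv")
    (stage.dir / "threshold.txt").write_text(f"{t_opt}\n")
    stage.commit()
    logger.info("seqproc: t_opt=%.2f, %d detections", t_opt, len(detections))
    return det_path


def _diet_stage(config: RunConfig, out: Path, det_path: Path, inputs: dict[str, Path]) -> DietMatrix:
    meta = pd.read_csv(inputs["metadata"], sep="\t", index_col="individual_id")
    detections = pd.read_csv(det_path, sep="\t")
    key = _digest({"det": _file_digest(det_path), "meta": _file_digest(Path(inputs["metadata"])), "v": __version__})
    stage = _Stage(out, "dietcore", key)
    diet_path = stage.dir / "diet.tsv"
    if stage.cached(["diet.tsv", "stats.tsv"]):
        logger.info("dietcore: cached")
        return DietMatrix.from_tsv(diet_path)
    taxa = set(detections.loc[detections["status"] == "assigned", "taxon"].dropna())
    rank_map = {t: t for t in taxa} | {sp: sp for sp in meta["predator_species"].unique()}
    diet = build_diet_matrix(detections, rank_map, meta)
    diet.to_tsv(diet_path)
    abundance = pd.read_csv(inputs["abundance"], sep="\t", index_col=["site_id", "season"])
    niche_statistics(diet, abundance).to_csv(stage.dir / "stats.tsv", sep="\t", index=False)
    stage.commit()
    logger.info("dietcore: %d individuals x %d taxa", *diet.incidence.shape)
    return diet


def _nullmodel_stage(config: RunConfig, out: Path, diet: DietMatrix, inputs: dict[str, Path]) -> None:
    p = dict(config.nullmodels)
    n_iter = int(p.get("n_iterations", 10_000))
    seed = int(p.get("seed", config.seed + 50))
    abundance = pd.read_csv(inputs["abundance"], sep="\t", index_col=["site_id", "season"])
    key = _digest({"diet": diet.incidence.to_dict(), "n_iter": n_iter, "seed": seed, "v": __version__})
    stage = _Stage(out, "nullmodels", key)
    species = sorted(diet.meta["predator_species"].unique())
    outputs = [f"selection_{sp}.tsv" for sp in species] + ["overlap.json"]
    if stage.cached(outputs):
        logger.info("nullmodels: cached")
        return
    # prey availability pooled across seasons and sites
    pooled = abundance.sum(axis=0)
    vectors = {}
    for i, sp in enumerate(species):
        sub = diet.subset(predator_species=sp)
        if sub.incidence.sum().sum() == 0:
            continue
        sel = selection_from_diet(sub, pooled, n_iterations=n_iter, seed=seed + i)
        sel.to_tsv(stage.dir / f"selection_{sp}.tsv")
        vectors[sp] = utilization_vector(sub)
    if len(vectors) == 2:
        a, b = (vectors[sp] for sp in species)
        res = overlap_null_test(a, b, n_iterations=n_iter, seed=seed + 10)
        (stage.dir / "overlap.json").write_text(
            json.dumps(
                {
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "proportion_exceeded": res.proportion_exceeded,
                    "proportion_geq": res.proportion_geq,
                    "n_iterations": res.n_iterations,
                    "seed": res.seed,
                    "algorithm": res.algorithm,
                },
                indent=2,
            )
        )
    else:
        (stage.dir / "overlap.json").write_text("{}\n")
    stage.commit()
    logger.info("nullmodels: done for %s", ", ".join(species))


def _community_stage(config: RunConfig, out: Path, diet: DietMatrix, inputs: dict[str, Path]) -> None:
    p = dict(config.community)
    seed = int(p.get("seed", config.seed + 90))
    abundance = pd.read_csv(inputs["abundance"], sep="\t", index_col=["site_id", "season"])
    key = _digest({"ab": _file_digest(Path(inputs["abundance"])), "diet": diet.incidence.to_dict(), "p": p, "seed": seed, "v": __version__})
    stage = _Stage(out, "community", key)
    if stage.cached(["nmds_scores.tsv", "accumulation.tsv"]):
        logger.info("community: cached")
        return
    d = bray_curtis(abundance, transform=p.get("transform", "fourth_root"))
    ordination = nmds(d, n_restarts=int(p.get("n_restarts", 20)), seed=seed)
    ordination.scores.assign(stress=ordination.stress).to_csv(stage.dir / "nmds_scores.tsv", sep="\t")
    curves = []
    for sp in sorted(diet.meta["predator_species"].unique()):
        sub = diet.subset(predator_species=sp)
        if sub.incidence.empty:
            continue
        curve = accumulation_curve(sub.incidence)
        curves.append(curve.to_frame().assign(predator_species=sp, chao2=curve.estimated_total_richness))
    if curves:
        pd.concat(curves).to_csv(stage.dir / "accumulation.tsv", sep="\t", index=False)
    else:
        (stage.dir / "accumulation.tsv").write_text("")
    stage.commit()
    logger.info("community: stress=%.3f", ordination.stress)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in order and return the run manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
    }
    current = "simulate"
    try:
        if config.simulate is not None:
            inputs = _simulate_stage(config, out)
        else:
            inputs = {k: Path(v) for k, v in (config.inputs or {}).items()}
        manifest["stages"].append("simulate" if config.simulate is not None else "inputs")
        current = "seqproc"
        det_path = _seqproc_stage(config, out, inputs)
        manifest["stages"].append("seqproc")
        current = "dietcore"
        diet = _diet_stage(config, out, det_path, inputs)
        manifest["stages"].append("dietcore")
        current = "nullmodels"
        _nullmodel_stage(config, out, diet, inputs)
        manifest["stages"].append("nullmodels")
        current = "community"
        _community_stage(config, out, diet, inputs)
        manifest["stages"].append("community")
    except (ConfigError,):
        raise
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        raise StageError(f"stage {current!r} failed: {exc}") from exc
    manifest["input_digests"] = {k: _file_digest(Path(v)) for k, v in inputs.items() if Path(v).is_file()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
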