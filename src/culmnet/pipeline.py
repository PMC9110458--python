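"""End-to-end workflow: preprocess -> tensor -> Tucker3 -> network -> selection.

``run_pipeline`` executes every stage from a single :class:`RunConfig`, writes
all artifacts as plain text under the output directory, and records a JSON
manifest (seed, config, input hashes, output paths) sufficient to reproduce
the run bit-identically.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .containers import ValidationError
from .network import (
    NetworkConfig,
    adjacency,
    detect_modules,
    gene_significance,
    module_eigengene,
    module_significance,
    module_trait_relation,
    pick_soft_threshold,
    tom_similarity,
)
from .preprocess import (
    build_threeway_array,
    compute_tmm_factors,
    filter_min_count,
    normalize_log,
    sample_pca,
)
from .selection import top_k_by_significance, trait_specific_candidates
from .tucker3 import (
    choose_model,
    core_contributions,
    fit_tucker3,
    model_selection_grid,
    partition_main_effects,
)

log = logging.getLogger("culmnet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All paths and settings for one end-to-end run."""

    counts_path: str
    metadata_path: str
    traits_path: str
    outdir: str
    # preprocessing
    min_count: int = 10
    min_fraction: float = 0.70
    use_tmm: bool = True
    # tucker3
    pmax: int = 3
    qmax: int = 6
    rmax: int = 3
    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 1
    elbow_epsilon: float = 0.01
    seed: int = 0
    # network
    network: NetworkConfig = field(default_factory=NetworkConfig)
    pick_power: bool = True
    # selection
    trait: str | None = None
    target_module: str | None = None
    exclude_module: str = "none"
    top_k: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        net = data.pop("network", None)
        cfg = cls(**data)
        if net:
            cfg.network = NetworkConfig(**net)
        return cfg

    def to_yaml(self, path) -> Path:
        data = dataclasses.asdict(self)
        data["network"]["candidate_powers"] = list(self.network.candidate_powers)
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return (and write) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        for key, p in (
            ("counts", config.counts_path),
            ("metadata", config.metadata_path),
            ("traits", config.traits_path),
        ):
            if not Path(p).exists():
                raise ValidationError(f"missing {key} file: {p}")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        counts = cio.read_expression(config.counts_path, "counts")
        meta = cio.read_metadata(config.metadata_path)
        traits = cio.read_traits(config.traits_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        stage("preprocess")
        filtered, removed = filter_min_count(counts, config.min_count, config.min_fraction)
        log.info("filter_min_count kept %d / %d genes", filtered.n_genes, counts.n_genes)
        factors = (
            compute_tmm_factors(filtered, relative_to_library_size=True)
            if config.use_tmm
            else None
        )
        logexpr = normalize_log(filtered, factors=factors, mode="CPM")
        manifest["outputs"]["log2cpm"] = str(cio.write_expression(logexpr, outdir / "log2cpm1.tsv"))
        scores, explained = sample_pca(logexpr, n_components=min(5, logexpr.n_samples - 1))
        pca_path = outdir / "sample_pca.tsv"
        scores.assign().to_csv(pca_path, sep="\t")
        (outdir / "sample_pca_explained.json").write_text(json.dumps(explained.tolist()))
        manifest["outputs"]["sample_pca"] = str(pca_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc

    try:
        stage("tensor")
        tensor = build_threeway_array(logexpr, meta)
        total_ss = tensor.total_ss()
    except Exception as exc:  # noqa: BLE001
        raise StageError("tensor", exc) from exc

    try:
        stage("tucker3")
        grid = model_selection_grid(
            tensor,
            Pmax=config.pmax,
            Qmax=config.qmax,
            Rmax=config.rmax,
            tol=config.tol,
            max_iter=config.max_iter,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        grid_path = outdir / "model_grid.tsv"
        grid.to_csv(grid_path, sep="\t", index=False)
        manifest["outputs"]["model_grid"] = str(grid_path)
        P, Q, R = choose_model(grid, epsilon=config.elbow_epsilon)
        log.info("chosen ranks (P, Q, R) = (%d, %d, %d)", P, Q, R)
        model = fit_tucker3(
            tensor, P, Q, R,
            tol=config.tol, max_iter=config.max_iter,
            n_restarts=config.n_restarts, seed=config.seed,
        )
        manifest["outputs"]["tucker3"] = cio.write_tucker_model(
            model, outdir / "tucker3", total_ss=total_ss
        )
        partition = partition_main_effects(model, core_contributions(model))
        part_path = outdir / "tucker3" / "main_effect_partition.tsv"
        partition.to_csv(part_path, sep="\t", index=False)
        manifest["outputs"]["main_effect_partition"] = str(part_path)
        manifest["tucker3"] = {
            "ranks": [P, Q, R],
            "explained_fraction": model.explained_fraction,
            "converged": model.converged,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("tucker3", exc) from exc

    try:
        stage("network")
        net = config.network
        if config.pick_power:
            beta, power_table = pick_soft_threshold(logexpr, net)
            power_table.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
        else:
            beta = net.power
        log.info("soft-thresholding power beta = %g", beta)
        adj = adjacency(logexpr, beta=beta)
        tom = tom_similarity(adj)
        assignment = detect_modules(tom, net, adj=adj)
        mod_path = outdir / "modules.tsv"
        assignment.labels.rename("module").to_csv(mod_path, sep="\t", index_label="gene_id")
        manifest["outputs"]["modules"] = str(mod_path)
        eig = module_eigengene(logexpr, assignment)
        eig_path = outdir / "eigengenes.tsv"
        eig.to_csv(eig_path, sep="\t", index_label="module")
        manifest["outputs"]["eigengenes"] = str(eig_path)
        mtr = module_trait_relation(eig, traits)
        mtr_path = outdir / "module_trait.tsv"
        mtr.to_csv(mtr_path, sep="\t", index=False)
        manifest["outputs"]["module_trait"] = str(mtr_path)
        manifest["network"] = {"beta": beta, "n_modules": len(assignment.modules())}
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    try:
        stage("selection")
        trait_name = config.trait or traits.columns[0]
        gs = gene_significance(logexpr, traits[trait_name])
        gs_path = outdir / "gene_significance.tsv"
        gs.to_csv(gs_path, sep="\t")
        manifest["outputs"]["gene_significance"] = str(gs_path)
        ms = module_significance(gs, assignment)
        ms.to_csv(outdir / "module_significance.tsv", sep="\t", index=False)
        top = top_k_by_significance(gs, k=min(config.top_k, len(gs)))
        top.to_csv(outdir / "top_genes.tsv", sep="\t")
        target = config.target_module
        if target is None and len(ms):
            non_grey = ms[ms["module"] != "grey"]
            if len(non_grey):
                target = non_grey.loc[non_grey["module_significance"].idxmax(), "module"]
        if target is not None:
            candidates = trait_specific_candidates(
                top, assignment, target=target, exclude=config.exclude_module, trait=trait_name
            )
            cand_path = outdir / "candidates.tsv"
            candidates.table.to_csv(cand_path, sep="\t", index=False)
            manifest["outputs"]["candidates"] = str(cand_path)
            manifest["selection"] = {
                "trait": trait_name,
                "target_module": target,
                "excluded_module": config.exclude_module,
                "n_candidates": len(candidates),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("selection", exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
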