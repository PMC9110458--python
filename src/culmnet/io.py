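"""Readers and writers for the pipeline's plain-text artifacts.

Expression matrices travel as TSV (genes in rows, header row of sample ids),
metadata and traits as CSV, Tucker3 models as a JSON manifest plus per-matrix
TSVs, ground truth as JSON + loading TSVs, and dendrograms as Newick.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError, validate_metadata
from .simulate import GroundTruth
from .tucker3 import Tucker3Model


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV with descriptive errors.

    The first column holds gene ids, the header row sample ids.  Duplicate
    ids, ragged rows and non-numeric cells raise errors naming the offender
    and its line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][-1]) + 2  # header + 1-based
        raise ValidationError(f"{path}: duplicate gene id {dup!r} (line {line})")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r} in header")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            line = int(np.where(df.index == gene)[0][0]) + 2
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} "
                f"for gene {gene!r}, sample {col!r} (line {line})"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in matrix")
    return ExpressionMatrix(df, unit)


def write_expression(expr: ExpressionMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_metadata(meta).to_csv(path, index=False)
    return path


def read_traits(path) -> pd.DataFrame:
    traits = pd.read_csv(path, index_col=0)
    if traits.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in trait table")
    return traits


def write_traits(traits: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traits.to_csv(path, index_label="sample_id")
    return path


def write_ground_truth(truth: GroundTruth, outdir) -> dict:
    """Ground truth as JSON (membership, loadings) + loading-matrix TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat in (("A_true", truth.A_true), ("B_true", truth.B_true), ("C_true", truth.C_true)):
        p = outdir / f"{name}.tsv"
        pd.DataFrame(mat).to_csv(p, sep="\t", index=False, header=False)
        paths[name] = str(p)
    core_p = outdir / "G_true.json"
    core_p.write_text(json.dumps({"shape": truth.G_true.shape, "values": truth.G_true.ravel().tolist()}))
    paths["G_true"] = str(core_p)
    meta_p = outdir / "ground_truth.json"
    meta_p.write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "module_membership": truth.module_membership,
                "trait_loadings": truth.trait_loadings,
            },
            indent=2,
        )
    )
    paths["ground_truth"] = str(meta_p)
    return paths


def write_tucker_model(model: Tucker3Model, outdir, total_ss: float | None = None) -> dict:
    """JSON manifest (ranks, fit diagnostics) + TSVs for loadings and core."""
    from .tucker3 import core_contributions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat in (("A", model.A), ("B", model.B), ("C", model.C)):
        p = outdir / f"loadings_{name}.tsv"
        pd.DataFrame(mat, columns=[f"{name}{c+1}" for c in range(mat.shape[1])]).to_csv(
            p, sep="\t", index=False
        )
        paths[name] = str(p)
    contrib = core_contributions(model, total_ss=total_ss)
    p = outdir / "core_contributions.tsv"
    contrib.to_csv(p, sep="\t", index=False)
    paths["core_contributions"] = str(p)
    manifest = {
        "ranks": list(model.ranks),
        "explained_fraction": model.explained_fraction,
        "iterations": model.iterations,
        "converged": model.converged,
        "fitted_ss": model.fitted_ss(),
    }
    mp = outdir / "model.json"
    mp.write_text(json.dumps(manifest, indent=2))
    paths["model"] = str(mp)
    return paths


def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree with branch lengths
    equal to the height drop from parent to child."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(z)

    def recurse(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def write_newick(z: np.ndarray, labels, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(linkage_to_newick(z, labels) + "\n")
    return path
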