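"""Normalization, filtering, replicate averaging and exploratory clustering.

Two pre-processing tracks feed the downstream stages:

* counts -> TMM factors -> log2(CPM + 1) -> low-count filter -> replicate
  averaging into the centred genotype x gene x internode tensor (three-way
  analysis track);
* TPM -> log2(TPM + 1) with a zero-fraction filter (co-expression track).

Boundary semantics are taken verbatim from the conventions they implement:
"at least 70%" of samples with >= 10 reads is inclusive; "more than 80%"
zeros is strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import ExpressionMatrix, ThreeWayArray, ValidationError, validate_metadata

__all__ = [
    "compute_tmm_factors",
    "normalize_log",
    "filter_min_count",
    "filter_zero_fraction",
    "build_threeway_array",
    "sample_pca",
    "ward_d_linkage",
    "expression_dendrogram",
    "autoscale_traits",
]


def compute_tmm_factors(
    counts: ExpressionMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    relative_to_library_size: bool = False,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose upper quartile is closest to the mean
    upper quartile.  For each sample, gene-wise M (log-ratio) and A (average
    log abundance) values against the reference are computed on genes with
    non-zero counts in both libraries; the most extreme ``logratio_trim``
    share of M and ``sum_trim`` share of A are trimmed from both tails, and
    the factor is 2 to the precision-weighted mean of the remaining M values.
    Factors are then normalized to geometric mean 1.

    By default M values are computed on raw counts, so for scaled copies of
    one library the factors recover the scaling ratios exactly.  With
    ``relative_to_library_size=True`` counts are first divided by library
    size (edgeR's convention, factors multiplying library sizes).
    """
    if counts.unit != "counts":
        raise ValidationError(f"TMM needs raw counts, got unit {counts.unit!r}")
    if counts.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    y = counts.values.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        names = counts.sample_ids[zero].tolist()
        raise ValidationError(f"all-zero sample(s): {names}")

    # reference: upper quartile of library-scaled counts closest to the mean
    uq = np.array([np.quantile(y[:, s] / lib[s], 0.75) for s in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    scale = lib if relative_to_library_size else np.ones_like(lib)
    factors = np.ones(y.shape[1])
    for s in range(y.shape[1]):
        if s == ref:
            factors[s] = 1.0
            continue
        ys, yr = y[:, s], y[:, ref]
        keep = (ys > 0) & (yr > 0)
        if not keep.any():
            factors[s] = 1.0
            continue
        ps, pr = ys[keep] / scale[s], yr[keep] / scale[ref]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = (lib[s] - ys[keep]) / (lib[s] * ys[keep]) + (lib[ref] - yr[keep]) / (
            lib[ref] * yr[keep]
        )
        n = M.size
        if np.max(np.abs(M)) < 1e-6:
            factors[s] = 1.0
            continue
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rm, ra = rankdata(M), rankdata(A)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not kept.any():
            factors[s] = 1.0
            continue
        inv_w = 1.0 / w[kept]
        factors[s] = 2.0 ** (np.sum(inv_w * M[kept]) / np.sum(inv_w))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def normalize_log(
    expr: ExpressionMatrix, factors: pd.Series | None = None, mode: str = "CPM"
) -> ExpressionMatrix:
    """log2(CPM + 1) or log2(TPM + 1) transform.

    CPM mode scales counts by library size (times the TMM factor when given)
    per million; TPM mode passes the values through scaling-free.
    """
    vals = expr.values
    if (vals.to_numpy() < 0).any():
        raise ValidationError("negative expression values")
    if mode == "CPM":
        if expr.unit != "counts":
            raise ValidationError(f"CPM mode needs counts, got {expr.unit!r}")
        lib = vals.sum(axis=0)
        if factors is not None:
            lib = lib * factors.reindex(vals.columns)
        cpm = vals.div(lib, axis=1) * 1e6
        return ExpressionMatrix(np.log2(cpm + 1.0), "log2CPM1")
    if mode == "TPM":
        if expr.unit != "TPM":
            raise ValidationError(f"TPM mode needs TPM, got {expr.unit!r}")
        return ExpressionMatrix(np.log2(vals + 1.0), "log2TPM1")
    raise ValidationError(f"unknown mode {mode!r}")


def filter_min_count(
    counts: ExpressionMatrix, min_count: int = 10, min_fraction: float = 0.70
):
    """Keep genes with >= min_count reads in at least min_fraction of samples.

    The boundary is inclusive: a gene meeting the fraction exactly is kept.
    Returns the filtered matrix and the index of removed genes.
    """
    if counts.unit != "counts":
        raise ValidationError(f"count filter needs counts, got {counts.unit!r}")
    if not (0.0 < min_fraction <= 1.0):
        raise ValidationError("min_fraction must be in (0, 1]")
    frac = (counts.values >= min_count).sum(axis=1) / counts.n_samples
    keep = frac >= min_fraction
    removed = counts.gene_ids[~keep]
    return ExpressionMatrix(counts.values.loc[keep], counts.unit), removed


def filter_zero_fraction(expr: ExpressionMatrix, max_zero_fraction: float = 0.80):
    """Remove genes whose zero fraction strictly exceeds the threshold.

    "More than 80%" is strict: a gene with exactly 80% zeros is kept.
    """
    if not (0.0 <= max_zero_fraction <= 1.0):
        raise ValidationError("max_zero_fraction must be in [0, 1]")
    frac = (expr.values == 0).sum(axis=1) / expr.n_samples
    keep = frac <= max_zero_fraction
    removed = expr.gene_ids[~keep]
    return ExpressionMatrix(expr.values.loc[keep], expr.unit), removed


def build_threeway_array(expr: ExpressionMatrix, meta: pd.DataFrame) -> ThreeWayArray:
    """Replicate-average into a genotype x gene x internode array, then centre
    each gene to grand mean zero over all I x K cells ("centred, not scaled").
    """
    if expr.unit not in ("log2CPM1", "log2TPM1"):
        raise ValidationError(f"tensor needs log2CPM1/log2TPM1 values, got {expr.unit!r}")
    meta = validate_metadata(meta)
    missing = set(meta["sample_id"]) - set(expr.sample_ids)
    if missing:
        raise ValidationError(f"metadata samples absent from matrix: {sorted(missing)[:5]}")
    genotypes = list(dict.fromkeys(meta["genotype"]))
    internodes = list(dict.fromkeys(meta["internode"]))
    I, J, K = len(genotypes), expr.n_genes, len(internodes)

    cells = meta.groupby(["genotype", "internode"], sort=False)["sample_id"].apply(list)
    missing_cells = [
        (g, k) for g in genotypes for k in internodes if (g, k) not in cells.index
    ]
    if missing_cells:
        raise ValidationError(f"missing (genotype, internode) cells: {missing_cells}")

    arr = np.empty((I, J, K))
    for i, g in enumerate(genotypes):
        for k, n in enumerate(internodes):
            arr[i, :, k] = expr.values[cells[(g, n)]].mean(axis=1).to_numpy()
    arr -= arr.mean(axis=(0, 2), keepdims=True)
    return ThreeWayArray(
        values=arr,
        genotype_ids=genotypes,
        gene_ids=list(expr.gene_ids),
        internode_ids=internodes,
        centering="per-gene grand mean over all I x K cells",
    )


def sample_pca(expr: ExpressionMatrix, n_components: int = 2):
    """Sample scores on the leading principal components of gene-centred data.

    Returns a (samples x components) score table and the explained-variance
    fractions (non-increasing, summing to <= 1).
    """
    if expr.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if n_components > min(expr.n_samples, expr.n_genes):
        raise ValidationError(
            f"n_components={n_components} exceeds min dimension "
            f"{min(expr.n_samples, expr.n_genes)}"
        )
    x = expr.values.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    # deterministic sign: largest-magnitude score positive
    for c in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, c])))
        if scores[j, c] < 0:
            scores[:, c] = -scores[:, c]
    explained = (s**2) / max(float(np.sum(s**2)), np.finfo(float).tiny)
    table = pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{c+1}" for c in range(n_components)]
    )
    return table, explained[:n_components]


def ward_d_linkage(dist: np.ndarray) -> np.ndarray:
    """Classical ward.D linkage on a condensed or square dissimilarity matrix.

    ward.D applies the Ward update to the supplied dissimilarities without
    squaring them first; it equals ward.D2 on the square roots with heights
    squared, which is how it is computed here.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    if np.any(d < 0):
        raise ValidationError("dissimilarities must be non-negative")
    z = hierarchy.linkage(np.sqrt(d), method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2
    return z


def expression_dendrogram(
    expr: ExpressionMatrix,
    meta: pd.DataFrame | None = None,
    transform: str = "passthrough",
    linkage: str = "ward",
    distance: str = "euclidean",
):
    """Hierarchical (ward.D, Euclidean) clustering of expression profiles.

    ``transform="log10_mean_tpm1"`` averages TPM over the replicates of each
    (genotype, internode) cell and clusters log10(mean TPM + 1) profiles (a
    global sign flip leaves Euclidean distances unchanged);
    ``"passthrough"`` clusters the sample columns as given.  Leaves are
    ordered by id before clustering so ties break deterministically.
    Returns (linkage matrix with ward.D heights, leaf labels).
    """
    if linkage != "ward" or distance != "euclidean":
        raise ValidationError("only ward linkage on Euclidean distance is supported")
    if transform == "log10_mean_tpm1":
        if expr.unit != "TPM":
            raise ValidationError("log10_mean_tpm1 transform needs TPM values")
        if meta is None:
            raise ValidationError("metadata required for genotype x stage averaging")
        meta = validate_metadata(meta)
        groups = meta.groupby(["genotype", "internode"], sort=False)["sample_id"].apply(list)
        profiles = pd.DataFrame(
            {f"{g}|{k}": expr.values[s].mean(axis=1) for (g, k), s in groups.items()}
        )
        profiles = np.log10(profiles + 1.0)
    elif transform == "passthrough":
        if expr.unit not in ("log2CPM1", "log2TPM1"):
            raise ValidationError("passthrough transform expects log-scale values")
        profiles = expr.values
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    labels = sorted(profiles.columns)
    if len(labels) < 2:
        raise ValidationError("dendrogram needs at least 2 leaves")
    mat = profiles[labels].to_numpy().T  # leaves x features
    z = ward_d_linkage(pdist(mat, metric="euclidean"))
    return z, labels


def autoscale_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Auto-scale (z-score) each trait column to mean 0, sample SD 1."""
    out = {}
    for col in traits.columns:
        v = pd.to_numeric(traits[col], errors="raise")
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"constant trait column: {col!r}")
        out[col] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=traits.index)
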