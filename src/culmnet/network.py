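"""Weighted co-expression network analysis, from scratch.

Unsigned adjacency a_ij = |cor(g_i, g_j)|^beta, topological overlap
smoothing, module detection by ward.D clustering of 1 - TOM with a static
height search and a minimum module size, module eigengenes, and module /
gene trait statistics.  The grey label is reserved for unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ValidationError
from .preprocess import ward_d_linkage

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "MODULE_PALETTE",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_relation",
    "gene_significance",
    "module_significance",
]

#: Deterministic colour sequence for module labels, assigned in decreasing
#: size order. "grey" is reserved for unassigned genes.
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)

GREY = "grey"

DEFAULT_CANDIDATE_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class NetworkConfig:
    power: float = 4.0
    network_type: str = "unsigned"
    min_module_size: int = 500
    correlation: str = "pearson"
    linkage: str = "ward"
    candidate_powers: tuple = DEFAULT_CANDIDATE_POWERS
    target_r2: float = 0.80
    #: a branch is module-eligible only when its mean internal topological
    #: overlap is at least this multiple of the matrix-wide mean (keeps pure
    #: noise branches grey regardless of their size)
    min_relative_overlap: float = 2.0

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.min_relative_overlap < 1:
            raise ValidationError("min_relative_overlap must be >= 1")
        if self.network_type != "unsigned":
            raise ValidationError("only unsigned networks are implemented")
        if self.correlation != "pearson":
            raise ValidationError("only Pearson correlation is implemented")
        if not (0.0 < self.target_r2 <= 1.0):
            raise ValidationError("target_r2 must be in (0, 1]")


@dataclass
class ModuleAssignment:
    """Gene -> module colour labels; non-grey modules meet the minimum size."""

    labels: pd.Series
    min_module_size: int
    cut_height: float = np.nan
    linkage: np.ndarray | None = None

    def modules(self, include_grey: bool = False) -> list:
        sizes = self.labels.value_counts()
        mods = [m for m in sizes.index if m != GREY]
        # palette order == decreasing size order by construction
        mods.sort(key=lambda m: (-sizes[m], m))
        if include_grey and (self.labels == GREY).any():
            mods.append(GREY)
        return mods

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def _check_variance(expr: ExpressionMatrix) -> np.ndarray:
    x = expr.values.to_numpy(dtype=float)
    var = x.var(axis=1)
    bad = np.where(var == 0)[0]
    if bad.size:
        names = expr.gene_ids[bad].tolist()
        raise ValidationError(f"zero-variance gene(s): {names[:10]}")
    return x


def adjacency(expr: ExpressionMatrix, beta: float = 4.0, network_type: str = "unsigned") -> pd.DataFrame:
    """Unsigned weighted adjacency |Pearson r|^beta with a zero diagonal."""
    if network_type != "unsigned":
        raise ValidationError("only unsigned networks are implemented")
    x = _check_variance(expr)
    r = np.corrcoef(x)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.gene_ids, columns=expr.gene_ids)


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed scale-free topology fit of a connectivity vector.

    Discretizes k into ``n_bins`` equal-width bins, regresses log10(mean
    frequency) on log10(mean k) over non-empty bins, and signs the R^2 by the
    slope (negative slope, the scale-free direction, gives a positive value).
    Returns (signed_r2, slope, degenerate_flag).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) <= 1e-10 * k.max():
        return np.nan, np.nan, True
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_k.append(k[sel].mean())
            freq.append(sel.mean())
    if len(mean_k) < 3:
        return np.nan, np.nan, True
    lx, ly = np.log10(mean_k), np.log10(freq)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return np.nan, np.nan, True
    res = stats.linregress(lx, ly)
    return -np.sign(res.slope) * res.rvalue**2, float(res.slope), False


def pick_soft_threshold(expr: ExpressionMatrix, config: NetworkConfig | None = None):
    """Choose the soft-thresholding power by the scale-free topology criterion.

    For each candidate power, the connectivity k_i = sum_j a_ij is computed
    and its distribution's log-log linearity scored; the chosen beta is the
    smallest power whose signed R^2 reaches ``target_r2``, falling back to
    the argmax when none does.
    """
    config = config or NetworkConfig()
    if expr.n_genes < 3:
        raise ValidationError("need at least 3 genes")
    if expr.n_samples < 4:
        raise ValidationError("need at least 4 samples")
    x = _check_variance(expr)
    absr = np.abs(np.clip(np.corrcoef(x), -1.0, 1.0))
    np.fill_diagonal(absr, 0.0)
    rows = []
    for p in config.candidate_powers:
        k = (absr**p).sum(axis=1)
        r2, slope, degenerate = scale_free_fit(k)
        rows.append(
            {
                "power": p,
                "signed_r2": r2,
                "slope": slope,
                "degenerate": degenerate,
                "mean_k": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[~table["degenerate"] & (table["signed_r2"] >= config.target_r2)]
    if len(ok):
        beta = float(ok["power"].iloc[0])
    elif table["signed_r2"].notna().any():
        beta = float(table.loc[table["signed_r2"].idxmax(), "power"])
    else:
        beta = float(config.power)
    return beta, table


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with l = A @ A; the diagonal is reported as 1."""
    a = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be 0")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    l = a @ a
    tom = (l + a) / (np.minimum.outer(k, k) + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def detect_modules(
    tom: pd.DataFrame,
    config: NetworkConfig | None = None,
    adj: pd.DataFrame | None = None,
) -> ModuleAssignment:
    """Cluster genes on 1 - TOM with ward.D linkage and a static height cut.

    The cut height is searched over the tree's merge heights.  Branches of at
    least ``min_module_size`` genes whose mean internal cohesion reaches
    ``min_relative_overlap`` times the matrix-wide mean are module
    candidates; each candidate height is scored by the summed within-branch
    cohesion of its active candidates in excess of the matrix-wide
    expectation, and the best-scoring height (lowest on ties) defines the
    modules, named from a fixed colour palette in decreasing size order;
    everything else is grey.

    Cohesion is measured on the soft-thresholded adjacency when ``adj`` is
    given (recommended: the power transform is what suppresses diffuse
    background correlation), falling back to the TOM itself otherwise.  A
    bare count of minimum-size branches rewards heights that shred correlated
    background into fragments, and ward merge heights grow with cluster size,
    so neither raw counts nor height gaps identify the natural cut; the
    excess-cohesion score favours branches kept whole.
    """
    config = config or NetworkConfig()
    if not isinstance(tom, pd.DataFrame):
        raise ValidationError("tom must be a DataFrame with gene ids")
    genes = tom.index
    n = len(genes)
    if n < config.min_module_size:
        warnings.warn(
            f"only {n} genes for min_module_size={config.min_module_size}; all grey",
            stacklevel=2,
        )
        return ModuleAssignment(
            labels=pd.Series(GREY, index=genes), min_module_size=config.min_module_size
        )
    t = tom.to_numpy(dtype=float).copy()
    np.fill_diagonal(t, 0.0)
    diss = 1.0 - t
    np.fill_diagonal(diss, 0.0)
    z = ward_d_linkage(squareform(diss, checks=False))

    if adj is not None:
        coh = adj.to_numpy(dtype=float).copy() if isinstance(adj, pd.DataFrame) else np.array(adj, float)
        if coh.shape != t.shape:
            raise ValidationError("adjacency and TOM shapes differ")
        np.fill_diagonal(coh, 0.0)
    else:
        coh = t
    coh_mean = coh.sum() / (n * (n - 1))

    # bottom-up per node: member leaves, within-branch cohesion, parent height
    n_nodes = z.shape[0]
    members: list = [np.array([i]) for i in range(n)] + [None] * n_nodes
    coh_to_branch: list = [coh[:, i].copy() for i in range(n)] + [None] * n_nodes
    within: np.ndarray = np.zeros(n + n_nodes)
    parent_height = np.full(n + n_nodes, np.inf)
    heights = np.concatenate([np.zeros(n), z[:, 2]])
    for row in range(n_nodes):
        a, b = int(z[row, 0]), int(z[row, 1])
        members[n + row] = np.concatenate([members[a], members[b]])
        cross = float(coh_to_branch[a][members[b]].sum())
        within[n + row] = within[a] + within[b] + 2.0 * cross
        coh_to_branch[n + row] = coh_to_branch[a] + coh_to_branch[b]
        coh_to_branch[a] = coh_to_branch[b] = None
        parent_height[a] = parent_height[b] = z[row, 2]

    sizes = np.array([len(members[node]) for node in range(n, n + n_nodes)])
    pairs = sizes * (sizes - 1)
    w_all = within[n:] - coh_mean * pairs
    eligible = (sizes >= config.min_module_size) & (
        within[n:] >= config.min_relative_overlap * coh_mean * pairs
    )
    if coh_mean == 0.0:  # fully disconnected network: nothing co-expressed
        eligible &= False
    if not eligible.any():
        return ModuleAssignment(
            labels=pd.Series(GREY, index=genes),
            min_module_size=config.min_module_size,
            linkage=z,
        )

    # each candidate is active for cut heights in [own height, parent height)
    cand = np.flatnonzero(eligible)
    lo = heights[n:][cand]
    hi = parent_height[n:][cand]
    w = w_all[cand]
    cut_points = np.unique(z[:, 2])
    best_height, best_score = np.nan, -np.inf
    for h in cut_points:
        score = float(w[(lo <= h) & (h < hi)].sum())
        if score > best_score:
            best_height, best_score = float(h), score
    active_mask = (lo <= best_height) & (best_height < hi)
    best_active = [n + int(c) for c in cand[active_mask]]
    best_active.sort(key=lambda c: (-len(members[c]), c))

    labels = pd.Series(GREY, index=genes)
    gene_arr = np.asarray(genes)
    for rank, node in enumerate(best_active):
        name = MODULE_PALETTE[rank] if rank < len(MODULE_PALETTE) else f"module_{rank + 1}"
        labels[gene_arr[np.sort(members[node])]] = name
    return ModuleAssignment(
        labels=labels,
        min_module_size=config.min_module_size,
        cut_height=best_height,
        linkage=z,
    )


def module_eigengene(expr: ExpressionMatrix, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's gene-standardized expression.

    Eigengenes are unit-norm over samples and sign-fixed so each correlates
    non-negatively with the module's mean expression profile.  Grey is
    excluded.  Returns a module x sample table.
    """
    out = {}
    for mod in assignment.modules():
        genes = assignment.genes_in(mod)
        sub = expr.values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        if np.all(sd == 0):
            raise ValidationError(f"degenerate module {mod!r}: no gene with variance > 0")
        keep = sd > 0
        z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        out[mod] = me
    if not out:
        raise ValidationError("no non-grey modules to summarize")
    return pd.DataFrame(out, index=expr.sample_ids).T


def _pearson_with_p(x: np.ndarray, y: np.ndarray):
    """Row-wise Pearson r of x (m x n) against y (n,), with exact-t p-values."""
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    if np.any(denom == 0):
        raise ValidationError("zero-variance profile in correlation")
    r = np.clip(xc @ yc / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return r, p


def module_trait_relation(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation (with exact-t p-value) of each module eigengene
    with each trait over the shared samples."""
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 4:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 4")
    me = eigengenes[shared].to_numpy(dtype=float)
    rows = []
    for trait in traits.columns:
        y = traits.loc[shared, trait].to_numpy(dtype=float)
        if y.std() == 0:
            raise ValidationError(f"constant trait {trait!r}")
        r, p = _pearson_with_p(me, y)
        for mod, ri, pi in zip(eigengenes.index, r, p):
            rows.append({"module": mod, "trait": trait, "r": float(ri), "p": float(pi)})
    return pd.DataFrame(rows)


def gene_significance(
    expr: ExpressionMatrix, trait: pd.Series, trait_name: str | None = None
) -> pd.DataFrame:
    """Per-gene signed trait correlation, absolute gene significance GS = |r|
    and exact-t p-value."""
    name = trait_name or (trait.name if trait.name is not None else "trait")
    shared = [s for s in expr.sample_ids if s in trait.index]
    if len(shared) < 4:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 4")
    y = trait.loc[shared].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValidationError(f"constant trait {name!r}")
    x = expr.values[shared].to_numpy(dtype=float)
    r, p = _pearson_with_p(x, y)
    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "trait": name,
            "r": r,
            "GS": np.abs(r),
            "p": p,
        }
    ).set_index("gene")


def module_significance(gs: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """Module significance: the mean absolute gene significance over the
    module's genes (grey reported alongside the colour modules)."""
    rows = []
    for mod in assignment.modules(include_grey=True):
        genes = assignment.genes_in(mod)
        genes = [g for g in genes if g in gs.index]
        if not genes:
            warnings.warn(f"module {mod!r} has no genes with significance values", stacklevel=2)
            continue
        rows.append(
            {
                "module": mod,
                "module_significance": float(gs.loc[genes, "GS"].mean()),
                "n_genes": len(genes),
            }
        )
    return pd.DataFrame(rows)
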