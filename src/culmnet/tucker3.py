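"""Tucker3 (three-way PCA) decomposition of an expression tensor.

The model writes each entry of a centred genotype x gene x internode array as

    x_ijk = sum_p sum_q sum_r  a_ip * b_jq * c_kr * g_pqr  +  e_ijk

with orthonormal loading matrices A (I x P, genotypes), B (J x Q, genes),
C (K x R, internodes) and a dense core array G (P x Q x R) whose squared
entries partition the fitted sum of squares among component triples.

Fitting is alternating least squares with orthonormal mode updates
(TUCKALS3): each sweep replaces one mode's loadings by the leading left
singular vectors of the unfolded tensor projected onto the other two modes,
then recomputes the core.  Initialisation is the higher-order SVD by default,
with optional random-orthonormal restarts.

Unfolding convention (fixed so cores are byte-reproducible): mode-n rows
index mode n, and the remaining modes order the columns with the *lower*
mode varying fastest (mode-1: columns (j, k) with j fastest, i.e. k-major).
Under this convention  X_(1) = A G_(1) (C (x) B)^T  and likewise for the
other modes with the Kronecker factors in decreasing-mode order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ThreeWayArray, ValidationError

__all__ = [
    "Tucker3Model",
    "unfold",
    "refold",
    "hosvd_init",
    "fit_tucker3",
    "tucker_reconstruct",
    "explained_variance",
    "core_contributions",
    "model_selection_grid",
    "choose_model",
    "partition_main_effects",
]


@dataclass
class Tucker3Model:
    """Fitted Tucker3 model: loadings, core and convergence diagnostics."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    explained_fraction: float
    iterations: int
    converged: bool
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def ranks(self) -> tuple:
        return self.G.shape

    def fitted_ss(self) -> float:
        return float(np.sum(self.G**2))


def _as_array(tensor) -> np.ndarray:
    if isinstance(tensor, ThreeWayArray):
        return tensor.values
    return np.asarray(tensor, dtype=float)


def unfold(tensor, mode: int) -> np.ndarray:
    """Mode-n matricisation (modes numbered 1..3).

    Rows index the chosen mode; columns run over the remaining modes with the
    lower mode varying fastest.
    """
    x = _as_array(tensor)
    if mode not in (1, 2, 3):
        raise ValidationError(f"mode must be 1, 2 or 3, got {mode}")
    n = mode - 1
    return np.reshape(np.moveaxis(x, n, 0), (x.shape[n], -1), order="F")


def refold(mat: np.ndarray, mode: int, shape: tuple) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    if mode not in (1, 2, 3):
        raise ValidationError(f"mode must be 1, 2 or 3, got {mode}")
    n = mode - 1
    rest = [s for i, s in enumerate(shape) if i != n]
    x = np.reshape(np.asarray(mat, dtype=float), (shape[n], *rest), order="F")
    return np.moveaxis(x, 0, n)


def _mode_product(x: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """Multiply tensor x along one mode by a matrix (rows of mat contract)."""
    shape = list(x.shape)
    shape[mode - 1] = mat.shape[0]
    return refold(mat @ unfold(x, mode), mode, tuple(shape))


def tucker_reconstruct(A: np.ndarray, B: np.ndarray, C: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Dense reconstruction  X_hat = G x1 A x2 B x3 C."""
    return np.einsum("ip,jq,kr,pqr->ijk", A, B, C, G, optimize=True)


def _check_ranks(shape: tuple, P: int, Q: int, R: int) -> None:
    I, J, K = shape
    for r, d, name in ((P, I, "P"), (Q, J, "Q"), (R, K, "R")):
        if not (1 <= r <= d):
            raise ValidationError(f"rank {name}={r} outside [1, {d}]")


def _leading_left_singular(mat: np.ndarray, k: int) -> np.ndarray:
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    return u[:, :k]


def hosvd_init(tensor, P: int, Q: int, R: int):
    """Higher-order SVD initialisation: leading left singular vectors of each
    unfolding.  Columns are orthonormal."""
    x = _as_array(tensor)
    _check_ranks(x.shape, P, Q, R)
    A0 = _leading_left_singular(unfold(x, 1), P)
    B0 = _leading_left_singular(unfold(x, 2), Q)
    C0 = _leading_left_singular(unfold(x, 3), R)
    return A0, B0, C0


def _core(x: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.einsum("ijk,ip,jq,kr->pqr", x, A, B, C, optimize=True)


def _fix_signs(A: np.ndarray, B: np.ndarray, C: np.ndarray, G: np.ndarray):
    """Flip each loading column so its largest-magnitude entry is positive,
    compensating in the core so the reconstruction is unchanged."""
    mats = [A.copy(), B.copy(), C.copy()]
    G = G.copy()
    for m, mat in enumerate(mats):
        for col in range(mat.shape[1]):
            j = int(np.argmax(np.abs(mat[:, col])))
            if mat[j, col] < 0:
                mat[:, col] = -mat[:, col]
                idx = [slice(None)] * 3
                idx[m] = col
                G[tuple(idx)] = -G[tuple(idx)]
    return mats[0], mats[1], mats[2], G


def _random_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q[:, :k]


def fit_tucker3(
    tensor,
    P: int,
    Q: int,
    R: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 1,
    seed: int | None = 0,
) -> Tucker3Model:
    """Fit the Tucker3 model by orthonormal alternating least squares.

    The first start uses the HOSVD initialisation; any additional restarts use
    random orthonormal loadings drawn from ``seed``.  The best fit (largest
    fitted sum of squares) over restarts is returned.  Convergence is declared
    when the relative change of the fitted SS falls below ``tol``; hitting
    ``max_iter`` flags ``converged=False`` rather than raising.
    """
    x = _as_array(tensor)
    _check_ranks(x.shape, P, Q, R)
    total_ss = float(np.sum(x**2))
    if total_ss == 0.0:
        raise ValidationError("tensor has zero sum of squares")
    rng = np.random.default_rng(seed)

    best: Tucker3Model | None = None
    for start in range(max(1, n_restarts)):
        if start == 0:
            A, B, C = hosvd_init(x, P, Q, R)
        else:
            A = _random_orthonormal(rng, x.shape[0], P)
            B = _random_orthonormal(rng, x.shape[1], Q)
            C = _random_orthonormal(rng, x.shape[2], R)

        fitted = float(np.sum(_core(x, A, B, C) ** 2))
        trace = [fitted]
        converged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            # one sweep: SVD-based update of each mode in turn
            A = _leading_left_singular(
                unfold(np.einsum("ijk,jq,kr->iqr", x, B, C, optimize=True), 1), P
            )
            B = _leading_left_singular(
                unfold(np.einsum("ijk,ip,kr->pjr", x, A, C, optimize=True), 2), Q
            )
            C = _leading_left_singular(
                unfold(np.einsum("ijk,ip,jq->pqk", x, A, B, optimize=True), 3), R
            )
            new_fitted = float(np.sum(_core(x, A, B, C) ** 2))
            trace.append(new_fitted)
            if abs(new_fitted - fitted) <= tol * max(fitted, np.finfo(float).tiny):
                fitted = new_fitted
                converged = True
                break
            fitted = new_fitted

        G = _core(x, A, B, C)
        A, B, C, G = _fix_signs(A, B, C, G)
        model = Tucker3Model(
            A=A,
            B=B,
            C=C,
            G=G,
            explained_fraction=float(np.sum(G**2)) / total_ss,
            iterations=iterations,
            converged=converged,
            # loss = residual SS, non-increasing along the sweeps
            loss_trace=total_ss - np.asarray(trace),
        )
        if best is None or model.fitted_ss() > best.fitted_ss():
            best = model
    assert best is not None
    return best


def explained_variance(model: Tucker3Model, tensor) -> float:
    """1 - ||X - X_hat||^2 / ||X||^2 for the model's reconstruction."""
    x = _as_array(tensor)
    if x.shape != (model.A.shape[0], model.B.shape[0], model.C.shape[0]):
        raise ValidationError("tensor shape does not match model loadings")
    total_ss = float(np.sum(x**2))
    if total_ss == 0.0:
        raise ValidationError("tensor has zero sum of squares")
    resid = x - tucker_reconstruct(model.A, model.B, model.C, model.G)
    return 1.0 - float(np.sum(resid**2)) / total_ss


def core_contributions(model: Tucker3Model, total_ss: float | None = None) -> pd.DataFrame:
    """Per core-element variance shares, sorted by descending fitted share.

    Columns: p, q, r (1-based), g, fitted_share (g^2 / sum g^2) and, when the
    tensor's total SS is given, total_share (g^2 / ||X||^2).
    """
    G = model.G
    fitted_ss = float(np.sum(G**2))
    rows = []
    for (p, q, r), g in np.ndenumerate(G):
        row = {
            "p": p + 1,
            "q": q + 1,
            "r": r + 1,
            "g": float(g),
            "fitted_share": float(g**2) / fitted_ss if fitted_ss > 0 else np.nan,
        }
        if total_ss is not None:
            row["total_share"] = float(g**2) / total_ss
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["fitted_share", "p", "q", "r"], ascending=[False, True, True, True]
    )
    return table.reset_index(drop=True)


def model_selection_grid(
    tensor,
    Pmax: int = 5,
    Qmax: int = 20,
    Rmax: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 1,
    seed: int | None = 0,
    fit_fn=None,
) -> pd.DataFrame:
    """Fit every rank combination (P, Q, R) in [1..Pmax] x [1..Qmax] x [1..Rmax].

    Returns one row per combination with the explained fraction, so a scree
    plot over the total number of components S = P + Q + R can be inspected.
    ``fit_fn(tensor, P, Q, R) -> explained fraction`` may be injected (e.g. for
    enumeration tests); the default runs :func:`fit_tucker3`.
    """
    x = _as_array(tensor)
    I, J, K = x.shape
    if Pmax > I or Qmax > J or Rmax > K:
        raise ValidationError(
            f"grid maxima ({Pmax},{Qmax},{Rmax}) exceed tensor dimensions {(I, J, K)}"
        )
    if fit_fn is None:

        def fit_fn(t, P, Q, R):  # noqa: ANN001
            return fit_tucker3(
                t, P, Q, R, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
            ).explained_fraction

    rows = []
    for P, Q, R in itertools.product(range(1, Pmax + 1), range(1, Qmax + 1), range(1, Rmax + 1)):
        rows.append(
            {
                "P": P,
                "Q": Q,
                "R": R,
                "total_components": P + Q + R,
                "explained_fraction": float(fit_fn(x, P, Q, R)),
                "restarts": n_restarts,
            }
        )
    return pd.DataFrame(rows)


def choose_model(grid: pd.DataFrame, rule: str = "elbow", epsilon: float = 0.01, manual=None):
    """Automated stand-in for scree-plot inspection.

    ``elbow`` (default): order candidates by total components S = P + Q + R;
    among the per-S best (Pareto-optimal) models, pick the smallest S whose
    remaining achievable gain — the best explained fraction at any larger S
    minus the fraction at S — is below ``epsilon``.  (Consecutive-S gains are
    unusable here: growing one mode's rank in isolation often gains nothing
    until the matching ranks of the other modes follow, so the explained
    curve is a staircase with flat steps before its jumps.)  Ties within an S
    break lexicographically on (P, Q, R).  ``manual`` passes through the
    given ranks.
    """
    if grid is None or len(grid) == 0:
        raise ValidationError("empty model grid")
    if rule == "manual":
        if manual is None or len(manual) != 3:
            raise ValidationError("manual rule needs (P, Q, R)")
        return tuple(int(v) for v in manual)
    if rule not in ("elbow", "knee"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    if not (0 <= epsilon):
        raise ValidationError("epsilon must be non-negative")

    g = grid.sort_values(["total_components", "P", "Q", "R"]).reset_index(drop=True)
    best_per_s = {}
    for _, row in g.iterrows():
        s = int(row["total_components"])
        cur = best_per_s.get(s)
        if cur is None or row["explained_fraction"] > cur["explained_fraction"] + 0.0:
            best_per_s[s] = row
    s_values = sorted(best_per_s)
    fractions = np.array([float(best_per_s[s]["explained_fraction"]) for s in s_values])
    # best achievable at any strictly larger S (0 remaining gain at the last S)
    future_best = np.append(np.maximum.accumulate(fractions[::-1])[::-1][1:], fractions[-1])
    for s, frac, future in zip(s_values, fractions, future_best):
        if future - frac < epsilon:
            row = best_per_s[s]
            return (int(row["P"]), int(row["Q"]), int(row["R"]))
    row = best_per_s[s_values[-1]]
    return (int(row["P"]), int(row["Q"]), int(row["R"]))


def _column_cv(col: np.ndarray) -> float:
    """Coefficient of variation after flipping the sign so the mean is positive."""
    v = col if col.sum() >= 0 else -col
    mean = float(v.mean())
    if mean == 0.0:
        return np.inf
    return float(v.std(ddof=0)) / abs(mean)


def partition_main_effects(
    model: Tucker3Model, contributions: pd.DataFrame | None = None, cv_threshold: float = 0.2
) -> pd.DataFrame:
    """Attribute the fitted variance to genotype / internode main effects vs
    genotype x internode interaction.

    A mode component is "constant" when the coefficient of variation of its
    loadings (sign-fixed so the mean is positive) is below ``cv_threshold``
    — e.g. genotype loadings all close to 1/sqrt(I) mean every genotype shares
    that profile.  A core element whose internode component is constant is a
    genotype main effect; one whose genotype component is constant is an
    internode main effect; anything else is interaction.
    """
    if contributions is None:
        contributions = core_contributions(model)
    a_const = [_column_cv(model.A[:, p]) < cv_threshold for p in range(model.A.shape[1])]
    c_const = [_column_cv(model.C[:, r]) < cv_threshold for r in range(model.C.shape[1])]

    def classify(row) -> str:
        p, r = int(row["p"]) - 1, int(row["r"]) - 1
        if c_const[r]:
            return "genotype_main_effect"
        if a_const[p]:
            return "internode_main_effect"
        return "interaction"

    tab = contributions.copy()
    tab["effect_class"] = tab.apply(classify, axis=1)
    report = (
        tab.groupby("effect_class")["fitted_share"].sum().rename("fitted_share_sum").reset_index()
    )
    for cls in ("genotype_main_effect", "internode_main_effect", "interaction"):
        if cls not in set(report["effect_class"]):
            report = pd.concat(
                [report, pd.DataFrame([{"effect_class": cls, "fitted_share_sum": 0.0}])],
                ignore_index=True,
            )
    return report.sort_values("effect_class").reset_index(drop=True)
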