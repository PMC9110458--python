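"""Synthetic culm-transcriptome data with a known, recoverable ground truth.

Emulates the study design the pipeline targets — 24 genotypes x 5
developmental stages (internodes) x 3 replicates, negative-binomial counts —
with three planted layers of structure:

1. a Tucker3 (genotype, gene, internode) signal on the log2 scale, built from
   orthonormal loading matrices and a core whose designated main-effect
   element dominates;
2. co-expressed gene modules driven by per-sample latent factors, with a
   target inter-gene correlation;
3. quantitative traits that are linear combinations of the standardized
   module latent factors plus Gaussian noise.

Every operation draws from its own deterministic sub-stream of the single
config seed, so outputs are byte-identical across runs and the three
generators can be called independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError, validate_metadata
from .tucker3 import tucker_reconstruct

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tucker_tensor",
    "simulate_counts",
    "simulate_traits",
    "simulate_dataset",
]

# sub-stream keys so each generator is independently reproducible
_STREAM_TENSOR, _STREAM_COUNTS, _STREAM_TRAITS = 0, 1, 2


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    trait_effect: float = 0.0
    inter_gene_cor: float = 0.8

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("module size must be >= 1")
        if not (0.0 <= self.inter_gene_cor <= 1.0):
            raise ValidationError("inter_gene_cor must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the field design the pipeline emulates: 24 genotypes,
    5 internode stages, 3 replicates (360 libraries).  ``signal_rms`` sets the
    log2-scale RMS amplitude of the planted tensor signal and ``module_sd``
    the log2-scale amplitude of module latent factors.
    """

    n_genotypes: int = 24
    n_genes: int = 2000
    n_internodes: int = 5
    n_replicates: int = 3
    true_ranks: tuple = (2, 3, 2)
    module_spec: list = field(default_factory=list)
    noise_sd: float = 0.1
    nb_dispersion: float = 10.0
    library_size_range: tuple = (10_000_000, 20_000_000)
    seed: int = 0
    # amplitude / shape choices the study design leaves open
    signal_rms: float = 1.0
    module_sd: float = 2.0
    baseline_log2_range: tuple = (2.0, 8.0)
    core_dominance: float = 0.55
    genotype_level_latent: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_genes", "n_internodes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        P, Q, R = self.true_ranks
        if not (1 <= P <= self.n_genotypes):
            raise ValidationError(f"rank P={P} exceeds n_genotypes={self.n_genotypes}")
        if not (1 <= Q <= self.n_genes):
            raise ValidationError(f"rank Q={Q} exceeds n_genes={self.n_genes}")
        if not (1 <= R <= self.n_internodes):
            raise ValidationError(f"rank R={R} exceeds n_internodes={self.n_internodes}")
        self.module_spec = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in self.module_spec
        ]
        if sum(m.size for m in self.module_spec) > self.n_genes:
            raise ValidationError("module sizes sum to more than n_genes")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (self.nb_dispersion > 0):
            raise ValidationError("nb_dispersion must be > 0 (may be inf for Poisson)")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must be increasing positive")
        if not (0.0 < self.core_dominance < 1.0):
            raise ValidationError("core_dominance must be in (0, 1)")

    @property
    def genotype_ids(self) -> list:
        return [f"G{i:02d}" for i in range(1, self.n_genotypes + 1)]

    @property
    def gene_ids(self) -> list:
        return [f"gene_{j:05d}" for j in range(1, self.n_genes + 1)]

    @property
    def internode_ids(self) -> list:
        return [f"I{k}" for k in range(1, self.n_internodes + 1)]


@dataclass
class GroundTruth:
    """Planted parameters recorded for downstream recovery checks."""

    A_true: np.ndarray
    B_true: np.ndarray
    C_true: np.ndarray
    G_true: np.ndarray
    module_membership: dict
    trait_loadings: dict
    seed: int = 0
    # filled by simulate_counts: per-sample module latent factors
    module_latent: pd.DataFrame | None = None

    def signal_tensor(self) -> np.ndarray:
        return tucker_reconstruct(self.A_true, self.B_true, self.C_true, self.G_true)

    def module_ids(self) -> list:
        seen: list = []
        for m in self.module_membership.values():
            if m is not None and m not in seen:
                seen.append(m)
        return seen


def _orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, k)))
    # fix the QR sign ambiguity for reproducibility across BLAS builds
    return q * np.sign(np.diag(r))


def _anchor_positions(P: int, Q: int, R: int) -> list:
    """Designated core positions, one per component of the widest mode.

    Each anchor uses a triple whose complementary index pairs differ from all
    previous anchors' in every mode, so the anchored core keeps full
    multilinear rank (coinciding pairs make unfolding rows parallel and
    collapse a mode's effective rank).  Greedy with cyclic bumps; for
    degenerate rank requests the distinctness is best effort.
    """
    m = max(P, Q, R)
    anchors = [(0, 0, 0)]
    for i in range(1, m):
        p, q, r = i % P, i % Q, i % R
        placed = False
        for bump in range(P * Q * R):
            rr = (r + bump) % R
            qq = (q + bump // R) % Q
            pp = (p + bump // (R * Q)) % P
            cand = (pp, qq, rr)
            if cand in anchors:
                continue
            if all(
                (cand[1], cand[2]) != (a[1], a[2])
                and (cand[0], cand[2]) != (a[0], a[2])
                and (cand[0], cand[1]) != (a[0], a[1])
                for a in anchors
            ):
                anchors.append(cand)
                placed = True
                break
        if not placed:  # degenerate rank combination: reuse the start position
            anchors.append((p, q, r))
    return anchors


def simulate_tucker_tensor(config: SimulationConfig):
    """Draw orthonormal loadings and a dominant-main-element core, and return
    the noisy signal tensor together with the planted :class:`GroundTruth`.

    The array equals the Tucker3 reconstruction plus iid Normal(0, noise_sd^2)
    entries; at ``noise_sd=0`` it reconstructs exactly from the truth.
    """
    rng = _rng(config.seed, _STREAM_TENSOR)
    I, J, K = config.n_genotypes, config.n_genes, config.n_internodes
    P, Q, R = config.true_ranks

    A = _orthonormal(rng, I, P)
    B = _orthonormal(rng, J, Q)
    C = _orthonormal(rng, K, R)

    # Core construction: a dominant (1,1,1) element plus designated secondary
    # elements with geometrically decaying shares that touch every component
    # of every mode, over a small Gaussian background.  This mimics the
    # main-effect-dominated regime and keeps each component identifiable
    # (a purely random core can leave a component with negligible energy).
    G = rng.standard_normal((P, Q, R))
    G[0, 0, 0] = 0.0
    bg_ss = float(np.sum(G**2))
    anchors = _anchor_positions(P, Q, R)[1:]
    if bg_ss > 0:
        bg_share = 0.2 if anchors else 1.0
        G *= math.sqrt(bg_share * (1.0 - config.core_dominance) / bg_ss)
    if anchors:
        decay = 0.6 ** np.arange(1, len(anchors) + 1)
        shares = 0.8 * (1.0 - config.core_dominance) * decay / decay.sum()
        for (p, q, r), share in zip(anchors, shares):
            G[p, q, r] += rng.choice([-1.0, 1.0]) * math.sqrt(share)
    # exact dominant share after normalising the rest
    rest_ss = float(np.sum(G**2))
    if rest_ss > 0:
        G *= math.sqrt((1.0 - config.core_dominance) / rest_ss)
    G[0, 0, 0] = math.sqrt(config.core_dominance)
    # total signal SS = ||G||^2 (orthonormal loadings); set per-cell RMS
    G *= config.signal_rms * math.sqrt(I * J * K)

    signal = tucker_reconstruct(A, B, C, G)
    noise = config.noise_sd * rng.standard_normal(signal.shape)

    membership: dict = {g: None for g in config.gene_ids}
    offset = 0
    for idx, mod in enumerate(config.module_spec, start=1):
        for g in config.gene_ids[offset : offset + mod.size]:
            membership[g] = f"M{idx}"
        offset += mod.size
    trait_loadings = {
        f"M{idx}": mod.trait_effect for idx, mod in enumerate(config.module_spec, start=1)
    }

    from .containers import ThreeWayArray

    tensor = ThreeWayArray(
        values=signal + noise,
        genotype_ids=config.genotype_ids,
        gene_ids=config.gene_ids,
        internode_ids=config.internode_ids,
        centering="none (simulated signal)",
    )
    truth = GroundTruth(
        A_true=A,
        B_true=B,
        C_true=C,
        G_true=G,
        module_membership=membership,
        trait_loadings=trait_loadings,
        seed=config.seed,
    )
    return tensor, truth


def simulate_counts(config: SimulationConfig, truth: GroundTruth):
    """Negative-binomial count matrix for the full replicated design.

    Per gene and sample, the log2 mean CPM is baseline + the tensor signal of
    the sample's (genotype, internode) cell + the gene's module latent term;
    counts are NB with that mean scaled to a drawn library size (gamma-Poisson
    mixture; ``nb_dispersion=inf`` gives the Poisson limit).  Records the
    module latent factors on ``truth.module_latent`` for trait simulation.
    """
    rng = _rng(config.seed, _STREAM_COUNTS)
    I, J, K, T = config.n_genotypes, config.n_genes, config.n_internodes, config.n_replicates

    rows = []
    for gi, g in enumerate(config.genotype_ids):
        for ki, k in enumerate(config.internode_ids):
            for t in range(1, T + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{k}_R{t}",
                        "genotype": g,
                        "internode": k,
                        "replicate": t,
                        "_gi": gi,
                        "_ki": ki,
                    }
                )
    meta = pd.DataFrame(rows)
    n_samples = len(meta)

    baseline = rng.uniform(*config.baseline_log2_range, size=J)
    signal = truth.signal_tensor()  # I x J x K
    log2_mean = baseline[None, :] + signal[meta["_gi"].to_numpy(), :, meta["_ki"].to_numpy()]
    # shape: samples x genes

    module_ids = truth.module_ids()
    latent = pd.DataFrame(
        np.zeros((n_samples, len(module_ids))), index=meta["sample_id"], columns=module_ids
    )
    gene_index = {g: j for j, g in enumerate(config.gene_ids)}
    for mod_id, mod_def in zip(module_ids, config.module_spec):
        if config.genotype_level_latent:
            per_geno = rng.standard_normal(I)
            f = per_geno[meta["_gi"].to_numpy()]
        else:
            f = rng.standard_normal(n_samples)
        latent[mod_id] = f
        members = [g for g, m in truth.module_membership.items() if m == mod_id]
        cols = [gene_index[g] for g in members]
        rho = mod_def.inter_gene_cor
        idio = rng.standard_normal((n_samples, len(cols)))
        term = config.module_sd * (math.sqrt(rho) * f[:, None] + math.sqrt(1 - rho) * idio)
        log2_mean[:, cols] += term

    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng.integers(int(lib_lo), int(lib_hi) + 1, size=n_samples)
    mu = np.exp2(log2_mean) * (lib_sizes[:, None] / 1e6)
    if math.isinf(config.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=config.nb_dispersion, scale=mu / config.nb_dispersion)
        counts = rng.poisson(lam)

    values = pd.DataFrame(
        counts.T, index=pd.Index(config.gene_ids, name="gene_id"), columns=meta["sample_id"]
    )
    truth.module_latent = latent
    meta = validate_metadata(meta.drop(columns=["_gi", "_ki"]))
    return ExpressionMatrix(values, "counts"), meta


def simulate_traits(
    truth: GroundTruth,
    metadata: pd.DataFrame,
    noise_sd: float = 0.0,
    loadings: dict | None = None,
    name: str = "trait",
    genotype_level: bool = False,
) -> pd.DataFrame:
    """Trait value per sample: sum over modules of loading x standardized
    latent factor, plus Normal noise.

    With ``genotype_level=True`` the noise is drawn once per genotype and
    replicated across its samples (per-genotype phenotyping); the latent part
    is genotype-constant only if the counts were simulated with
    ``genotype_level_latent=True``.
    """
    if truth.module_latent is None:
        raise ValidationError("simulate_counts must run before simulate_traits")
    meta = validate_metadata(metadata)
    loadings = dict(truth.trait_loadings if loadings is None else loadings)
    known = set(truth.module_latent.columns)
    unknown = sorted(set(loadings) - known)
    if unknown:
        raise ValidationError(f"unknown module ids in trait loadings: {unknown}")

    rng = _rng(truth.seed, _STREAM_TRAITS)
    sample_ids = meta["sample_id"].tolist()
    values = np.zeros(len(sample_ids))
    for mod, load in loadings.items():
        f = truth.module_latent.loc[sample_ids, mod].to_numpy()
        sd = f.std(ddof=0)
        z = (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)
        values = values + load * z
    if noise_sd > 0:
        if genotype_level:
            genos = meta["genotype"].tolist()
            uniq = list(dict.fromkeys(genos))
            per = dict(zip(uniq, noise_sd * rng.standard_normal(len(uniq))))
            values = values + np.array([per[g] for g in genos])
        else:
            values = values + noise_sd * rng.standard_normal(len(sample_ids))
    return pd.DataFrame({name: values}, index=pd.Index(sample_ids, name="sample_id"))


def simulate_dataset(config: SimulationConfig, trait_noise_sd: float = 0.2):
    """Convenience: tensor + truth + counts + metadata + traits in one call."""
    tensor, truth = simulate_tucker_tensor(config)
    counts, meta = simulate_counts(config, truth)
    traits = simulate_traits(truth, meta, noise_sd=trait_noise_sd)
    return tensor, truth, counts, meta, traits
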