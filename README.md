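# culmnet

Three-way (Tucker3) decomposition and weighted co-expression analysis of
developing sugarcane culm transcriptomes — normalization and filtering of
RNA-seq count matrices, decomposition of the genotype x gene x internode
expression tensor into interpretable components, co-expression module
detection with module-trait statistics, and the trait-specific filtration
that short-lists candidate biomarker genes for sugar and fibre content.

The package targets the question a sugarcane breeding programme asks of a
multi-genotype, multi-stage culm RNA-seq experiment: how much of the
transcriptome's variation is genotype main effect, internode (development)
main effect, or genotype x internode interaction — and which co-expressed
gene groups track agronomic traits such as early-season sugar content and
fibre content.  Because the original 360-library dataset is not bundled,
everything is exercised end-to-end on a synthetic study design with planted,
recoverable ground truth: a known Tucker3 signal, known co-expression
modules, and traits tied linearly to module activity.

## The models

**Tucker3 / three-way PCA.**  Replicate-averaged, per-gene centred
expression is arranged as an `I x J x K` array (genotypes x genes x
internodes) and decomposed as

    x_ijk = Σ_p Σ_q Σ_r  a_ip b_jq c_kr g_pqr + e_ijk

with orthonormal loading matrices `A, B, C` and core array `G`.  Each
squared core element `g_pqr^2` is the fitted-variance share of one component
triple; elements whose genotype component is (near-)constant across
genotypes are internode main effects, and vice versa.  Fitting is
alternating least squares with HOSVD initialisation; ranks are chosen by a
scree-elbow rule over an exhaustive `(P, Q, R)` grid (canonically
5 x 20 x 3 = 300 combinations).

**Weighted co-expression network.**  Unsigned adjacency `|cor|^beta`
(default beta = 4, selected by scale-free topology fit), topological overlap
smoothing, ward.D clustering of `1 - TOM` with a static cohesion-scored
height cut and a minimum module size, module eigengenes (first PC of a
module), gene significance `GS = |cor(gene, trait)|`, module significance
(module mean GS), and candidate filtration: top-100 genes by GS intersected
with the trait's module, excluding the antagonistic trait's module.

## Worked example

```python
from culmnet.simulate import SimulationConfig, ModuleSpec, simulate_dataset
from culmnet.preprocess import (filter_min_count, compute_tmm_factors,
                                normalize_log, build_threeway_array)
from culmnet.tucker3 import fit_tucker3, core_contributions
from culmnet.network import (NetworkConfig, adjacency, tom_similarity,
                             detect_modules, module_eigengene,
                             module_trait_relation)

cfg = SimulationConfig(
    n_genes=2000, true_ranks=(2, 3, 2), noise_sd=0.1,
    module_spec=[ModuleSpec(200, trait_effect=+1.0, inter_gene_cor=0.9),
                 ModuleSpec(200, trait_effect=-1.0, inter_gene_cor=0.9)],
    seed=1,
)
tensor, truth, counts, meta, traits = simulate_dataset(cfg)

kept, _ = filter_min_count(counts)                       # >=10 reads in >=70%
factors = compute_tmm_factors(kept, relative_to_library_size=True)
lg = normalize_log(kept, factors=factors, mode="CPM")    # log2(CPM+1)

model = fit_tucker3(build_threeway_array(lg, meta), 2, 3, 2, seed=1)
print(f"explained: {100*model.explained_fraction:.1f}%")
print(core_contributions(model).head(1)[["p", "q", "r", "fitted_share"]])

adj = adjacency(lg, beta=4)
asn = detect_modules(tom_similarity(adj), NetworkConfig(min_module_size=50),
                     adj=adj)
mtr = module_trait_relation(module_eigengene(lg, asn), traits)
print(mtr[mtr.p < 0.01])
```

prints

```
explained: 76.0%
   p  q  r  fitted_share
0  1  1  1      0.512123
   module  trait         r             p
2   brown  trait  0.701676  1.184297e-54
3  yellow  trait -0.724126  9.930196e-60
```

i.e. the fitted model recovers most of the planted variance, the dominant
core element `g111` carries about half of the fitted sum of squares (the
planted dominance is 0.55 of the noise-free core), and exactly two detected
modules — the planted ones — correlate strongly and with opposite signs
with the trait.

The same workflow is laid out as numbered drivers under `analysis/`
(`01_simulate_dataset.py` ... `05_candidate_genes.py`), each writing its
tables under `results/`, and as a `culmnet` command-line tool with
`simulate / preprocess / tucker3 / network / select / run` subcommands.

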