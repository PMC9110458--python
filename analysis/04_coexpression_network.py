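"""Weighted co-expression network, modules and module-trait statistics.

Scores candidate soft-thresholding powers by scale-free fit, builds the
unsigned adjacency and topological overlap, detects modules (minimum size
50 on the 2,000-gene design), and correlates module eigengenes and single
genes with the trait.  Writes tables under results/network/.
"""

import argparse
from pathlib import Path

from culmnet import io as cio
from culmnet.network import (
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

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--power", type=float, default=4.0)
    ap.add_argument("--min-module-size", type=int, default=50)
    args = ap.parse_args()

    out = ROOT / "results" / "network"
    out.mkdir(parents=True, exist_ok=True)

    lg = cio.read_expression(ROOT / "results" / "preprocess" / "log2cpm1.tsv", "log2CPM1")
    traits = cio.read_traits(ROOT / "results" / "data" / "traits.csv")
    config = NetworkConfig(power=args.power, min_module_size=args.min_module_size)

    beta_auto, power_table = pick_soft_threshold(lg, config)
    power_table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
    row4 = power_table.set_index("power").loc[4]
    print(f"scale-free R^2 at beta=4: {row4.signed_r2:.2f} "
          f"(automatic pick over candidates: beta={beta_auto:g}); using beta={args.power:g}")

    adj = adjacency(lg, beta=args.power)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, config, adj=adj)
    assignment.labels.rename("module").to_csv(out / "modules.tsv", sep="\t",
                                              index_label="gene_id")
    sizes = assignment.labels.value_counts()
    print(f"{len(assignment.modules())} modules detected "
          f"(+{int(sizes.get('grey', 0))} grey genes): "
          + ", ".join(f"{m}={sizes[m]}" for m in assignment.modules()))

    eig = module_eigengene(lg, assignment)
    eig.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
    mtr = module_trait_relation(eig, traits)
    mtr.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    print("module-trait correlations:")
    for _, row in mtr.iterrows():
        print(f"  {row.module:>12s}: r = {row.r:+.2f} (p = {row.p:.2e})")

    gs = gene_significance(lg, traits[traits.columns[0]])
    gs.to_csv(out / "gene_significance.tsv", sep="\t")
    ms = module_significance(gs, assignment)
    ms.to_csv(out / "module_significance.tsv", sep="\t", index=False)
    best = ms.sort_values("module_significance", ascending=False).iloc[0]
    print(f"highest module significance: {best.module} "
          f"(mean |GS| = {best.module_significance:.2f})")


if __name__ == "__main__":
    main()
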