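"""Generate the synthetic study dataset with known ground truth.

Emulates the field design the pipeline targets — 24 genotypes x 5 internode
stages x 3 replicates (360 libraries), 2,000 genes — with a planted
rank-(2,3,2) genotype x gene x internode signal and two antagonistic
200-gene co-expression modules whose latent activity drives a quantitative
trait (loadings +1 / -1).  Writes counts, metadata, traits and the ground
truth under results/data/.
"""

import argparse
from pathlib import Path

from culmnet import io as cio
from culmnet.simulate import ModuleSpec, SimulationConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(
        n_genes=2000,
        true_ranks=(2, 3, 2),
        noise_sd=0.1,
        module_spec=[
            ModuleSpec(size=200, trait_effect=1.0, inter_gene_cor=0.9),
            ModuleSpec(size=200, trait_effect=-1.0, inter_gene_cor=0.9),
        ],
        seed=args.seed,
    )
    tensor, truth, counts, meta, traits = simulate_dataset(cfg, trait_noise_sd=0.2)

    out = ROOT / "results" / "data"
    cio.write_expression(counts, out / "counts.tsv")
    cio.write_metadata(meta, out / "metadata.csv")
    cio.write_traits(traits, out / "traits.csv")
    cio.write_ground_truth(truth, out / "truth")

    print(f"simulated {counts.n_genes} genes x {counts.n_samples} libraries (seed {args.seed})")
    print(f"planted modules: M1 (+1, 200 genes), M2 (-1, 200 genes); tensor ranks (2, 3, 2)")
    print(f"wrote {out}/counts.tsv, metadata.csv, traits.csv, truth/")


if __name__ == "__main__":
    main()
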