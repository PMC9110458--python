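"""Trait-specific candidate genes and recovery against the planted truth.

Replays the biomarker filtration: the top-100 genes by gene significance are
intersected with the trait's positively-correlated module and genes of the
antagonistic module are excluded; the reverse gives the second list.  Both
lists are checked against the planted module membership.  Writes tables
under results/selection/.
"""

import json
from pathlib import Path

import pandas as pd

from culmnet import io as cio
from culmnet.network import ModuleAssignment
from culmnet.selection import (
    module_overlap,
    positive_subset,
    top_k_by_significance,
    trait_specific_candidates,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "selection"
    out.mkdir(parents=True, exist_ok=True)
    net = ROOT / "results" / "network"

    gs = pd.read_csv(net / "gene_significance.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(net / "modules.tsv", sep="\t", index_col=0)["module"]
    mtr = pd.read_csv(net / "module_trait.tsv", sep="\t").set_index("module")
    truth = json.loads(
        (ROOT / "results" / "data" / "truth" / "ground_truth.json").read_text()
    )
    membership = pd.Series(truth["module_membership"])
    assignment = ModuleAssignment(labels=labels, min_module_size=50)

    # the positively- and negatively-correlated trait modules play the roles
    # of the sugar- and fibre-linked modules in the filtration logic
    non_grey = mtr[mtr.index != "grey"]
    pos_module = non_grey["r"].idxmax()
    neg_module = non_grey["r"].idxmin()
    print(f"trait-positive module: {pos_module} (r = {non_grey.loc[pos_module, 'r']:+.2f}); "
          f"trait-negative module: {neg_module} (r = {non_grey.loc[neg_module, 'r']:+.2f})")

    pos_set = positive_subset(assignment, gs, pos_module)
    print(f"{len(pos_set)} genes of {pos_module} significantly positively "
          f"correlated to the trait")

    top = top_k_by_significance(gs, k=100)
    top.to_csv(out / "top100_by_gene_significance.tsv", sep="\t")

    cand_pos = trait_specific_candidates(top, assignment, target=pos_module,
                                         exclude=neg_module, trait="trait")
    cand_neg = trait_specific_candidates(top, assignment, target=neg_module,
                                         exclude=pos_module, trait="trait")
    cand_pos.table.to_csv(out / "candidates_positive.tsv", sep="\t", index=False)
    cand_neg.table.to_csv(out / "candidates_negative.tsv", sep="\t", index=False)

    n_overlap, _ = module_overlap(cand_pos.genes, cand_neg.genes)
    print(f"candidate lists: {len(cand_pos)} positive, {len(cand_neg)} negative, "
          f"overlap {n_overlap}")

    for name, cand in (("positive", cand_pos), ("negative", cand_neg)):
        if not len(cand):
            continue
        planted = {m for g, m in membership.items() if g in set(cand.genes)}
        frac = (membership.reindex(cand.genes).notna()).mean()
        print(f"{name} list: {100 * frac:.0f}% of candidates are planted module "
              f"genes ({sorted(planted - {None}) or 'none'})")


if __name__ == "__main__":
    main()
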