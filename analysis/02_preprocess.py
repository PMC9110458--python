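"""Filter and normalize the count matrix; exploratory sample structure.

Applies the low-count filter (>= 10 reads in >= 70% of libraries), TMM
scaling factors and the log2(CPM + 1) transform, then summarizes sample
structure with a PCA and a ward.D dendrogram.  Writes the normalized matrix
and reports under results/preprocess/.
"""

import json
from pathlib import Path

from culmnet import io as cio
from culmnet.preprocess import (
    compute_tmm_factors,
    expression_dendrogram,
    filter_min_count,
    normalize_log,
    sample_pca,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results" / "preprocess"
    out.mkdir(parents=True, exist_ok=True)

    counts = cio.read_expression(data / "counts.tsv", "counts")
    meta = cio.read_metadata(data / "metadata.csv")

    filtered, removed = filter_min_count(counts)
    print(f"low-count filter kept {filtered.n_genes}/{counts.n_genes} genes")
    factors = compute_tmm_factors(filtered, relative_to_library_size=True)
    factors.to_csv(out / "tmm_factors.tsv", sep="\t")
    print(f"TMM factors span [{factors.min():.3f}, {factors.max():.3f}]")

    lg = normalize_log(filtered, factors=factors, mode="CPM")
    cio.write_expression(lg, out / "log2cpm1.tsv")

    scores, explained = sample_pca(lg, n_components=5)
    scores.to_csv(out / "sample_pca_scores.tsv", sep="\t")
    (out / "sample_pca_explained.json").write_text(json.dumps(explained.tolist()))
    print(
        "sample PCA: PC1 explains "
        f"{100 * explained[0]:.1f}%, PC2 {100 * explained[1]:.1f}% of variance"
    )

    z, labels = expression_dendrogram(lg, meta, transform="passthrough")
    cio.write_newick(z, labels, out / "sample_dendrogram.nwk")
    print(f"wrote normalized matrix, PCA and dendrogram to {out}")


if __name__ == "__main__":
    main()
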