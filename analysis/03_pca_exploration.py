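"""PCA exploration: variance structure, scores, class-similarity tree.

Fits a 10-component PCA to the preprocessed, outlier-screened spectra,
tabulates per-component and cumulative variance fractions, writes the
score matrix, and builds the class-mean similarity dendrogram.
"""

import importlib
import json
from pathlib import Path

import numpy as np

import libsclass as L

prev = importlib.import_module("02_preprocess_outliers")


def main():
    ds = prev.load_preprocessed()
    flagged = L.detect_outliers_by_class(ds)
    ds = ds.select(np.setdiff1d(np.arange(ds.n_spectra), flagged))

    model = L.fit_pca(ds, 10)
    scores = L.project(model, ds)
    out = Path("results")
    out.mkdir(exist_ok=True)
    with (out / "pca_variance.csv").open("w") as fh:
        fh.write("component,fraction,cumulative\n")
        for j in range(1, 11):
            fh.write(f"{j},{model.variance_fractions[j-1]:.6f},"
                     f"{L.variance_explained(model, j):.6f}\n")
    with (out / "pca_scores.csv").open("w") as fh:
        fh.write("class," + ",".join(f"PC{j}" for j in range(1, 11)) + "\n")
        for label, row in zip(ds.labels, scores):
            fh.write(label + "," + ",".join(f"{v:.6g}" for v in row) + "\n")

    means = L.class_mean_spectra(ds)
    tree = L.class_similarity_dendrogram(means)
    (out / "class_dendrogram.json").write_text(L.tree_to_json(tree))
    (out / "class_dendrogram.nwk").write_text(L.tree_to_newick(tree))

    print("variance explained: "
          f"PC1 {100*L.variance_explained(model,1):.1f}%, "
          f"PC1-2 {100*L.variance_explained(model,2):.1f}%, "
          f"PC1-3 {100*L.variance_explained(model,3):.1f}%")
    first = tree.merges[0]
    pair = {tree.leaf_ids[int(first[0])], tree.leaf_ids[int(first[1])]}
    print(f"most similar class pair (first dendrogram merge): {sorted(pair)}")
    print("wrote results/pca_variance.csv, pca_scores.csv, class_dendrogram.{json,nwk}")


if __name__ == "__main__":
    main()
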