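#!/usr/bin/env python
"""Reduce the 10 network features per band and cluster the participants.

For each band: z-score the 5 metrics x pre/post feature table, check
sampling adequacy (KMO, Bartlett sphericity), extract two principal
components of the feature correlation matrix, cluster the PC scores with
Ward/Euclidean at k = 2 (elbow/silhouette curves emitted as evidence), and
quantify per-cluster reliability by bootstrap subsampling (300 iterations,
80% of participants, without replacement).

Writes per-band adequacy, loadings, scores, model-selection curves, labels,
and stability tables under results/cluster_<band>/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from bandclust.clustering import (  # noqa: E402
    bootstrap_stability,
    pca2,
    ward_cluster,
    zscore,
)
from bandclust.io import feature_table_from_metrics  # noqa: E402

SEED = 20260928


def main() -> None:
    metrics = pd.read_csv(ROOT / "results" / "metrics.csv")
    for band in ("delta", "beta"):
        out = ROOT / "results" / f"cluster_{band}"
        out.mkdir(parents=True, exist_ok=True)
        features = feature_table_from_metrics(metrics, band)
        table = zscore(features, band=band)
        pca = pca2(table)
        pca.loadings.to_csv(out / "pca_loadings.csv")
        pca.scores.to_csv(out / "pca_scores.csv")
        pd.DataFrame(
            [
                {
                    "kmo": pca.kmo,
                    "bartlett_chi2": pca.bartlett_chi2,
                    "bartlett_df": pca.bartlett_df,
                    "bartlett_p": pca.bartlett_p,
                }
            ]
        ).to_csv(out / "adequacy.csv", index=False)
        pd.DataFrame(
            {
                "component": np.arange(1, pca.explained_variance_ratio.size + 1),
                "explained_variance_ratio": pca.explained_variance_ratio,
            }
        ).to_csv(out / "explained_variance.csv", index=False)
        solution = ward_cluster(pca.scores.to_numpy(), k=2, k_range=range(2, 9))
        pd.DataFrame(
            {
                "k": list(solution.inertia_by_k),
                "inertia": list(solution.inertia_by_k.values()),
                "silhouette": [
                    solution.silhouette_by_k[k] for k in solution.inertia_by_k
                ],
            }
        ).to_csv(out / "model_selection.csv", index=False)
        pd.DataFrame(
            {"participant_id": pca.scores.index, "cluster": solution.labels}
        ).to_csv(out / "labels.csv", index=False)
        report = bootstrap_stability(
            pca.scores.to_numpy(), solution, n_boot=300, frac=0.8, seed=SEED
        )
        report.to_frame().to_csv(out / "stability.csv", index=False)

        sizes = np.bincount(solution.labels)[1:]
        evr = pca.explained_variance_ratio
        print(
            f"{band}: KMO {pca.kmo:.3f}, Bartlett chi2 {pca.bartlett_chi2:.1f} "
            f"(p {pca.bartlett_p:.2e}); PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%}"
        )
        print(
            f"  k=2 clusters sized {sizes.tolist()}; Jaccard "
            + ", ".join(
                f"{m:.2f}±{s:.2f} ({c})"
                for m, s, c in zip(
                    report.mean_jaccard, report.sd_jaccard, report.category
                )
            )
        )


if __name__ == "__main__":
    main()
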