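#!/usr/bin/env python
"""Compare the two clusters on clustering and non-clustering variables.

Per band: Mann-Whitney U with rank-biserial effect sizes (bootstrap 95% CI)
for the ten network features and the continuous behavioral variables;
Fisher's exact test with phi for the binary ones; plus paired pre/post
Wilcoxon tests of every graph metric across the whole cohort (the
connectivity null that holds by construction in the generator).

No multiple-comparison correction is applied; each output row carries that
note explicitly.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from bandclust.io import feature_table_from_metrics  # noqa: E402
from bandclust.metrics import METRIC_NAMES  # noqa: E402
from bandclust.pipeline import BEHAV_CATEGORICAL, BEHAV_CONTINUOUS  # noqa: E402
from bandclust.stats import (  # noqa: E402
    cluster_comparison_table,
    prepost_comparison_table,
)

SEED = 20260928


def main() -> None:
    metrics = pd.read_csv(ROOT / "results" / "metrics.csv")
    behavioral = pd.read_csv(ROOT / "results" / "cohort" / "behavioral.csv")
    for band in ("delta", "beta"):
        out = ROOT / "results" / f"cluster_{band}"
        features = feature_table_from_metrics(metrics, band)
        labels = (
            pd.read_csv(out / "labels.csv")
            .set_index("participant_id")["cluster"]
            .loc[features.index]
            .to_numpy()
        )
        behav = behavioral.set_index("participant_id").loc[features.index]
        data = features.join(behav)
        continuous = list(features.columns) + [
            c for c in BEHAV_CONTINUOUS if c in behav.columns
        ]
        categorical = [c for c in BEHAV_CATEGORICAL if c in behav.columns]
        table = cluster_comparison_table(
            data, labels, continuous, categorical, seed=SEED
        )
        table.to_csv(out / "comparisons.csv", index=False)
        prepost = prepost_comparison_table(features, list(METRIC_NAMES))
        prepost.to_csv(out / "prepost.csv", index=False)

        sig = table[table["p_value"] < 0.05]["variable"].tolist()
        print(f"{band}: {len(sig)} of {len(table)} comparisons at p < 0.05")
        print(f"  significant: {sig}")
        ns_prepost = (prepost["p_value"] >= 0.05).all()
        print(f"  pre/post metric differences all non-significant: {ns_prepost}")


if __name__ == "__main__":
    main()
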