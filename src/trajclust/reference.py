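"""Published reference counts from the original 16-week program cohort.

The study this pipeline re-implements analyzed a proprietary cohort of
13,140 mobile-app users, so its raw data cannot ship here.  What it did
publish is the weight-class distribution of each of its five trajectory
clusters — all class rows except "lost 5-10%", plus the per-cluster
totals.  That is enough to reconstruct the full 6x5 contingency table by
margin subtraction and to recompute the headline association statistics
(Cramer V of weight class vs. cluster, membership shares, the share of
cluster 1 losing more than 5%).  The printed counts ship as a small CSV
fixture in ``trajclust/data``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import chi_square_with_v

__all__ = [
    "load_reference_counts",
    "reconstruct_weight_class_table",
    "reference_association",
    "membership_shares",
    "cluster1_over5pct_loss",
]

_FIXTURE = "reference_weight_class_counts.csv"

# row order of the reconstructed table (derived row inserted in sequence)
_CLASS_ORDER = ["gain_gt2", "stable", "loss_2_5", "loss_5_10", "loss_10_15", "loss_gt15"]


def load_reference_counts() -> pd.DataFrame:
    """The printed per-cluster counts: five class rows + cluster totals."""
    with resources.files("trajclust.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, index_col="weight_class")
    return df


def reconstruct_weight_class_table() -> pd.DataFrame:
    """Full 6x5 weight-class x cluster table via margin subtraction.

    The "loss_5_10" row is not printed; each of its cells is the cluster
    total minus the five printed class counts of that cluster.
    """
    raw = load_reference_counts()
    totals = raw.loc["cluster_total"]
    printed = raw.drop(index="cluster_total")
    derived = totals - printed.sum(axis=0)
    if (derived < 0).any():
        raise ValueError("reference counts inconsistent: negative derived cell")
    table = printed.copy()
    table.loc["loss_5_10"] = derived
    return table.loc[_CLASS_ORDER]


def reference_association() -> dict:
    """Chi-square association of weight class with cluster membership."""
    table = reconstruct_weight_class_table()
    chi2, p, v, eff_type = chi_square_with_v(table.to_numpy())
    assert eff_type == "cramers_v"
    return {
        "chi2": chi2,
        "p_value": p,
        "cramers_v": v,
        "n": int(table.to_numpy().sum()),
    }


def membership_shares() -> pd.Series:
    """Each cluster's share of the analyzed cohort, in percent."""
    totals = load_reference_counts().loc["cluster_total"]
    return 100.0 * totals / totals.sum()


def cluster1_over5pct_loss() -> dict:
    """Count and percent of cluster-1 users who lost more than 5%."""
    table = reconstruct_weight_class_table()
    over5 = int(table.loc[["loss_5_10", "loss_10_15", "loss_gt15"], "cluster1"].sum())
    total = int(table["cluster1"].sum())
    return {"count": over5, "total": total, "percent": 100.0 * over5 / total}
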