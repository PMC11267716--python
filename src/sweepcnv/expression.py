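"""Per-species summaries of differential-expression evidence for a gene.

Aggregates a table of per-experiment fold changes and adjusted p-values
(e.g. resistant-vs-susceptible transcriptomic comparisons across many
microarray and RNA-seq studies) into per-species counts of significantly
up/down-regulated experiments and mean/median fold changes. Because the
scale on which mean fold changes are most meaningful is debatable, both the
linear and the log2 mean/median are always reported, explicitly labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionTable", "summarize_by_species"]

REQUIRED_COLUMNS = ["experiment_id", "species", "gene_id", "fold_change", "adjusted_p"]


@dataclass
class ExpressionTable:
    """Fold-change table with an explicitly declared scale.

    ``data`` needs columns ``experiment_id``, ``species``, ``gene_id``,
    ``fold_change`` and ``adjusted_p`` (``mean_count`` optional);
    ``fold_change_scale`` is ``"log2"`` or ``"linear"``.
    """

    data: pd.DataFrame
    fold_change_scale: str = "log2"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"expression table lacks columns: {missing}")
        if self.fold_change_scale not in ("log2", "linear"):
            raise ValueError("fold_change_scale must be 'log2' or 'linear'")
        p = self.data["adjusted_p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted_p values must lie in [0, 1]")
        if self.fold_change_scale == "linear" and (self.data["fold_change"] <= 0).any():
            raise ValueError("linear fold changes must be positive")

    def log2_fold_changes(self) -> pd.Series:
        fc = self.data["fold_change"].astype(float)
        return fc if self.fold_change_scale == "log2" else np.log2(fc)


def summarize_by_species(
    table: ExpressionTable, gene: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Summarize differential-expression evidence for one gene, per species.

    An experiment counts as significant-up when ``adjusted_p <= alpha`` and
    the log2 fold change is positive; significant-down analogously with a
    negative log2 fold change. Counts partition the experiments exactly
    (up + down + non-significant = total). Means and medians are reported on
    both the linear and log2 scales; for species strata with no experiments
    they are NaN.

    Returns a DataFrame indexed by species.
    """
    sub = table.data[table.data["gene_id"] == gene].copy()
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from expression table")
    sub["log2_fc"] = (
        sub["fold_change"].astype(float)
        if table.fold_change_scale == "log2"
        else np.log2(sub["fold_change"].astype(float))
    )
    sub["linear_fc"] = 2.0 ** sub["log2_fc"]
    sig = sub["adjusted_p"] <= alpha
    sub["category"] = np.where(
        sig & (sub["log2_fc"] > 0),
        "up",
        np.where(sig & (sub["log2_fc"] < 0), "down", "ns"),
    )

    rows = []
    for species, grp in sub.groupby("species", sort=True):
        n = len(grp)
        n_up = int((grp["category"] == "up").sum())
        n_down = int((grp["category"] == "down").sum())
        rows.append(
            {
                "species": species,
                "n_experiments": n,
                "mean_log2_fc": grp["log2_fc"].mean(),
                "median_log2_fc": grp["log2_fc"].median(),
                "mean_linear_fc": grp["linear_fc"].mean(),
                "median_linear_fc": grp["linear_fc"].median(),
                "n_up": n_up,
                "n_down": n_down,
                "n_ns": n - n_up - n_down,
                "frac_up": n_up / n,
                "frac_down": n_down / n,
            }
        )
    return pd.DataFrame(rows).set_index("species")
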