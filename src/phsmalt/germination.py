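"""Germination percentage (GE) and germination rate (GI) from plate counts.

A germination assay plates 30 kernels per plot (two technical-replicate
plates) and counts germinated kernels at 24, 48 and 72 h.  GE is the fraction
of plated kernels that germinated.  GI is an inverse mean germination time
scaled to [0, 10]:

    GI = 10 * (n24 + n48 + n72) * GE / (1*n24 + 2*n48 + 3*n72)

GI = 10 means every plated kernel germinated on day one; a fully dormant plate
(nothing germinates, a 0/0 case) is defined as GI = 0, the dormant extreme.
GI at the first after-ripening timepoint (TP1, 6 days post physiological
maturity) is the working measure of PHS resistance and is exposed under the
alias ``phs_score``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHS_TIMEPOINT = "TP1"


@dataclass(frozen=True)
class GerminationPlate:
    """Raw 24/48/72 h germination counts for one plate."""

    plot_id: str
    timepoint: str
    rep: int
    n24: int
    n48: int
    n72: int
    n_plated: int = 30

    def __post_init__(self):
        if self.n_plated <= 0:
            raise ValueError("n_plated must be positive")
        if min(self.n24, self.n48, self.n72) < 0:
            raise ValueError("kernel counts must be non-negative")
        if self.n24 + self.n48 + self.n72 > self.n_plated:
            raise ValueError(
                f"germinated counts ({self.n24}+{self.n48}+{self.n72}) exceed "
                f"plated kernels ({self.n_plated})"
            )


def germination_percentage(plate: GerminationPlate) -> float:
    """GE: proportion of plated kernels that germinated within 72 h."""
    return (plate.n24 + plate.n48 + plate.n72) / plate.n_plated


def germination_index(plate: GerminationPlate) -> float:
    """GI: inverse-mean-germination-time rate on the [0, 10] scale."""
    total = plate.n24 + plate.n48 + plate.n72
    if total == 0:
        return 0.0
    ge = total / plate.n_plated
    return 10.0 * total * ge / (1 * plate.n24 + 2 * plate.n48 + 3 * plate.n72)


def summarize_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-plate GE/GI for a plate-count table.

    Expects columns plot_id, timepoint, rep, n24, n48, n72 and optionally
    n_plated (default 30).
    """
    df = plates.copy()
    if "n_plated" not in df.columns:
        df["n_plated"] = 30
    total = df[["n24", "n48", "n72"]].sum(axis=1)
    if (total > df["n_plated"]).any():
        bad = df.loc[total > df["n_plated"], "plot_id"].iloc[0]
        raise ValueError(f"germinated counts exceed plated kernels (plot {bad})")
    ge = total / df["n_plated"]
    denom = df["n24"] + 2 * df["n48"] + 3 * df["n72"]
    with np.errstate(invalid="ignore", divide="ignore"):
        gi = 10.0 * total * ge / denom
    df["GE"] = ge
    df["GI"] = np.where(total == 0, 0.0, gi)
    return df


def plot_germination_means(plates: pd.DataFrame) -> pd.DataFrame:
    """Average per-plate GE and GI over technical replicates per plot x timepoint.

    The statistic is computed per plate first and then averaged (not pooled
    counts), matching how technical replicates are treated downstream.
    Single-rep plots pass through unchanged.
    """
    per_plate = summarize_plates(plates)
    keys = ["plot_id", "timepoint"]
    extra = [c for c in ("line_id", "year") if c in per_plate.columns]
    out = per_plate.groupby(keys + extra, as_index=False)[["GE", "GI"]].mean()
    return out


def phs_score(summary: pd.DataFrame) -> pd.DataFrame:
    """GI at TP1, the PHS-resistance measure (lower = more resistant)."""
    out = summary.loc[summary["timepoint"] == PHS_TIMEPOINT].copy()
    out = out.rename(columns={"GI": "phs_score"}).drop(columns=["GE"])
    return out
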