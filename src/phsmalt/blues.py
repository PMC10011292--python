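"""Fixed-effect line means (BLUEs) for each timepoint/year labelling scheme.

Line effects are reported as *adjusted means*: the line coefficient plus the
intercept plus the equally-weighted average of the other fixed-effect cells,
so estimates are on the trait scale and comparable across labelling schemes.
Labels follow the scheme vocabulary: per-timepoint ("TP4", "TP6"), timepoints
as replicates ("TP4/TP6"), and across-year sets ("20/21", "19/20/21",
"Combined").  These tables are the hand-off point to external genome-wide
association tools.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from phsmalt.mixedlm import FixedDesign, ModelError, ModelSpec, Residual, fit_lmm

log = logging.getLogger("phsmalt")

BLUE_COLUMNS = ["line_id", "trait", "label", "estimate", "se"]


def _adjusted_line_means(
    data: pd.DataFrame,
    covar_terms: list[str],
    label: str,
    trait: str,
    row_weights: np.ndarray | None = None,
    scale_vcov: bool = True,
) -> pd.DataFrame:
    """Weighted LS fit of covariates + line; returns adjusted line means.

    ``row_weights`` are inverse residual variances (GLS); when None an OLS fit
    is used and the coefficient covariance is scaled by the residual MS.
    """
    terms = covar_terms + ["line_id"]
    fd = FixedDesign(data, terms)
    y = data["value"].to_numpy(float)
    w = np.ones(len(y)) if row_weights is None else row_weights
    sw = np.sqrt(w)
    Xw = fd.X * sw[:, None]
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    XtX = Xw.T @ Xw
    V = np.linalg.pinv(XtX)
    if scale_vcov:
        dof = max(len(y) - fd.X.shape[1], 1)
        s2 = float(np.sum(w * (y - fd.X @ beta) ** 2)) / dof
        V = V * s2

    # equally-weighted average over observed covariate cells, line at reference
    if covar_terms:
        cell_cols = sorted({c for t in covar_terms for c in t.split(":")})
        grid = data[cell_cols].drop_duplicates().reset_index(drop=True)
        ref_line = fd.categories["line_id"][0]
        grid["line_id"] = ref_line
        cbar = fd.encode(grid).mean(axis=0)
    else:
        cbar = np.zeros(fd.X.shape[1])
        cbar[0] = 1.0
    base = float(cbar @ beta)
    Vc = V @ cbar
    base_var = float(cbar @ Vc)

    lines = fd.categories["line_id"]
    rows = []
    aliased = set(fd.aliased)
    for j, line in enumerate(lines):
        lab = f"line_id[{line}]"
        if j == 0:
            est, var = base, base_var
        elif lab in aliased:
            rows.append((line, trait, label, np.nan, np.nan))
            continue
        else:
            k = fd.labels.index(lab)
            est = base + beta[k]
            var = base_var + 2 * Vc[k] + V[k, k]
        rows.append((line, trait, label, est, float(np.sqrt(max(var, 0.0)))))
    return pd.DataFrame(rows, columns=BLUE_COLUMNS)


def blues_per_timepoint(data: pd.DataFrame, trait: str = "") -> pd.DataFrame:
    """Cell-mean BLUEs per line x malting timepoint (labels "TP4", "TP6", ...).

    With a cell-means model the least-squares solution per line x timepoint is
    the plain mean over technical replicates; the standard error uses the
    pooled within-cell residual.  Lines absent at a timepoint are simply
    missing, never imputed.
    """
    d = data.dropna(subset=["value"])
    cells = d.groupby(["line_id", "timepoint"])["value"].agg(["mean", "size"]).reset_index()
    resid = d["value"].to_numpy(float) - d.merge(
        cells, on=["line_id", "timepoint"], how="left"
    )["mean"].to_numpy(float)
    dof = max(len(d) - len(cells), 1)
    s2 = float(np.sum(resid**2)) / dof
    out = pd.DataFrame(
        {
            "line_id": cells["line_id"],
            "trait": trait,
            "label": cells["timepoint"].astype(str),
            "estimate": cells["mean"],
            "se": np.sqrt(s2 / cells["size"]),
        }
    )
    return out[BLUE_COLUMNS]


def blues_across_timepoints(data: pd.DataFrame, trait: str = "", label: str = "TP4/TP6") -> pd.DataFrame:
    """Line BLUEs treating malting timepoints as replicates: Y = TP + line + e."""
    d = data.dropna(subset=["value"])
    if d["timepoint"].nunique() < 2:
        log.warning("blues_across_timepoints: single timepoint; equivalent to cell means")
    return _adjusted_line_means(d, ["timepoint"], label, trait)


def blues_across_years(
    data: pd.DataFrame,
    trait: str = "",
    label: str = "Combined",
) -> pd.DataFrame:
    """Across-year line BLUEs: Y = E + TP + E:TP + line, heterogeneous error by year.

    Per-year residual variances are estimated by REML on the residual layer
    and used as feasible-GLS weights.  If the variance fit does not converge
    the fit falls back to homogeneous weights with a warning.  A single year
    reduces to the timepoints-as-replicates model.
    """
    d = data.dropna(subset=["value"]).copy()
    years = d["year"].nunique()
    if years < 2:
        return blues_across_timepoints(d, trait=trait, label=label)
    covar = ["year", "timepoint", "year:timepoint"]
    spec = ModelSpec("value", tuple(covar + ["line_id"]), (), Residual("DIAG", ("year",)))
    weights = None
    scale = True
    try:
        vfit = fit_lmm(spec, d, n_starts=1)
        if vfit.converged:
            yvar = {}
            for k, v in vfit.varcomp.items():
                if k.startswith("sigma2:resid|year="):
                    yvar[k.split("=", 1)[1]] = v
            w = d["year"].astype(str).map(yvar).to_numpy(float)
            if np.all(np.isfinite(w)) and np.all(w > 0):
                weights, scale = 1.0 / w, False
        if weights is None:
            log.warning("blues_across_years: variance fit unusable; homogeneous fallback")
    except ModelError as exc:
        log.warning("blues_across_years: %s; homogeneous fallback", exc)
    return _adjusted_line_means(d, covar, label, trait, row_weights=weights, scale_vcov=scale)
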