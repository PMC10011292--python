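"""Variance partitioning of malting-quality assays and heritability.

Four nested analyses, per trait:

1. *Technical repeatability* - within one year x malting timepoint, the model
   ``Y = plot (random) + e`` separates plot variance from the assay's
   extraction error; the ratio sigma2_pl / (sigma2_pl + sigma2_e) is the
   repeatability of the assay.
2. *Within-year partition* - ``Y = TP (fixed) + line + line:TP + e`` splits
   line variance from line-by-timepoint deviations (sigma2_g:TP).
3. *Plot-error decomposition* - sigma2_g:TP confounds true after-ripening
   change with the plot-level sampling error sigma2_pltE.  The replicated
   check cultivar (grain from a single lot, inserted every 15 samples)
   estimates sigma2_pltE as the variance of check per-plot means minus the
   assay error scaled by the technical-replicate count, and
   sigma2_dgTP = sigma2_g:TP - sigma2_pltE isolates genuine phenotypic change
   during after-ripening.  Negative estimates are flagged, never clamped.
4. *Across-year model* - ``Y = year + TP + year:TP (fixed) + line + line:TP + e``,
   with heritability across y years H2 = sigma2_g / (sigma2_g + sigma2_g:TP +
   sigma2_e / y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phsmalt.mixedlm import ModelError, ModelSpec, RandomTerm, Residual, fit_lmm

log = logging.getLogger("phsmalt")


@dataclass
class VarianceComponents:
    """Variance components for one trait/scope, in trait units squared."""

    context: dict
    sigma2_g: float = np.nan
    sigma2_gTP: float = np.nan
    sigma2_error: float = np.nan
    sigma2_pl: float = np.nan
    sigma2_pltE: float = np.nan
    sigma2_dgTP: float = np.nan
    ratio1: float = np.nan  # sigma2_pltE / sigma2_g:TP
    ratio2: float = np.nan  # sigma2_dgTP / sigma2_g
    flags: list = field(default_factory=list)
    loglik: float = np.nan
    converged: bool = True

    def as_row(self) -> dict:
        row = dict(self.context)
        for k in (
            "sigma2_g",
            "sigma2_gTP",
            "sigma2_error",
            "sigma2_pl",
            "sigma2_pltE",
            "sigma2_dgTP",
            "ratio1",
            "ratio2",
        ):
            row[k] = getattr(self, k)
        row["flags"] = ";".join(self.flags)
        row["converged"] = self.converged
        return row


@dataclass
class HeritabilityEstimate:
    trait: str
    scope: str  # "across-years" or "per-year"
    H2: float
    y: int


def technical_repeatability(data: pd.DataFrame, value: str = "value") -> float:
    """Repeatability of the assay from technical replicates within plots.

    ``data`` is one trait x year x timepoint subset with >=2 tech reps for at
    least some plots.
    """
    reps = data.dropna(subset=[value]).groupby("plot_id")[value].size()
    if (reps < 2).all():
        raise ModelError("no plot has >=2 technical replicates; repeatability undefined")
    spec = ModelSpec(value, (), (RandomTerm("plot_id"),), Residual())
    fit = fit_lmm(spec, data)
    s_pl = fit.varcomp["sigma2:plot_id"]
    s_e = fit.varcomp["sigma2:resid"]
    tot = s_pl + s_e
    return s_pl / tot if tot > 0 else np.nan


def within_year_partition(data: pd.DataFrame, context: dict | None = None) -> VarianceComponents:
    """Model per trait x year: Y = TP + line + line:TP + e."""
    tps = data["timepoint"].dropna().unique()
    if len(tps) < 2:
        raise ModelError(
            "within-year partition needs >=2 malting timepoints; "
            "use technical_repeatability for a single timepoint"
        )
    spec = ModelSpec(
        "value",
        ("timepoint",),
        (RandomTerm("line_id"), RandomTerm("line_id:timepoint")),
        Residual(),
    )
    fit = fit_lmm(spec, data)
    return VarianceComponents(
        context=context or {},
        sigma2_g=fit.varcomp["sigma2:line_id"],
        sigma2_gTP=fit.varcomp["sigma2:line_id:timepoint"],
        sigma2_error=fit.varcomp["sigma2:resid"],
        loglik=fit.loglik,
        converged=fit.converged,
        flags=[] if fit.converged else ["nonconverged"],
    )


def check_plot_error(
    check_values: pd.DataFrame,
    assay_error: float,
    value: str = "value",
) -> tuple[float, list[str]]:
    """sigma2_pltE from the replicated check cultivar.

    ``check_values`` holds the check's raw observations (one row per tech rep)
    with a ``plot_id`` column.  Each check sample - a plot, or a plot x
    malting-timepoint combination when a ``timepoint`` column is present - is
    a separate draw of the plot-level sampling error, so sample means are
    formed per sampling event and their variance is pooled within timepoint
    (removing the aggregate after-ripening shift):

        sigma2_pltE = var(check sample means) - assay_error / mean(reps)

    Negative estimates are reported as-is with a flag.  Fewer than 5 check
    samples yields a wide-uncertainty flag.
    """
    flags: list[str] = []
    d = check_values.dropna(subset=[value])
    keys = ["plot_id"] + (["timepoint"] if "timepoint" in d.columns else [])
    means = d.groupby(keys)[value].agg(["mean", "size"])
    n_samples = len(means)
    if n_samples < 2:
        raise ModelError("need >=2 check samples to estimate plot-level error")
    if n_samples < 5:
        flags.append("few_checks")
        log.warning("check_plot_error: only %d check samples; estimate is uncertain", n_samples)
    mean_reps = float(means["size"].mean())
    if "timepoint" in keys:
        # pooled within-timepoint variance of the sample means
        grp = means.groupby(level="timepoint")["mean"]
        ss = float((grp.transform(lambda v: v - v.mean()) ** 2).sum())
        dof = n_samples - grp.ngroups
        var_means = ss / max(dof, 1)
    else:
        var_means = float(means["mean"].var(ddof=1))
    est = var_means - assay_error / mean_reps
    if est < 0:
        flags.append("negative")
    return est, flags


def delta_gtp(vc: VarianceComponents, sigma2_pltE: float) -> VarianceComponents:
    """Decompose sigma2_g:TP into after-ripening change and plot-level error.

    Returns the components object updated with sigma2_dgTP = sigma2_g:TP -
    sigma2_pltE, ratio1 = sigma2_pltE / sigma2_g:TP and ratio2 = sigma2_dgTP /
    sigma2_g.  A negative sigma2_dgTP (plot error exceeding the interaction
    variance) is flagged, not truncated.
    """
    if not np.isfinite(vc.sigma2_gTP):
        raise ModelError("run within_year_partition before delta_gtp")
    vc.sigma2_pltE = sigma2_pltE
    vc.sigma2_dgTP = vc.sigma2_gTP - sigma2_pltE
    if vc.sigma2_gTP > 0:
        vc.ratio1 = sigma2_pltE / vc.sigma2_gTP
    else:
        vc.ratio1 = np.nan
        vc.flags.append("ratio1_undefined")
    vc.ratio2 = vc.sigma2_dgTP / vc.sigma2_g if vc.sigma2_g > 0 else np.nan
    if vc.sigma2_dgTP < 0:
        vc.flags.append("negative_dgTP")
    return vc


def across_year_partition(data: pd.DataFrame, context: dict | None = None) -> VarianceComponents:
    """Model per trait, all years: Y = E + TP + E:TP (fixed) + line + line:TP + e."""
    if data["year"].nunique() < 2:
        raise ModelError("across-year partition needs >=2 years")
    spec = ModelSpec(
        "value",
        ("year", "timepoint", "year:timepoint"),
        (RandomTerm("line_id"), RandomTerm("line_id:timepoint")),
        Residual(),
    )
    fit = fit_lmm(spec, data)
    return VarianceComponents(
        context=context or {},
        sigma2_g=fit.varcomp["sigma2:line_id"],
        sigma2_gTP=fit.varcomp["sigma2:line_id:timepoint"],
        sigma2_error=fit.varcomp["sigma2:resid"],
        loglik=fit.loglik,
        converged=fit.converged,
        flags=[] if fit.converged else ["nonconverged"],
    )


def heritability(vc: VarianceComponents, y: int, trait: str = "") -> HeritabilityEstimate:
    """Across-year heritability H2 = s2_g / (s2_g + s2_g:TP + s2_e / y).

    With ``y = 1`` this reduces to the per-year form
    s2_g / (s2_g + s2_g:TP + s2_e).
    """
    if y < 1:
        raise ValueError("y must be >= 1")
    parts = np.array([vc.sigma2_g, vc.sigma2_gTP, vc.sigma2_error])
    if not np.all(np.isfinite(parts)) or parts.sum() <= 0:
        raise ModelError("heritability undefined: all variance components are zero or missing")
    h2 = vc.sigma2_g / (vc.sigma2_g + vc.sigma2_gTP + vc.sigma2_error / y)
    scope = "across-years" if y > 1 else "per-year"
    return HeritabilityEstimate(trait=trait, scope=scope, H2=float(h2), y=y)
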