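"""Correlated response to selection across breeding cycles.

Lines in the population come from successive cycles of index selection
targeted at PHS resistance (C0 base, C1P phenotypic, C1G genomic, C2G second
genomic cycle).  Per malting trait the model

    Y = year + cycle + TP + year:TP + TP:cycle + year:cycle (fixed)
        + line (random, one genetic variance per cycle)
        + e (one residual variance per year)

estimates cycle means relative to the C0 base (Wald t-tests) and per-cycle
genetic variances, compared against a homogeneous-variance model with a
likelihood-ratio test on n_cycles - 1 df.  Interaction terms whose
cycle-by-year or cycle-by-timepoint cells are empty are dropped with a logged
note (the design is unbalanced by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phsmalt.mixedlm import (
    ModelError,
    ModelSpec,
    RandomTerm,
    Residual,
    fit_lmm,
    lrt,
    wald_fixed,
)

log = logging.getLogger("phsmalt")

CYCLE_ORDER = ["C0", "C1P", "C1G", "C2G"]
STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for cut, stars in STAR_TIERS:
        if p < cut:
            return stars
    return ""


@dataclass
class SelectionResponseResult:
    trait: str
    cycle_effects: pd.DataFrame  # cycle, estimate, se, t, df, p, stars
    cycle_variances: dict[str, float]
    lrt_hom_vs_het: tuple[float, float]
    year_residuals: dict[str, float]
    flags: list = field(default_factory=list)
    loglik_het: float = np.nan
    loglik_hom: float = np.nan


def _complete_cells(data: pd.DataFrame, a: str, b: str) -> bool:
    obs = data.groupby([a, b], observed=True).size()
    la, lb = data[a].nunique(), data[b].nunique()
    return len(obs) == la * lb


def fit_selection_response(
    data: pd.DataFrame,
    trait: str = "",
    include_parents: bool = False,
    min_lines_per_cycle: int = 5,
    n_starts: int = 3,
) -> SelectionResponseResult:
    """Model-10-style fit for one trait; cycle contrasts are vs the C0 base."""
    d = data.dropna(subset=["value"]).copy()
    drop = {"CHECK"} | (set() if include_parents else {"PARENT"})
    d = d[~d["cycle"].isin(drop)]
    cycles = [c for c in CYCLE_ORDER if c in set(d["cycle"])]
    if len(cycles) < 2:
        raise ModelError("selection response needs >=2 cycles")
    d["cycle"] = pd.Categorical(d["cycle"], categories=cycles, ordered=True)

    flags: list[str] = []
    lines_per_cycle = d.groupby("cycle", observed=True)["line_id"].nunique()
    for c, nl in lines_per_cycle.items():
        if nl < min_lines_per_cycle:
            flags.append(f"unreliable_variance:{c}")
            log.warning("cycle %s has only %d lines; its variance is unreliable", c, nl)

    fixed = ["year", "cycle", "timepoint", "year:timepoint"]
    for term, (a, b) in (("timepoint:cycle", ("timepoint", "cycle")),
                         ("year:cycle", ("year", "cycle"))):
        if _complete_cells(d, a, b):
            fixed.append(term)
        else:
            log.info("selection response (%s): dropping %s (empty cells)", trait, term)
            flags.append(f"dropped:{term}")
    if d["year"].nunique() < 2:
        fixed = [t for t in fixed if "year" not in t]
    if d["timepoint"].nunique() < 2:
        fixed = [t for t in fixed if "timepoint" not in t]

    resid = Residual("DIAG", ("year",)) if d["year"].nunique() > 1 else Residual()
    spec_het = ModelSpec(
        "value", tuple(fixed), (RandomTerm("line_id", "DIAG", "cycle"),), resid
    )
    spec_hom = ModelSpec("value", tuple(fixed), (RandomTerm("line_id"),), resid)
    fit_het = fit_lmm(spec_het, d, n_starts=n_starts)
    fit_hom = fit_lmm(spec_hom, d, n_starts=n_starts)
    if not (fit_het.converged and fit_hom.converged):
        flags.append("nonconverged")
    stat, p_lrt = lrt(fit_het, fit_hom, df=len(cycles) - 1)

    wald = wald_fixed(fit_het)
    rows = []
    for c in cycles[1:]:
        lab = f"cycle[{c}]"
        row = wald[wald["effect"] == lab]
        if row.empty or bool(row["aliased"].iloc[0]):
            rows.append((c, np.nan, np.nan, np.nan, np.nan, np.nan, ""))
            continue
        r = row.iloc[0]
        rows.append((c, r["estimate"], r["se"], r["t"], r["df"], r["p"],
                     significance_stars(r["p"])))
    eff = pd.DataFrame(rows, columns=["cycle", "estimate", "se", "t", "df", "p", "stars"])

    cyc_var = {
        c: fit_het.varcomp[f"sigma2:line_id|cycle={c}"] for c in cycles
    }
    year_res = {
        k.split("=", 1)[1]: v
        for k, v in fit_het.varcomp.items()
        if k.startswith("sigma2:resid|year=")
    }
    if not year_res:
        year_res = {"all": fit_het.varcomp.get("sigma2:resid", np.nan)}
    return SelectionResponseResult(
        trait=trait,
        cycle_effects=eff,
        cycle_variances=cyc_var,
        lrt_hom_vs_het=(stat, p_lrt),
        year_residuals=year_res,
        flags=flags,
        loglik_het=fit_het.loglik,
        loglik_hom=fit_hom.loglik,
    )


def response_summary(
    result: SelectionResponseResult,
    phs_means: dict[str, float],
    trait_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-cycle reporting table: PHS mean, trait mean, mean +- 2 genetic SD.

    ``phs_means`` maps cycle -> mean GI at TP1 (the PHS-resistance axis);
    ``trait_means`` maps cycle -> observed trait mean (for display alongside
    the model-based contrasts).  The band halfwidth is two genetic standard
    deviations from the cycle's estimated genetic variance.
    """
    eff = result.cycle_effects.set_index("cycle")
    rows = []
    for cycle, s2 in result.cycle_variances.items():
        sd = float(np.sqrt(max(s2, 0.0)))
        mean = (trait_means or {}).get(cycle, np.nan)
        if cycle in eff.index:
            p = float(eff.loc[cycle, "p"])
            est = float(eff.loc[cycle, "estimate"])
            stars = eff.loc[cycle, "stars"]
        else:  # baseline
            p, est, stars = np.nan, 0.0, ""
        rows.append(
            {
                "trait": result.trait,
                "cycle": cycle,
                "phs_mean": phs_means.get(cycle, np.nan),
                "trait_mean": mean,
                "effect_vs_C0": est,
                "band_halfwidth": 2.0 * sd,
                "band_lo": mean - 2.0 * sd,
                "band_hi": mean + 2.0 * sd,
                "p": p,
                "stars": stars,
                "lrt_stat": result.lrt_hom_vs_het[0],
                "lrt_p": result.lrt_hom_vs_het[1],
            }
        )
    return pd.DataFrame(rows)
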