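"""Bivariate genetic correlations, HvMKK3 allele stratification, and
phenotypic-correlation biplots.

The genetic correlation between a malting trait and a germination trait is
estimated from a bivariate mixed model on plot-level means (technical
replicates averaged so observations pair by plot):

    Y_ty = trait-by-year cell means (fixed) + g_t (line, 2x2 unstructured)
           + e_ty (heterogeneous by trait x year, zero cross-trait covariance)

with r_g = cov_g / sqrt(sigma2_gA * sigma2_gB), tested against the diagonal
line structure with a 1-df likelihood-ratio test.  Residual cross-trait
covariance is fixed at zero: the two traits are measured on different grain
samples from the plot, and with one plot per line per trial such a covariance
is near-unidentifiable.

Because a large-effect dormancy locus can drive genome-wide correlations, all
scans run across lines and within each HvMKK3 allele group (dormant D,
non-dormant N, highly non-dormant N*), classified from the E165Q causal SNP
and a linked 50k array marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phsmalt.mixedlm import ModelError, ModelSpec, RandomTerm, Residual, fit_lmm, lrt

log = logging.getLogger("phsmalt")

ALLELES = ("D", "N", "Nstar")
GROUPS = ("ALL",) + ALLELES

#: (E165Q call, linked-50k call) -> HvMKK3 allele.  The 50k marker allele
#: assignment is configurable; this default maps allele A to the non-dormant
#: background and B to the dormant one.
DEFAULT_MKK3_MAP = {
    ("MUT", "A"): "Nstar",
    ("MUT", "B"): "Nstar",
    ("MUT", "MISSING"): "Nstar",
    ("WT", "A"): "N",
    ("WT", "B"): "D",
}

E165Q_MARKER = "MKK3_E165Q"
LINKED_MARKER = "JHI-Hv50k-2016-367342"
STAR_P = 0.01  # significance-star threshold for scan output


def classify_mkk3(e165q: str, linked50k: str, mapping: dict | None = None) -> str:
    """HvMKK3 allele call from the two diagnostic markers.

    The E165Q mutation defines the highly non-dormant allele (N*); among
    wild-type lines the linked 50k marker separates N from D.  Any call that
    the mapping cannot resolve (including MISSING) yields UNKNOWN, which
    excludes the line from within-allele analyses.
    """
    mapping = DEFAULT_MKK3_MAP if mapping is None else mapping
    return mapping.get((e165q, linked50k), "UNKNOWN")


def mkk3_calls(markers: pd.DataFrame, mapping: dict | None = None) -> pd.DataFrame:
    """Per-line HvMKK3 allele table from a long marker table.

    The E165Q KASP marker is stored with genotype B = mutant, A = wild type.
    """
    wide = markers.pivot_table(
        index="line_id", columns="marker_id", values="genotype", aggfunc="first"
    )
    out = pd.DataFrame(index=wide.index)
    e = wide.get(E165Q_MARKER, pd.Series("MISSING", index=wide.index))
    out["e165q"] = e.map({"B": "MUT", "A": "WT", "HET": "HET"}).fillna("MISSING")
    out["linked50k"] = wide.get(LINKED_MARKER, pd.Series("MISSING", index=wide.index)).fillna(
        "MISSING"
    )
    out["allele"] = [
        classify_mkk3(a, b, mapping) for a, b in zip(out["e165q"], out["linked50k"])
    ]
    return out.reset_index()


@dataclass
class GeneticCorrelationResult:
    trait_pair: tuple[str, str]
    group: str
    timepoint: str | None
    r_g: float
    var_a: float
    var_b: float
    cov_g: float
    lrt_stat: float
    p: float
    n_lines: int
    flags: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "trait_a": self.trait_pair[0],
            "trait_b": self.trait_pair[1],
            "group": self.group,
            "timepoint": self.timepoint,
            "r_g": self.r_g,
            "var_a": self.var_a,
            "var_b": self.var_b,
            "cov_g": self.cov_g,
            "lrt_stat": self.lrt_stat,
            "p": self.p,
            "star": "*" if np.isfinite(self.p) and self.p < STAR_P else "",
            "n_lines": self.n_lines,
            "flags": ";".join(self.flags),
        }


def genetic_correlation(
    pairs: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    group: str = "ALL",
    timepoint: str | None = None,
    min_lines: int = 30,
    n_starts: int = 3,
) -> GeneticCorrelationResult:
    """Bivariate REML genetic correlation from paired plot-level means.

    ``pairs`` needs columns line_id, year, value_a, value_b with one row per
    plot (plot-level means).  Rows missing both traits are dropped; a plot
    with one trait still contributes to that trait's variance.
    """
    flags: list[str] = []
    d = pairs.copy()
    n_lines = d.loc[d[["value_a", "value_b"]].notna().any(axis=1), "line_id"].nunique()
    if n_lines < min_lines:
        flags.append("low_n")
    stacked = pd.concat(
        [
            d.assign(trait="A", value=d["value_a"]),
            d.assign(trait="B", value=d["value_b"]),
        ],
        ignore_index=True,
    ).dropna(subset=["value"])
    fixed = ("trait", "year", "trait:year") if d["year"].nunique() > 1 else ("trait",)
    resid_by = ("trait", "year") if d["year"].nunique() > 1 else ("trait",)
    spec = ModelSpec(
        "value",
        fixed,
        (RandomTerm("line_id", "US2", "trait"),),
        Residual("DIAG", resid_by),
    )
    spec0 = ModelSpec(
        "value",
        fixed,
        (RandomTerm("line_id", "DIAG", "trait"),),
        Residual("DIAG", resid_by),
    )
    try:
        fit = fit_lmm(spec, stacked, n_starts=n_starts)
        fit0 = fit_lmm(spec0, stacked, n_starts=n_starts)
    except ModelError as exc:
        log.warning("genetic_correlation(%s,%s,%s): %s", trait_a, trait_b, group, exc)
        return GeneticCorrelationResult(
            (trait_a, trait_b), group, timepoint, np.nan, np.nan, np.nan, np.nan,
            np.nan, np.nan, n_lines, flags + ["fit_failed"],
        )
    if not (fit.converged and fit0.converged):
        flags.append("nonconverged")
    va = fit.varcomp["sigma2:line_id|trait=A"]
    vb = fit.varcomp["sigma2:line_id|trait=B"]
    cov = fit.varcomp["cov:line_id|trait"]
    rg = fit.varcomp["corr:line_id|trait"]
    if not np.isfinite(rg):
        flags.append("undefined")
    elif abs(rg) > 0.9999:
        flags.append("boundary")
    stat, p = lrt(fit, fit0, df=1)
    return GeneticCorrelationResult(
        (trait_a, trait_b), group, timepoint, float(rg), va, vb, cov, stat, p, n_lines, flags
    )


def correlation_scan(
    malt_means: pd.DataFrame,
    germ_summary: pd.DataFrame,
    malt_traits: list[str],
    germ_trait: str = "GI",
    timepoints: list[str] | None = None,
    groups: list[str] | None = None,
    mkk3: pd.DataFrame | None = None,
    min_lines: int = 30,
    n_starts: int = 3,
) -> list[GeneticCorrelationResult]:
    """Genetic correlations of each malting trait with GE/GI per timepoint.

    ``malt_means``: plot-level malt means with columns plot_id, line_id, year,
    trait, value (technical reps and malting timepoints already averaged).
    ``germ_summary``: plot germination summaries with GE/GI per timepoint.
    ``groups`` beyond ALL require an ``mkk3`` allele table; a group/timepoint
    with no data yields a gap, not a failure.
    """
    timepoints = timepoints or sorted(germ_summary["timepoint"].unique())
    groups = list(groups or GROUPS)
    results: list[GeneticCorrelationResult] = []
    allele_of = None
    if mkk3 is not None:
        allele_of = mkk3.set_index("line_id")["allele"]
    malt_wide = malt_means.pivot_table(
        index=["plot_id", "line_id", "year"], columns="trait", values="value", aggfunc="mean"
    ).reset_index()
    for tp in timepoints:
        germ_tp = germ_summary.loc[
            germ_summary["timepoint"] == tp, ["plot_id", "line_id", "year", germ_trait]
        ]
        merged = malt_wide.merge(germ_tp, on=["plot_id", "line_id", "year"], how="inner")
        for grp in groups:
            sub = merged
            if grp != "ALL":
                if allele_of is None:
                    log.warning("correlation_scan: no MKK3 table; skipping group %s", grp)
                    continue
                sub = merged[merged["line_id"].map(allele_of) == grp]
            if sub.empty:
                continue
            for trait in malt_traits:
                if trait not in sub.columns:
                    continue
                pairs = sub.rename(columns={trait: "value_a", germ_trait: "value_b"})[
                    ["line_id", "year", "value_a", "value_b"]
                ]
                res = genetic_correlation(
                    pairs,
                    trait,
                    f"{germ_trait}_{tp}",
                    group=grp,
                    timepoint=tp,
                    min_lines=min_lines,
                    n_starts=n_starts,
                )
                results.append(res)
    return results


def scan_to_table(results: list[GeneticCorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def phenotypic_correlation_matrix(blues: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pearson correlations of scaled-and-centred line BLUEs, pairwise complete.

    ``blues`` is wide: one row per line, one column per trait.  Traits with
    zero variance are excluded with a warning.
    """
    cols = []
    for t in traits:
        if t not in blues.columns:
            log.warning("phenotypic_correlation_matrix: trait %s missing", t)
            continue
        v = blues[t].astype(float)
        if np.nanstd(v) <= 0 or v.notna().sum() < 3:
            log.warning("phenotypic_correlation_matrix: trait %s has no variance; excluded", t)
            continue
        cols.append(t)
    z = (blues[cols] - blues[cols].mean()) / blues[cols].std(ddof=1)
    corr = z.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def biplot_decomposition(corr: pd.DataFrame) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Eigen-decomposition of a trait correlation matrix for PC1-PC2 biplots.

    Loadings are eigenvectors scaled by sqrt(eigenvalue); variance explained
    is the top-two eigenvalues over the trace.  Small negative eigenvalues
    from pairwise completion are clipped at zero with a warning.
    """
    M = np.asarray(corr, float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(M)
    if vals.min() < -1e-10:
        log.warning("biplot: clipping %d negative eigenvalue(s)", int((vals < 0).sum()))
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = float(vals.sum())
    load = vecs[:, :2] * np.sqrt(vals[:2])
    names = list(corr.columns) if isinstance(corr, pd.DataFrame) else None
    loadings = pd.DataFrame(load, columns=["PC1", "PC2"], index=names)
    ve = (float(vals[0] / trace), float(vals[1] / trace)) if trace > 0 else (np.nan, np.nan)
    return loadings, ve
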