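"""End-to-end orchestration: simulate -> germination -> variance partition ->
BLUEs -> genetic correlations -> selection response -> quality scoring.

Stages exchange CSV files inside one output directory, so each stage is
independently testable and resumable; a manifest records the config digest,
seed, package version and a hash of every output.  A stage failure halts the
run with the stage name, keeping partial outputs on disk.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from phsmalt import __version__, germination, io
from phsmalt.blues import blues_across_years
from phsmalt.config import ALL_STAGES, RunConfig
from phsmalt.correlations import (
    biplot_decomposition,
    correlation_scan,
    mkk3_calls,
    phenotypic_correlation_matrix,
    scan_to_table,
)
from phsmalt.mixedlm import ModelError
from phsmalt.scoring import ScoreConfig, score_table
from phsmalt.selection import fit_selection_response, response_summary
from phsmalt.simulate import CHECK_LINE, simulate, truth_report
from phsmalt.variance import (
    across_year_partition,
    check_plot_error,
    delta_gtp,
    heritability,
    technical_repeatability,
    within_year_partition,
)

log = logging.getLogger("phsmalt")


class PipelineError(RuntimeError):
    pass


def _need(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise PipelineError(f"stage '{stage}' requires missing input file: {p}")
    return p


def _malt_plot_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Plot-level malt means: technical reps averaged within plot x trait x TP."""
    return pheno.dropna(subset=["value"]).groupby(
        ["plot_id", "line_id", "year", "trait", "timepoint"], as_index=False
    )["value"].mean()


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    res = simulate(cfg.sim_config(), cfg.seed)
    io.write_table(res.phenotypes, out / "phenotypes.csv")
    io.write_table(res.plates, out / "plates.csv")
    io.write_table(res.lines, out / "lines.csv")
    io.write_table(res.markers, out / "markers.csv")
    for name, df in truth_report(res.truth).items():
        io.write_table(df, out / f"{name}.csv")


def stage_germination(cfg: RunConfig, out: Path) -> None:
    plates = pd.read_csv(_need(out, "plates.csv", "germination"))
    summary = germination.plot_germination_means(plates)
    io.write_table(summary, out / "germination_summary.csv")


def stage_partition(cfg: RunConfig, out: Path) -> None:
    pheno = io.read_phenotypes(_need(out, "phenotypes.csv", "partition"))
    means = _malt_plot_means(pheno)
    traits = cfg.partition_traits or sorted(pheno["trait"].unique())
    vc_rows, h2_rows = [], []
    for trait in traits:
        sub_all = pheno[(pheno["trait"] == trait) & (pheno["line_id"] != CHECK_LINE)]
        checks = pheno[(pheno["trait"] == trait) & (pheno["line_id"] == CHECK_LINE)]
        # technical repeatability + within-year decomposition per year
        for year, sub in sub_all.groupby("year"):
            tps = sorted(sub["timepoint"].unique())
            rep_vals = [
                technical_repeatability(sub[sub["timepoint"] == tp]) for tp in tps
            ]
            assay_err = np.nan
            try:
                # assay error from the repeatability model's residual layer
                fitsub = sub.groupby(["plot_id", "timepoint"])["value"]
                within = fitsub.var(ddof=1).dropna()
                assay_err = float(within.mean())
            except Exception:  # pragma: no cover
                pass
            if len(tps) < 2:
                continue
            vc = within_year_partition(
                sub, context={"trait": trait, "scope": f"within-{year}"}
            )
            ysub = checks[checks["year"] == year]
            if ysub["plot_id"].nunique() >= 2 and np.isfinite(assay_err):
                pltE, flags = check_plot_error(ysub, assay_err)
                vc = delta_gtp(vc, pltE)
                vc.flags.extend(flags)
            row = vc.as_row()
            row["technical_repeatability"] = float(np.nanmean(rep_vals))
            vc_rows.append(row)
            h2_rows.append(heritability(vc, 1, trait=trait).__dict__ | {"year": year})
        # across-year model + heritability
        try:
            vca = across_year_partition(
                sub_all, context={"trait": trait, "scope": "across-years"}
            )
            vc_rows.append(vca.as_row())
            ny = sub_all["year"].nunique()
            h2_rows.append(heritability(vca, ny, trait=trait).__dict__ | {"year": "all"})
        except ModelError as exc:
            log.warning("partition(%s): %s", trait, exc)
    io.write_table(pd.DataFrame(vc_rows), out / "varcomp.csv")
    io.write_table(pd.DataFrame(h2_rows), out / "heritability.csv")
    io.write_table(means, out / "malt_plot_means.csv")


def stage_blues(cfg: RunConfig, out: Path) -> None:
    means = pd.read_csv(_need(out, "malt_plot_means.csv", "blues"))
    means = means[means["line_id"] != CHECK_LINE]
    tables = []
    for trait, d in means.groupby("trait"):
        tables.append(blues_across_years(d, trait=trait, label="Combined"))
        for tp, dtp in d.groupby("timepoint"):
            if dtp["year"].nunique() >= 1:
                tables.append(blues_across_years(dtp, trait=trait, label=str(tp)))
    io.write_table(pd.concat(tables, ignore_index=True), out / "blues.csv")


def stage_correlations(cfg: RunConfig, out: Path) -> None:
    means = pd.read_csv(_need(out, "malt_plot_means.csv", "correlations"))
    germ = pd.read_csv(_need(out, "germination_summary.csv", "correlations"))
    markers = io.read_markers(_need(out, "markers.csv", "correlations"))
    means = means[means["line_id"] != CHECK_LINE]
    mkk3 = mkk3_calls(markers)
    results = correlation_scan(
        means,
        germ,
        malt_traits=cfg.scan_traits,
        germ_trait=cfg.germ_trait,
        timepoints=[tp for tp in cfg.scan_timepoints if tp in set(germ["timepoint"])],
        groups=cfg.scan_groups,
        mkk3=mkk3,
        min_lines=cfg.min_lines,
        n_starts=cfg.n_starts,
    )
    io.write_table(scan_to_table(results), out / "genetic_correlations.csv")

    # phenotypic correlations + biplot from Combined BLUEs and line GI means
    blues = pd.read_csv(_need(out, "blues.csv", "correlations"))
    wide = (
        blues[blues["label"] == "Combined"]
        .pivot_table(index="line_id", columns="trait", values="estimate")
        .reset_index()
    )
    gi = (
        germ[germ["timepoint"].isin(cfg.scan_timepoints)]
        .groupby(["line_id", "timepoint"])[cfg.germ_trait]
        .mean()
        .unstack()
        .rename(columns=lambda tp: f"{cfg.germ_trait}_{tp}")
        .reset_index()
    )
    wide = wide.merge(gi, on="line_id", how="left")
    traits = [c for c in wide.columns if c != "line_id"]
    corr = phenotypic_correlation_matrix(wide, traits)
    io.write_table(corr.reset_index(names="trait"), out / "phenotypic_correlations.csv")
    loadings, ve = biplot_decomposition(corr)
    loadings = loadings.reset_index(names="trait")
    loadings["var_explained_PC1"] = ve[0]
    loadings["var_explained_PC2"] = ve[1]
    io.write_table(loadings, out / "biplot_loadings.csv")


def stage_selection(cfg: RunConfig, out: Path) -> None:
    means = pd.read_csv(_need(out, "malt_plot_means.csv", "selection"))
    germ = pd.read_csv(_need(out, "germination_summary.csv", "selection"))
    lines = io.read_lines(_need(out, "lines.csv", "selection"))
    cyc = lines.set_index("line_id")["cycle"]
    means = means.assign(cycle=means["line_id"].map(cyc))
    phs = (
        germ[germ["timepoint"] == "TP1"]
        .assign(cycle=lambda d: d["line_id"].map(cyc))
        .groupby("cycle")["GI"]
        .mean()
        .to_dict()
    )
    rows = []
    for trait in cfg.selection_traits or cfg.scan_traits:
        d = means[means["trait"] == trait]
        if d.empty:
            continue
        try:
            res = fit_selection_response(d, trait=trait, n_starts=cfg.n_starts)
        except ModelError as exc:
            log.warning("selection(%s): %s", trait, exc)
            continue
        obs_means = d.groupby(d["line_id"].map(cyc))["value"].mean().to_dict()
        rows.append(response_summary(res, phs, trait_means=obs_means))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    io.write_table(table, out / "selection_response.csv")


def stage_scoring(cfg: RunConfig, out: Path) -> None:
    blues = pd.read_csv(_need(out, "blues.csv", "scoring"))
    wide = (
        blues[blues["label"] == "Combined"]
        .pivot_table(index="line_id", columns="trait", values="estimate")
        .reset_index()
    )
    sc = (
        ScoreConfig.from_yaml(cfg.scoring_config)
        if cfg.scoring_config
        else ScoreConfig.default()
    )
    io.write_table(score_table(wide, sc), out / "scores.csv")


_STAGE_FN = {
    "simulate": stage_simulate,
    "germination": stage_germination,
    "partition": stage_partition,
    "blues": stage_blues,
    "correlations": stage_correlations,
    "selection": stage_selection,
    "scoring": stage_scoring,
}


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None,
                 stages: tuple | None = None) -> Path:
    """Run the enabled stages in order and write a manifest.  Deterministic
    under a fixed seed."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages or cfg.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in ALL_STAGES if s in stages]
    for stage in ordered:
        log.info("stage %s ...", stage)
        try:
            _STAGE_FN[stage](cfg, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    _write_manifest(cfg, out, ordered)
    return out


def _write_manifest(cfg: RunConfig, out: Path, stages) -> None:
    lines = [
        f"phsmalt_version={__version__}",
        f"seed={cfg.seed}",
        f"config_digest={cfg.digest()}",
        f"stages={','.join(stages)}",
    ]
    for p in sorted(out.glob("*.csv")):
        h = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        lines.append(f"sha256:{p.name}={h}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
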