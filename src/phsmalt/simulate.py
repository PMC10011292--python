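"""Synthetic spring-barley breeding population with a pleiotropic dormancy locus.

The generator emulates the study design every analysis stage assumes:

* seven half-sib families from crosses of family parents to one common
  parent, a C0 base population, and selected cycles C1P (phenotypic index),
  C1G and C2G (genomic index), with default sizes 105/108/87/114;
* a tri-allelic major dormancy locus (alleles D, N, N*) controlling the
  after-ripening trajectory of germination and acting pleiotropically on
  malting traits, on top of an infinitesimal polygenic background with a
  configurable genetic correlation matrix;
* three trial years; 30-kernel germination plates in duplicate at seven
  after-ripening timepoints (6-160 days post physiological maturity);
  malting at TP4/TP6 (TP6 only in the first year) with duplicate or
  triplicate technical replicates per assay; a check cultivar from a single
  grain lot inserted every 15 samples;
* plot-level sampling error (sigma2_pltE), genuine line-by-timepoint
  after-ripening change (sigma2_dgTP) and per-year assay error, so the
  check-based variance decomposition has a known truth.

Germination plates are drawn per kernel: capacity (GE) and mean germination
day follow saturating after-ripening curves per allele, shifted by the line's
polygenic value, calibrated so the expectation of the plate GI statistic
tracks the latent line GI.  Every latent value is recorded in a
:class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("phsmalt")

TIMEPOINT_DAYS = {"TP1": 6, "TP2": 20, "TP3": 34, "TP4": 48, "TP5": 69, "TP6": 110, "TP7": 160}
GERM_TIMEPOINTS = tuple(TIMEPOINT_DAYS)
CHECK_LINE = "CHECK_Tradition"


@dataclass(frozen=True)
class TraitDef:
    """One malting-quality trait: scale, genetics and error structure."""

    mean: float
    g_sd: float  # polygenic genetic SD
    eff_N: float  # additive deviation of the N allele vs D
    eff_Nstar: float  # deviation of the N* allele vs D
    pltE_sd: float  # plot-level sampling error SD (per plot x malting TP)
    dgtp_sd: float  # genuine after-ripening change SD (per line x malting TP)
    assay_sd: float  # technical / extraction error SD (per tech rep)
    tech_reps: int  # technical replicates per plot x malting TP
    tp6_shift: float  # fixed TP6-vs-TP4 shift (aggregate after-ripening trend)


@dataclass(frozen=True)
class AlleleCurve:
    """After-ripening kinetics of one HvMKK3 allele.

    Mean germination day decays as d(t) = 1 + 2 exp(-t / tau_day); capacity
    rises as GE(t) = ge_max (1 - exp(-t / tau_ge)); the latent germination
    rate is GI(t) = 10 GE(t) / d(t), a saturating curve in days post PM.
    """

    tau_day: float
    tau_ge: float
    ge_max: float = 0.98


DEFAULT_ALLELE_CURVES = {
    "D": AlleleCurve(tau_day=60.0, tau_ge=40.0),
    "N": AlleleCurve(tau_day=15.0, tau_ge=10.0),
    "Nstar": AlleleCurve(tau_day=4.0, tau_ge=3.0),
}

DEFAULT_TRAITS = {
    "AA": TraitDef(55.0, 6.0, 3.0, 9.0, 3.0, 1.5, 3.0, 3, 1.0),
    "DP": TraitDef(140.0, 12.0, 2.0, 6.0, 6.0, 3.0, 7.0, 3, 2.0),
    "FAN": TraitDef(190.0, 20.0, 10.0, 32.0, 9.0, 5.0, 10.0, 3, 6.0),
    "BG": TraitDef(180.0, 55.0, -20.0, -60.0, 30.0, 20.0, 35.0, 3, -25.0),
    "ME": TraitDef(79.5, 1.0, 0.2, 0.6, 0.5, 0.3, 0.5, 2, 0.2),
    "SP": TraitDef(5.6, 0.45, 0.15, 0.45, 0.2, 0.1, 0.2, 2, 0.1),
    "MP": TraitDef(11.8, 0.7, 0.0, 0.1, 0.3, 0.15, 0.35, 2, 0.0),
    "ST": TraitDef(47.0, 3.5, 1.2, 3.5, 1.5, 0.8, 1.8, 2, 0.8),
}

#: within-allele genetic correlation of each malting trait with the latent
#: germination-rate line effect
DEFAULT_GI_CORR = {
    "AA": 0.40, "DP": 0.10, "FAN": 0.50, "BG": -0.35,
    "ME": 0.20, "SP": 0.45, "MP": 0.10, "ST": 0.40,
}

DEFAULT_MALT_CORR = {
    ("FAN", "SP"): 0.70, ("FAN", "ST"): 0.50, ("SP", "ST"): 0.60,
    ("AA", "DP"): 0.50, ("FAN", "AA"): 0.35, ("SP", "MP"): 0.30,
    ("BG", "FAN"): -0.30, ("BG", "SP"): -0.25, ("BG", "ST"): -0.25,
    ("ME", "SP"): 0.30, ("ME", "FAN"): 0.25,
}


@dataclass
class SimConfig:
    cycle_sizes: dict = field(
        default_factory=lambda: {"C0": 105, "C1P": 108, "C1G": 87, "C2G": 114}
    )
    n_families: int = 7
    years: tuple = (2019, 2020, 2021)
    germ_timepoints: tuple = GERM_TIMEPOINTS
    germ_reps: int = 2
    n_plated: int = 30
    malt_timepoints: dict = field(
        default_factory=lambda: {2019: ("TP6",), 2020: ("TP4", "TP6"), 2021: ("TP4", "TP6")}
    )
    traits: dict = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    gi_sd: float = 0.9  # polygenic SD of the latent GI line effect
    gi_year_sd: float = 0.4
    gi_plot_sd: float = 0.3
    gi_corr: dict = field(default_factory=lambda: dict(DEFAULT_GI_CORR))
    malt_corr: dict = field(default_factory=lambda: dict(DEFAULT_MALT_CORR))
    allele_curves: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_CURVES))
    # common parent first; mirrors an N*-carrying common parent crossed to a
    # mix of dormant/non-dormant family parents
    parent_alleles: tuple = ("Nstar", "D", "N", "D", "N", "D", "N", "Nstar")
    parent_blocks: int = 2  # parents replicated across blocks (augmented design)
    # half-sib family structure (crosses to a common parent).  False draws C0
    # lines i.i.d. from the polygenic covariance (panel-style), so the realized
    # moments match the configured ones exactly in expectation - used by
    # calibration and recovery scenarios.
    family_structure: bool = True
    year_effect_frac: float = 0.5  # year main-effect SD as fraction of g_sd
    check_interval: int = 15
    selection_frac: float = 0.25
    per_family_selected: int = 2  # C1 parents picked per half-sib family
    index_weights: dict = field(default_factory=lambda: {"GI_TP1": 1.0, "MP": 0.15})
    phen_index_noise: dict = field(default_factory=lambda: {"GI_TP1": 1.0, "MP": 0.5})
    genomic_accuracy_noise: float = 0.6  # imperfect genomic prediction, GI units
    selection_modes: dict = field(
        default_factory=lambda: {"C1P": "phenotypic", "C1G": "genomic", "C2G": "genomic"}
    )
    # C1 parents are chosen within families (as in the emulated scheme); C2
    # uses mass truncation selection on the source cycle
    selection_scheme: dict = field(
        default_factory=lambda: {"C1P": "family", "C1G": "family", "C2G": "mass"}
    )
    cycle_source: dict = field(
        default_factory=lambda: {"C1P": "C0", "C1G": "C0", "C2G": "C1G"}
    )
    n_qc_markers: int = 40

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def genetic_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Polygenic covariance over (malt traits..., GI latent); PSD-repaired."""
        names = self.trait_names + ["GI"]
        k = len(names)
        corr = np.eye(k)
        idx = {n: i for i, n in enumerate(names)}
        for (a, b), r in self.malt_corr.items():
            if a in idx and b in idx:
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        for t, r in self.gi_corr.items():
            if t in idx:
                corr[idx[t], idx["GI"]] = corr[idx["GI"], idx[t]] = r
        # clip eigenvalues and renormalise to a valid correlation matrix
        vals, vecs = np.linalg.eigh(corr)
        if vals.min() < 1e-8:
            corr = vecs @ np.diag(np.clip(vals, 1e-8, None)) @ vecs.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        sds = np.array([self.traits[t].g_sd for t in self.trait_names] + [self.gi_sd])
        cov = corr * np.outer(sds, sds)
        return cov, names


@dataclass
class Population:
    """Simulated lines with alleles and polygenic values (incl. latent GI)."""

    lines: pd.DataFrame  # line_id, cycle, family, allele
    z: np.ndarray  # (n_lines, n_traits + 1), order = trait_names + ["GI"]
    value_names: list[str]
    config: SimConfig


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    line_values: pd.DataFrame
    r_g: pd.DataFrame  # realized genetic correlations per group
    varcomp: pd.DataFrame  # per-trait true variance components
    cycle_means: pd.DataFrame
    nstar_freq: pd.DataFrame
    seed: int


@dataclass
class SimResult:
    phenotypes: pd.DataFrame
    plates: pd.DataFrame
    lines: pd.DataFrame
    markers: pd.DataFrame
    truth: SyntheticTruth


def latent_gi(cfg: SimConfig, allele, z_gi, t_days: float) -> np.ndarray:
    """Latent line germination rate at ``t_days`` post PM, clipped to [0, 10]."""
    allele = np.asarray(allele)
    z_gi = np.asarray(z_gi, float)
    out = np.empty(allele.shape, float)
    for a, curve in cfg.allele_curves.items():
        m = allele == a
        if not m.any():
            continue
        ge = curve.ge_max * (1.0 - np.exp(-t_days / curve.tau_ge))
        d = 1.0 + 2.0 * np.exp(-t_days / curve.tau_day)
        out[m] = 10.0 * ge / d
    return np.clip(out + z_gi, 0.0, 10.0)


def _allele_effect(cfg: SimConfig, trait: str, allele) -> np.ndarray:
    td = cfg.traits[trait]
    eff = {"D": 0.0, "N": td.eff_N, "Nstar": td.eff_Nstar}
    return np.array([eff[a] for a in np.asarray(allele)])


def simulate_founders_and_cycles(cfg: SimConfig, seed: int) -> Population:
    """Create parents, the C0 base and the selected cycles.

    Progeny receive the polygenic mid-parent value plus a segregation draw at
    half the polygenic covariance, and inherit the major-locus allele of one
    random parent (lines are inbred, carrying a single allele).  C1/C2 lines
    come from truncation selection on the configured index (phenotypic for
    C1P, true breeding values for the genomic cycles) followed by random
    mating among the selected fraction.
    """
    rng = np.random.default_rng(seed)
    cov, names = cfg.genetic_covariance()
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(names)))
    k = len(names)

    def draw(n):
        return rng.standard_normal((n, k)) @ L.T

    n_par = len(cfg.parent_alleles)
    z_par = draw(n_par)
    rows = [
        {"line_id": f"P{i}", "cycle": "PARENT", "family": None, "allele": a}
        for i, a in enumerate(cfg.parent_alleles)
    ]
    z_all = [z_par]
    alleles = list(cfg.parent_alleles)

    def cross(i_mother: np.ndarray, i_father: np.ndarray, ids, cycle, fams):
        zm, zf = z_stack[i_mother], z_stack[i_father]
        seg = rng.standard_normal((len(ids), k)) @ (L.T * np.sqrt(0.5))
        z_child = 0.5 * (zm + zf) + seg
        pick = rng.integers(0, 2, len(ids))
        al = np.where(pick == 0, np.array(alleles)[i_mother], np.array(alleles)[i_father])
        for lid, cyc, fam, a in zip(ids, [cycle] * len(ids), fams, al):
            rows.append({"line_id": lid, "cycle": cyc, "family": fam, "allele": a})
        z_all.append(z_child)
        alleles.extend(al)

    # C0: stratified sampling of the seven half-sib families (common parent 0)
    z_stack = np.vstack(z_all)
    n_c0 = cfg.cycle_sizes.get("C0", 0)
    fam_parent = 1 + (np.arange(n_c0) % cfg.n_families)
    ids = [f"C0_{i:04d}" for i in range(n_c0)]
    if cfg.family_structure:
        cross(np.zeros(n_c0, dtype=int), fam_parent, ids, "C0",
              [f"F{f}" for f in fam_parent])
    else:  # unrelated panel: i.i.d. polygenic values, alleles from the pool
        z_all.append(draw(n_c0))
        al = rng.choice(np.array(cfg.parent_alleles), n_c0)
        alleles.extend(al)
        for lid, fam, a in zip(ids, fam_parent, al):
            rows.append({"line_id": lid, "cycle": "C0", "family": f"F{fam}", "allele": a})
    z_stack = np.vstack(z_all)

    df = pd.DataFrame(rows)

    def index_values(idx: np.ndarray, mode: str) -> np.ndarray:
        vals = np.zeros(len(idx))
        for tname, w in cfg.index_weights.items():
            if not tname.startswith("GI_") and tname not in cfg.traits:
                continue  # index component not simulated in this scenario
            if tname.startswith("GI_"):
                t = TIMEPOINT_DAYS[tname.split("_", 1)[1]]
                x = latent_gi(cfg, df["allele"].to_numpy()[idx], z_stack[idx, -1], t)
            else:
                x = cfg.traits[tname].mean + _allele_effect(
                    cfg, tname, df["allele"].to_numpy()[idx]
                ) + z_stack[idx, names.index(tname)]
            if mode == "phenotypic":
                x = x + rng.normal(0.0, cfg.phen_index_noise.get(tname, 0.0), len(idx))
            elif mode == "genomic" and tname.startswith("GI_"):
                x = x + rng.normal(0.0, cfg.genomic_accuracy_noise, len(idx))
            vals += w * x
        return vals

    for cyc in ("C1P", "C1G", "C2G"):
        n_child = cfg.cycle_sizes.get(cyc, 0)
        if n_child <= 0:
            continue
        src = cfg.cycle_source[cyc]
        cand = np.where(df["cycle"].to_numpy() == src)[0]
        iv = index_values(cand, cfg.selection_modes[cyc])
        if cfg.selection_scheme.get(cyc, "mass") == "family":
            # best per_family_selected individuals within every family
            fams = df["family"].to_numpy()[cand]
            sel_list = []
            for fam in pd.unique(fams):
                m = fams == fam
                order = np.argsort(iv[m], kind="stable")[: cfg.per_family_selected]
                sel_list.append(cand[m][order])
            sel = np.concatenate(sel_list)
        else:
            n_sel = max(2, int(np.ceil(cfg.selection_frac * len(cand))))
            sel = cand[np.argsort(iv, kind="stable")[:n_sel]]  # low index = resistant
        mothers = rng.choice(sel, n_child)
        fathers = rng.choice(sel, n_child)
        clash = mothers == fathers
        while clash.any():
            fathers[clash] = rng.choice(sel, int(clash.sum()))
            clash = mothers == fathers
        ids = [f"{cyc}_{i:04d}" for i in range(n_child)]
        cross(mothers, fathers, ids, cyc, [None] * n_child)
        z_stack = np.vstack(z_all)
        df = pd.DataFrame(rows)

    return Population(lines=df, z=z_stack, value_names=names, config=cfg)


def _plate_counts(rng, gi_lat: np.ndarray, ge_curve: np.ndarray, n_plated: int):
    """Per-plate kernel counts whose GI statistic tracks the latent GI.

    Capacity is clipped into [GI/10, 3 GI/10] so the implied mean germination
    day 10 GE / GI stays within the observable 1-3 day window.
    """
    ge = np.clip(ge_curve, gi_lat / 10.0, np.minimum(1.0, 3.0 * gi_lat / 10.0))
    ge[gi_lat <= 0.05] = 0.0
    ng = rng.binomial(n_plated, ge)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(gi_lat > 0, 10.0 * ge / np.maximum(gi_lat, 1e-9), 3.0)
    m = np.clip(m, 1.0, 3.0)
    n24 = np.zeros_like(ng)
    n48 = np.zeros_like(ng)
    n72 = np.zeros_like(ng)
    early = m <= 2.0
    n48[early] = rng.binomial(ng[early], m[early] - 1.0)
    n24[early] = ng[early] - n48[early]
    late = ~early
    n72[late] = rng.binomial(ng[late], m[late] - 2.0)
    n48[late] = ng[late] - n72[late]
    return n24, n48, n72


def simulate_trials(pop: Population, cfg: SimConfig, seed: int) -> SimResult:
    """Field/lab phase: plots, checks, germination plates, malting assays."""
    rng = np.random.default_rng(seed)
    lines = pop.lines.reset_index(drop=True)
    names = pop.value_names
    n_lines = len(lines)
    tnames = cfg.trait_names
    allele = lines["allele"].to_numpy()

    # fixed structure drawn once
    year_eff = {
        t: dict(zip(cfg.years, rng.normal(0.0, cfg.year_effect_frac * cfg.traits[t].g_sd,
                                          len(cfg.years))))
        for t in tnames
    }
    gi_year = dict(zip(cfg.years, rng.normal(0.0, cfg.gi_year_sd, len(cfg.years))))
    all_malt_tps = sorted({tp for tps in cfg.malt_timepoints.values() for tp in tps})
    dg = {
        t: rng.normal(0.0, cfg.traits[t].dgtp_sd, (n_lines, len(all_malt_tps)))
        for t in tnames
    }
    tp_col = {tp: i for i, tp in enumerate(all_malt_tps)}

    pheno_parts = []
    plate_parts = []
    for year in cfg.years:
        # plot sequence: every line once, parents replicated, checks inserted
        par_idx = np.where(lines["cycle"].to_numpy() == "PARENT")[0]
        entry_idx = np.concatenate(
            [np.arange(n_lines)] + [par_idx] * max(cfg.parent_blocks - 1, 0)
        )
        entry_idx = rng.permutation(entry_idx)
        seq_line, is_check = [], []
        for i, e in enumerate(entry_idx):
            if i > 0 and i % cfg.check_interval == 0:
                seq_line.append(-1)
                is_check.append(True)
            seq_line.append(int(e))
            is_check.append(False)
        seq_line = np.array(seq_line)
        is_check = np.array(is_check)
        n_plots = len(seq_line)
        plot_id = np.array([f"{year}-{i:04d}" for i in range(n_plots)])
        block = (np.arange(n_plots) // cfg.check_interval).astype(str)
        line_id = np.where(
            is_check, CHECK_LINE, lines["line_id"].to_numpy()[np.maximum(seq_line, 0)]
        )

        # ---- malting assays --------------------------------------------
        for tp in cfg.malt_timepoints.get(year, ()):  # per malting timepoint
            for t in tnames:
                td = cfg.traits[t]
                tp_shift = td.tp6_shift if tp == "TP6" else 0.0
                base = np.full(n_plots, td.mean + year_eff[t][year] + tp_shift)
                gen = np.where(
                    is_check,
                    0.0,
                    _allele_effect(cfg, t, allele)[np.maximum(seq_line, 0)]
                    + pop.z[np.maximum(seq_line, 0), names.index(t)]
                    + dg[t][np.maximum(seq_line, 0), tp_col[tp]],
                )
                plt_e = rng.normal(0.0, td.pltE_sd, n_plots)
                latent = base + gen + plt_e
                for rep in range(1, td.tech_reps + 1):
                    val = latent + rng.normal(0.0, td.assay_sd, n_plots)
                    pheno_parts.append(
                        pd.DataFrame(
                            {
                                "plot_id": plot_id,
                                "line_id": line_id,
                                "year": year,
                                "location": "LOC1",
                                "block": block,
                                "trait": t,
                                "timepoint": tp,
                                "tech_rep": rep,
                                "value": val,
                            }
                        )
                    )

        # ---- germination plates (field lines only) ---------------------
        live = ~is_check
        lidx = seq_line[live]
        for tp in cfg.germ_timepoints:
            t_days = TIMEPOINT_DAYS[tp]
            gi_lat = latent_gi(
                cfg, allele[lidx], pop.z[lidx, -1] + gi_year[year], t_days
            )
            gi_lat = np.clip(
                gi_lat + rng.normal(0.0, cfg.gi_plot_sd, len(lidx)), 0.0, 10.0
            )
            ge_curve = np.empty(len(lidx))
            for a, curve in cfg.allele_curves.items():
                m = allele[lidx] == a
                ge_curve[m] = curve.ge_max * (1.0 - np.exp(-t_days / curve.tau_ge))
            for rep in range(1, cfg.germ_reps + 1):
                n24, n48, n72 = _plate_counts(rng, gi_lat, ge_curve, cfg.n_plated)
                plate_parts.append(
                    pd.DataFrame(
                        {
                            "plot_id": plot_id[live],
                            "line_id": line_id[live],
                            "year": year,
                            "timepoint": tp,
                            "rep": rep,
                            "n24": n24,
                            "n48": n48,
                            "n72": n72,
                            "n_plated": cfg.n_plated,
                        }
                    )
                )

    phenotypes = (
        pd.concat(pheno_parts, ignore_index=True)
        if pheno_parts
        else pd.DataFrame(
            columns=["plot_id", "line_id", "year", "location", "block", "trait",
                     "timepoint", "tech_rep", "value"]
        )
    )
    plates = (
        pd.concat(plate_parts, ignore_index=True)
        if plate_parts
        else pd.DataFrame(
            columns=["plot_id", "line_id", "year", "timepoint", "rep",
                     "n24", "n48", "n72", "n_plated"]
        )
    )

    lines_out = lines[["line_id", "cycle", "family", "allele"]].copy()
    lines_out["is_check"] = False
    lines_out = pd.concat(
        [
            lines_out,
            pd.DataFrame(
                [{"line_id": CHECK_LINE, "cycle": "CHECK", "family": None,
                  "allele": "D", "is_check": True}]
            ),
        ],
        ignore_index=True,
    )

    markers = _marker_table(cfg, lines, rng)
    truth = _build_truth(pop, cfg, seed)
    return SimResult(phenotypes, plates, lines_out, markers, truth)


def _marker_table(cfg: SimConfig, lines: pd.DataFrame, rng) -> pd.DataFrame:
    from phsmalt.correlations import E165Q_MARKER, LINKED_MARKER

    allele = lines["allele"].to_numpy()
    parts = [
        pd.DataFrame(
            {
                "line_id": lines["line_id"],
                "marker_id": E165Q_MARKER,
                "genotype": np.where(allele == "Nstar", "B", "A"),
            }
        ),
        pd.DataFrame(
            {
                "line_id": lines["line_id"],
                "marker_id": LINKED_MARKER,
                # N and N* share the non-dormant linked haplotype (A); D carries B
                "genotype": np.where(allele == "D", "B", "A"),
            }
        ),
    ]
    n = len(lines)
    for j in range(cfg.n_qc_markers):
        p = rng.uniform(0.05, 0.5)
        g = rng.choice(["A", "B"], size=n, p=[1 - p, p])
        het = rng.random(n) < 0.02
        g = np.where(het, "HET", g)
        miss = rng.random(n) < 0.02
        g = np.where(miss, "MISSING", g)
        parts.append(
            pd.DataFrame({"line_id": lines["line_id"], "marker_id": f"QC{j:03d}", "genotype": g})
        )
    return pd.concat(parts, ignore_index=True)


def _build_truth(pop: Population, cfg: SimConfig, seed: int) -> SyntheticTruth:
    lines = pop.lines.reset_index(drop=True)
    names = pop.value_names
    allele = lines["allele"].to_numpy()
    lv = lines.copy()
    gcols = {}
    for t in cfg.trait_names:
        g = _allele_effect(cfg, t, allele) + pop.z[:, names.index(t)]
        lv[f"g_{t}"] = g
        gcols[t] = g
    for tp in ("TP1", "TP4", "TP6"):
        lv[f"gi_true_{tp}"] = latent_gi(cfg, allele, pop.z[:, -1], TIMEPOINT_DAYS[tp])
        gcols[f"GI_{tp}"] = lv[f"gi_true_{tp}"].to_numpy()

    groups = {"ALL": np.ones(len(lines), bool)}
    for a in ("D", "N", "Nstar"):
        groups[a] = allele == a
    pairs = []
    keys = list(gcols)
    for gname, mask in groups.items():
        if mask.sum() < 3:
            continue
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                va, vb = gcols[a][mask], gcols[b][mask]
                if va.std() > 0 and vb.std() > 0:
                    r = float(np.corrcoef(va, vb)[0, 1])
                else:
                    r = np.nan
                pairs.append({"group": gname, "trait_a": a, "trait_b": b, "r_g": r})
    r_g = pd.DataFrame(pairs)

    vc_rows = []
    cycles = [c for c in ("C0", "C1P", "C1G", "C2G") if (lines["cycle"] == c).any()]
    for t in cfg.trait_names:
        td = cfg.traits[t]
        row = {
            "trait": t,
            "sigma2_pltE": td.pltE_sd**2,
            "sigma2_dgTP": td.dgtp_sd**2,
            "sigma2_assay": td.assay_sd**2,
            "sigma2_g_poly": td.g_sd**2,
        }
        for c in cycles:
            m = lines["cycle"] == c
            row[f"sigma2_g_{c}"] = float(np.var(gcols[t][m], ddof=1)) if m.sum() > 1 else np.nan
        vc_rows.append(row)
    varcomp = pd.DataFrame(vc_rows)

    cm_rows = []
    for c in cycles:
        m = lines["cycle"] == c
        for t in cfg.trait_names:
            cm_rows.append(
                {"cycle": c, "trait": t,
                 "true_mean": cfg.traits[t].mean + float(np.mean(gcols[t][m]))}
            )
        cm_rows.append(
            {"cycle": c, "trait": "GI_TP1", "true_mean": float(np.mean(gcols["GI_TP1"][m]))}
        )
    cycle_means = pd.DataFrame(cm_rows)

    nstar = pd.DataFrame(
        [
            {"cycle": c, "freq_Nstar": float(np.mean(allele[lines["cycle"] == c] == "Nstar"))}
            for c in cycles
        ]
    )
    return SyntheticTruth(
        line_values=lv, r_g=r_g, varcomp=varcomp, cycle_means=cycle_means,
        nstar_freq=nstar, seed=seed,
    )


def truth_report(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Machine-readable oracle tables for recovery tests."""
    return {
        "truth_r_g": truth.r_g,
        "truth_varcomp": truth.varcomp,
        "truth_cycle_means": truth.cycle_means,
        "truth_nstar_freq": truth.nstar_freq,
        "truth_line_values": truth.line_values,
    }


def simulate(cfg: SimConfig, seed: int) -> SimResult:
    """Population + trials in one call, all randomness from ``seed``."""
    pop = simulate_founders_and_cycles(cfg, seed)
    return simulate_trials(pop, cfg, seed + 1)


# ---------------------------------------------------------------------------
# reduced scenario configs used by recovery and calibration studies


def bivariate_malt_scenario(
    r_g: float,
    n_lines: int = 500,
    years: tuple = (2020, 2021),
    traits: tuple = ("FAN", "SP"),
) -> SimConfig:
    """Base population only, two malting traits with genetic correlation r_g.

    A single dormancy allele removes major-locus effects, so the configured
    polygenic correlation is the whole genetic correlation.
    """
    a, b = traits
    return SimConfig(
        cycle_sizes={"C0": n_lines},
        years=years,
        germ_timepoints=(),
        malt_timepoints={y: ("TP4", "TP6") for y in years},
        traits={a: DEFAULT_TRAITS[a], b: DEFAULT_TRAITS[b]},
        gi_corr={},
        malt_corr={(a, b): r_g},
        parent_alleles=("D",) * 8,
        index_weights={},
        n_qc_markers=0,
        family_structure=False,
    )


def germination_recovery_scenario(
    r_g: float,
    n_lines: int = 150,
    years: tuple = (2020, 2021),
    trait: str = "FAN",
) -> SimConfig:
    """Mono-allelic (N) population to check plate-based GI vs malt-trait r_g."""
    return SimConfig(
        cycle_sizes={"C0": n_lines},
        years=years,
        germ_timepoints=("TP1", "TP4"),
        malt_timepoints={y: ("TP4", "TP6") for y in years},
        traits={trait: DEFAULT_TRAITS[trait]},
        gi_corr={trait: r_g},
        malt_corr={},
        parent_alleles=("N",) * 8,
        index_weights={},
        n_qc_markers=0,
        family_structure=False,
    )


def selection_scenario(n_per_cycle: int = 60, years: tuple = (2020, 2021)) -> SimConfig:
    """Scaled-down selection experiment for response-direction studies."""
    return SimConfig(
        cycle_sizes={"C0": n_per_cycle, "C1P": n_per_cycle, "C1G": n_per_cycle,
                     "C2G": n_per_cycle},
        years=years,
        germ_timepoints=("TP1",),
        malt_timepoints={y: ("TP4", "TP6") for y in years},
        traits={t: DEFAULT_TRAITS[t] for t in ("FAN", "AA")},
        gi_corr={"FAN": DEFAULT_GI_CORR["FAN"], "AA": DEFAULT_GI_CORR["AA"]},
        malt_corr={("FAN", "AA"): DEFAULT_MALT_CORR[("FAN", "AA")]},
        n_qc_markers=0,
    )
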