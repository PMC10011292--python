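"""Domain tables, CSV readers/writers and marker QC.

All tables are plain :class:`pandas.DataFrame` objects with documented column
schemas; readers validate structure and keys, writers emit RFC-4180 CSV with a
deterministic column order and full float precision so that every result
round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger("phsmalt")

CYCLES = ("PARENT", "C0", "C1P", "C1G", "C2G")
#: sentinel cycle value carried by check plots (the replicated standard line)
CHECK_CYCLE = "CHECK"

PHENOTYPE_COLUMNS = [
    "plot_id",
    "line_id",
    "year",
    "location",
    "block",
    "trait",
    "timepoint",
    "tech_rep",
    "value",
]
PHENOTYPE_KEY = ["plot_id", "trait", "timepoint", "tech_rep"]

MARKER_COLUMNS = ["line_id", "marker_id", "genotype"]
GENOTYPE_DOMAIN = {"A", "B", "HET", "MISSING"}


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(ValueError):
    """A table violates a uniqueness or referential-integrity invariant."""


@dataclass(frozen=True)
class LineRecord:
    """One breeding line: identity, selection-cycle membership and check flag."""

    line_id: str
    cycle: str | None
    family: str | None = None
    is_check: bool = False

    def __post_init__(self):
        if self.is_check:
            if self.cycle not in (None, CHECK_CYCLE):
                raise ValueError("check lines carry the CHECK sentinel cycle")
        elif self.cycle not in CYCLES:
            raise ValueError(f"unknown cycle {self.cycle!r}")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table in place and return it.

    Rows with a missing ``value`` are kept and flagged (column ``missing``)
    rather than dropped: different model stages exclude missing data at fit
    time on their own subsets.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"phenotype table missing required column(s): {missing_cols}")
    dup = df.duplicated(subset=PHENOTYPE_KEY)
    if dup.any():
        first = df.loc[dup, PHENOTYPE_KEY].iloc[0].to_dict()
        raise IntegrityError(f"duplicated (plot_id, trait, timepoint, tech_rep) key, e.g. {first}")
    plot_map = df.groupby("plot_id")[["line_id", "year"]].nunique()
    bad = plot_map[(plot_map > 1).any(axis=1)]
    if len(bad):
        raise IntegrityError(f"plot(s) mapped to >1 line_id/year: {list(bad.index[:5])}")
    df = df.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["missing"] = df["value"].isna()
    log.info("phenotypes: %d rows, %d flagged missing", len(df), int(df["missing"].sum()))
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a plot-level phenotype CSV."""
    df = pd.read_csv(path, dtype={"plot_id": str, "line_id": str, "block": str, "location": str})
    return validate_phenotypes(df)


def read_lines(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str, "family": str})
    need = {"line_id", "cycle", "is_check"}
    if not need.issubset(df.columns):
        raise SchemaError(f"line table missing {sorted(need - set(df.columns))}")
    if df["line_id"].duplicated().any():
        raise IntegrityError("duplicate line_id in line table")
    return df


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"marker table missing required column(s): {missing}")
    bad = set(df["genotype"].unique()) - GENOTYPE_DOMAIN
    if bad:
        raise SchemaError(f"genotype values outside domain {sorted(GENOTYPE_DOMAIN)}: {sorted(bad)}")
    if df.duplicated(subset=["line_id", "marker_id"]).any():
        raise IntegrityError("duplicate (line_id, marker_id) in marker table")
    return df


def marker_stats(markers: pd.DataFrame) -> pd.DataFrame:
    """Per-marker heterozygosity and minor-allele frequency.

    MAF is computed from non-missing calls with HET counted as half a dose of
    each allele; heterozygosity is the HET fraction of non-missing calls.
    """
    counts = (
        markers.pivot_table(index="marker_id", columns="genotype", values="line_id", aggfunc="count")
        .reindex(columns=["A", "B", "HET", "MISSING"], fill_value=0)
        .fillna(0)
        .astype(int)
    )
    called = counts["A"] + counts["B"] + counts["HET"]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (counts["A"] + 0.5 * counts["HET"]) / called
        het = counts["HET"] / called
    maf = np.minimum(p, 1.0 - p)
    out = pd.DataFrame({"n_called": called, "het": het, "maf": maf})
    return out.reset_index()


def qc_markers(markers: pd.DataFrame, max_het: float = 0.10, min_maf: float = 0.05) -> pd.DataFrame:
    """Filter markers by heterozygosity and minor allele frequency.

    Retains markers with het <= ``max_het`` and MAF >= ``min_maf`` (both
    boundaries inclusive, matching the strict-inequality filtering phrasing
    "het > 10%" / "MAF < 0.05"). Markers with no non-missing call are dropped
    with a warning. Idempotent.
    """
    if not (0 <= max_het <= 0.5 and 0 <= min_maf <= 0.5):
        raise ValueError("max_het and min_maf must lie in [0, 0.5]")
    stats = marker_stats(markers)
    all_missing = stats.loc[stats["n_called"] == 0, "marker_id"]
    if len(all_missing):
        log.warning("qc_markers: %d marker(s) with all calls missing excluded", len(all_missing))
    # tiny tolerance so that e.g. 9A/1B -> MAF 0.05 survives float round-off
    eps = 1e-12
    keep = stats.loc[
        (stats["n_called"] > 0) & (stats["het"] <= max_het + eps) & (stats["maf"] >= min_maf - eps),
        "marker_id",
    ]
    out = markers[markers["marker_id"].isin(set(keep))].reset_index(drop=True)
    log.info("qc_markers: kept %d/%d markers", out["marker_id"].nunique(), markers["marker_id"].nunique())
    return out


def write_table(df: pd.DataFrame, path: str | Path, columns: Iterable[str] | None = None) -> Path:
    """Write a result table as CSV: deterministic column order, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
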