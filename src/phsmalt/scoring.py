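"""Config-driven end-use quality scores and breeding-target classification.

Malting labs rank barley for adjunct vs all-malt brewing by awarding points
per trait from banded score tables and by checking trait values against
published acceptable target ranges.  The exact point tables and target
intervals are lab/association specific, so scoring here is entirely driven by
a declarative config: per trait and end use, an ordered list of half-open
value bands ``[lo, hi) -> points`` (values outside every band score 0 via an
implicit catch-all) plus an acceptance interval for range classification.

The shipped ``data/scoring_default.yaml`` is an illustrative synthetic
configuration for tests and demonstrations; it does not reproduce any lab's
proprietary point values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("phsmalt")

END_USES = ("adjunct", "all_malt")
RANGE_CLASSES = ("ALL_MALT", "ADJUNCT", "BOTH", "NEITHER")


class ScoreConfigError(ValueError):
    """Invalid scoring configuration (overlapping bands, bad points, ...)."""


@dataclass(frozen=True)
class Band:
    lo: float
    hi: float
    points: float

    def contains(self, x: float) -> bool:
        return self.lo <= x < self.hi


@dataclass
class ScoreConfig:
    """Per trait, per end use: score bands and an acceptance target interval."""

    bands: dict[str, dict[str, list[Band]]] = field(default_factory=dict)
    targets: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScoreConfig":
        bands: dict[str, dict[str, list[Band]]] = {}
        targets: dict[str, dict[str, tuple[float, float]]] = {}
        for trait, per_use in cfg.get("traits", {}).items():
            bands[trait] = {}
            targets[trait] = {}
            for use, spec in per_use.items():
                if use not in END_USES:
                    raise ScoreConfigError(f"unknown end use {use!r} for trait {trait}")
                bl = []
                for b in spec.get("bands", []):
                    band = Band(float(b.get("lo", -np.inf)), float(b.get("hi", np.inf)),
                                float(b["points"]))
                    if band.points < 0:
                        raise ScoreConfigError(f"negative points in {trait}/{use}")
                    if band.hi <= band.lo:
                        raise ScoreConfigError(f"empty band {band} in {trait}/{use}")
                    bl.append(band)
                bl.sort(key=lambda b: b.lo)
                for b1, b2 in zip(bl, bl[1:]):
                    if b2.lo < b1.hi:
                        raise ScoreConfigError(
                            f"overlapping bands in {trait}/{use}: {b1} vs {b2}"
                        )
                bands[trait][use] = bl
                if "target" in spec:
                    t = spec["target"]
                    targets[trait][use] = (
                        float(t.get("lo", -np.inf)),
                        float(t.get("hi", np.inf)),
                    )
        return cls(bands=bands, targets=targets)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoreConfig":
        """The packaged illustrative (synthetic) scoring configuration."""
        src = resources.files("phsmalt").joinpath("data/scoring_default.yaml")
        return cls.from_dict(yaml.safe_load(src.read_text()))

    def traits(self, use: str) -> list[str]:
        return [t for t, per in self.bands.items() if use in per]


@dataclass
class QualityScore:
    line_id: str
    ccru_adj: float
    ccru_allmalt: float
    range_class: str
    complete: bool


def _score(values: dict[str, float], cfg: ScoreConfig, use: str) -> tuple[float, bool]:
    total, complete = 0.0, True
    for trait in cfg.traits(use):
        x = values.get(trait)
        if x is None or not np.isfinite(x):
            complete = False
            log.warning("score: trait %s missing; skipped", trait)
            continue
        total += next((b.points for b in cfg.bands[trait][use] if b.contains(x)), 0.0)
    return total, complete


def classify_ranges(values: dict[str, float], cfg: ScoreConfig) -> str:
    """ALL_MALT / ADJUNCT / BOTH / NEITHER from the acceptance intervals.

    A line classifies for an end use iff every evaluated trait with a defined
    target interval falls inside that interval.
    """
    ok = {}
    for use in END_USES:
        inside = True
        for trait, per_use in cfg.targets.items():
            if use not in per_use:
                continue
            x = values.get(trait)
            if x is None or not np.isfinite(x):
                continue
            lo, hi = per_use[use]
            inside &= lo <= x <= hi
        ok[use] = inside
    if ok["adjunct"] and ok["all_malt"]:
        return "BOTH"
    if ok["all_malt"]:
        return "ALL_MALT"
    if ok["adjunct"]:
        return "ADJUNCT"
    return "NEITHER"


def score_line(line_id: str, values: dict[str, float], cfg: ScoreConfig) -> QualityScore:
    """Total adjunct and all-malt points plus target-range class for one line."""
    adj, c1 = _score(values, cfg, "adjunct")
    allm, c2 = _score(values, cfg, "all_malt")
    return QualityScore(
        line_id=line_id,
        ccru_adj=adj,
        ccru_allmalt=allm,
        range_class=classify_ranges(values, cfg),
        complete=c1 and c2,
    )


def score_table(blues_wide, cfg: ScoreConfig):
    """Score every line of a wide per-line trait table; returns a DataFrame."""
    import pandas as pd

    rows = []
    for _, rec in blues_wide.iterrows():
        values = {t: rec.get(t, np.nan) for t in cfg.bands}
        qs = score_line(str(rec["line_id"]), values, cfg)
        rows.append(
            {
                "line_id": qs.line_id,
                "CCRU_Adj": qs.ccru_adj,
                "CCRU_allMalt": qs.ccru_allmalt,
                "range_class": qs.range_class,
                "complete": qs.complete,
            }
        )
    return pd.DataFrame(rows)
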