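import numpy as np
import pandas as pd
import pytest

from phsmalt.blues import blues_across_timepoints, blues_across_years, blues_per_timepoint


def _balanced(rng, n_lines=12, years=(2020, 2021), tps=("TP4", "TP6"), reps=2):
    rows = []
    for j in range(n_lines):
        for y in years:
            for tp in tps:
                for r in range(reps):
                    rows.append(
                        dict(line_id=f"L{j:02d}", year=y, timepoint=tp, tech_rep=r + 1,
                             value=50 + j + 2 * (tp == "TP6") + 3 * (y == 2021)
                             + rng.normal(0, 0.5))
                    )
    return pd.DataFrame(rows)


def test_balanced_data_all_routes_equal_simple_means(rng):
    df = _balanced(rng)
    simple = df.groupby("line_id")["value"].mean()
    b1 = blues_across_timepoints(df).set_index("line_id")["estimate"]
    b2 = blues_across_years(df).set_index("line_id")["estimate"]
    cell = blues_per_timepoint(df)
    cellmean = cell.groupby("line_id")["estimate"].mean()
    assert np.allclose(b1[simple.index], simple, atol=1e-8)
    assert np.allclose(cellmean[simple.index], simple, atol=1e-8)
    # the across-years route estimates per-year weights from the data
    # (feasible GLS), which perturbs the exact balanced identity at O(1/sqrt n)
    assert np.allclose(b2[simple.index], simple, atol=0.05)


def test_per_timepoint_cell_mean():
    df = pd.DataFrame(
        [
            dict(line_id="L1", year=2020, timepoint="TP4", tech_rep=1, value=4.0),
            dict(line_id="L1", year=2020, timepoint="TP4", tech_rep=2, value=6.0),
            dict(line_id="L1", year=2020, timepoint="TP6", tech_rep=1, value=9.0),
        ]
    )
    out = blues_per_timepoint(df).set_index("label")
    assert out.loc["TP4", "estimate"] == pytest.approx(5.0)
    assert out.loc["TP6", "estimate"] == pytest.approx(9.0)


def test_across_timepoints_removes_additive_shift():
    rows = []
    for j, base in enumerate([10.0, 14.0, 17.0]):
        rows.append(dict(line_id=f"L{j}", year=2020, timepoint="TP4", tech_rep=1, value=base))
        rows.append(dict(line_id=f"L{j}", year=2020, timepoint="TP6", tech_rep=1,
                         value=base + 2.0))
    out = blues_across_timepoints(pd.DataFrame(rows)).set_index("line_id")["estimate"]
    # adjusted means recover base + half the shift, exactly additive
    assert np.allclose(out[["L0", "L1", "L2"]], [11.0, 15.0, 18.0], atol=1e-10)


def test_line_seen_only_at_one_timepoint_is_adjusted():
    # hand-solved normal equations: b0=10, TP6 effect=2, G2=8
    df = pd.DataFrame(
        [
            dict(line_id="L1", year=2020, timepoint="TP4", tech_rep=1, value=10.0),
            dict(line_id="L1", year=2020, timepoint="TP6", tech_rep=1, value=12.0),
            dict(line_id="L2", year=2020, timepoint="TP6", tech_rep=1, value=20.0),
        ]
    )
    out = blues_across_timepoints(df).set_index("line_id")["estimate"]
    assert out["L1"] == pytest.approx(11.0, abs=1e-10)
    assert out["L2"] == pytest.approx(19.0, abs=1e-10)


def test_blues_equivariant_under_constant_shift(rng):
    df = _balanced(rng, n_lines=8)
    base = blues_across_years(df).set_index("line_id")["estimate"]
    shifted = blues_across_years(df.assign(value=df["value"] + 7.5))
    shifted = shifted.set_index("line_id")["estimate"]
    assert np.allclose(shifted - base, 7.5, atol=1e-8)


def test_across_years_weighting_limits(rng):
    df = _balanced(rng, n_lines=10)
    hom = blues_across_timepoints(
        df.assign(timepoint=df["year"].astype(str) + ":" + df["timepoint"])
    )
    # equal year variances: heterogeneous fit matches a homogeneous fit closely
    # (up to the sampling noise in the estimated year weights)
    het = blues_across_years(df)
    merged = het.set_index("line_id")["estimate"]
    hom2 = hom.set_index("line_id")["estimate"]
    assert np.allclose(merged[hom2.index], hom2, atol=0.05)

    # inflate one year's noise 100x: BLUEs approach the clean year's line means
    noisy = df.copy()
    m2021 = noisy["year"] == 2021
    noisy.loc[m2021, "value"] += rng.normal(0, 5.0, int(m2021.sum()))
    est = blues_across_years(noisy).set_index("line_id")["estimate"]
    clean_rank = (
        noisy[~m2021].groupby("line_id")["value"].mean().rank()
    )
    assert (est[clean_rank.index].rank() == clean_rank).mean() > 0.9


def test_single_year_reduces_to_timepoint_replicates(rng):
    df = _balanced(rng, years=(2020,))
    a = blues_across_years(df, label="X").set_index("line_id")["estimate"]
    b = blues_across_timepoints(df, label="X").set_index("line_id")["estimate"]
    assert np.allclose(a[b.index], b, atol=1e-10)


def test_blue_precision_improves_with_replication(rng):
    # correlation between true line values and BLUEs rises from 2 to 6 reps
    true = rng.normal(0, 1.0, 40)
    corrs = []
    for reps in (2, 6):
        rows = []
        for j in range(40):
            for tp in ("TP4", "TP6"):
                for r in range(reps):
                    rows.append(dict(line_id=f"L{j:02d}", year=2020, timepoint=tp,
                                     tech_rep=r + 1,
                                     value=true[j] + rng.normal(0, 2.0)))
        est = blues_across_timepoints(pd.DataFrame(rows)).sort_values("line_id")["estimate"]
        corrs.append(np.corrcoef(true, est)[0, 1])
    assert corrs[1] > corrs[0]
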