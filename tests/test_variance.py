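import numpy as np
import pandas as pd
import pytest

from phsmalt.mixedlm import ModelError
from phsmalt.variance import (
    VarianceComponents,
    across_year_partition,
    check_plot_error,
    delta_gtp,
    heritability,
    technical_repeatability,
    within_year_partition,
)


def _tech_rep_data(rng, n_plots=200, reps=3, s2_pl=4.0, s2_e=1.0):
    u = rng.normal(0, np.sqrt(s2_pl), n_plots)
    rows = [
        dict(plot_id=f"p{j:03d}", value=50 + u[j] + rng.normal(0, np.sqrt(s2_e)))
        for j in range(n_plots)
        for _ in range(reps)
    ]
    return pd.DataFrame(rows)


def _partition_data(rng, n_lines=150, s2_g=2.0, s2_gtp=1.0, s2_e=1.0, reps=2,
                    tps=("TP4", "TP6"), years=(2020,)):
    g = rng.normal(0, np.sqrt(s2_g), n_lines)
    gtp_draw = {
        (j, tp): rng.normal(0, np.sqrt(s2_gtp)) for j in range(n_lines) for tp in tps
    }
    rows = []
    for j in range(n_lines):
        for y in years:
            for ti, tp in enumerate(tps):
                gtp = gtp_draw[(j, tp)]  # line x timepoint, stable across years
                for r in range(reps):
                    rows.append(
                        dict(line_id=f"L{j:03d}", year=y, timepoint=tp, tech_rep=r + 1,
                             value=100 + 2 * ti + g[j] + gtp + rng.normal(0, np.sqrt(s2_e)))
                    )
    return pd.DataFrame(rows)


def test_repeatability_limits(rng):
    ident = pd.DataFrame(
        dict(plot_id=np.repeat([f"p{i}" for i in range(30)], 2),
             value=np.repeat(rng.normal(5, 2, 30), 2))
    )
    assert technical_repeatability(ident) == pytest.approx(1.0, abs=1e-6)
    noise = _tech_rep_data(rng, n_plots=80, s2_pl=0.0, s2_e=1.0)
    assert technical_repeatability(noise) < 0.1


def test_repeatability_recovers_simulated_ratio(rng):
    df = _tech_rep_data(rng, n_plots=200, reps=3, s2_pl=4.0, s2_e=1.0)
    assert technical_repeatability(df) == pytest.approx(0.8, abs=0.05)


def test_repeatability_requires_replicates():
    df = pd.DataFrame(dict(plot_id=[f"p{i}" for i in range(20)], value=np.arange(20.0)))
    with pytest.raises(ModelError):
        technical_repeatability(df)


def test_within_year_partition_null_interaction(rng):
    df = _partition_data(rng, s2_gtp=0.0)
    vc = within_year_partition(df)
    assert vc.sigma2_gTP <= 0.05 * max(vc.sigma2_g, 1.0)


def test_within_year_partition_duplicated_timepoint(rng):
    df = _partition_data(rng, tps=("TP4",), s2_gtp=0.0)
    dup = df.assign(timepoint="TP6")
    both = pd.concat([df, dup], ignore_index=True)
    both["tech_rep"] = both.groupby(["line_id", "timepoint"]).cumcount() + 1
    vc = within_year_partition(both)
    assert vc.sigma2_gTP == pytest.approx(0.0, abs=0.05)


def test_within_year_partition_single_timepoint_redirects(rng):
    df = _partition_data(rng, tps=("TP4",))
    with pytest.raises(ModelError, match="technical_repeatability"):
        within_year_partition(df)


def test_check_plot_error_arithmetic():
    # three check "plots" with one rep each and known variance 1.5
    vals = np.array([0.0, np.sqrt(1.5 * 3 / 2) * 1, -np.sqrt(1.5 * 3 / 2)])
    df = pd.DataFrame(dict(plot_id=["c1", "c2", "c3"], value=vals))
    est, flags = check_plot_error(df, assay_error=0.5)
    assert est == pytest.approx(float(np.var(vals, ddof=1)) - 0.5)
    assert "few_checks" in flags
    # noiseless checks -> -assay_error/reps, flagged negative
    df0 = pd.DataFrame(dict(plot_id=["c1"] * 2 + ["c2"] * 2 + ["c3"] * 2, value=[3.0] * 6))
    est0, flags0 = check_plot_error(df0, assay_error=0.8)
    assert est0 == pytest.approx(-0.4)
    assert "negative" in flags0


def test_delta_gtp_arithmetic_and_flags():
    vc = VarianceComponents(context={}, sigma2_g=2.0, sigma2_gTP=1.5, sigma2_error=1.0)
    vc = delta_gtp(vc, 0.5)
    assert vc.sigma2_dgTP == pytest.approx(1.0)
    assert vc.ratio1 == pytest.approx(0.5 / 1.5)
    assert vc.ratio2 == pytest.approx(0.5)
    vc2 = delta_gtp(VarianceComponents({}, sigma2_g=2.0, sigma2_gTP=1.0, sigma2_error=1.0), 0.0)
    assert vc2.sigma2_dgTP == pytest.approx(1.0)
    vc3 = delta_gtp(VarianceComponents({}, sigma2_g=2.0, sigma2_gTP=0.4, sigma2_error=1.0), 0.9)
    assert vc3.sigma2_dgTP == pytest.approx(-0.5)
    assert "negative_dgTP" in vc3.flags
    vc4 = delta_gtp(VarianceComponents({}, sigma2_g=2.0, sigma2_gTP=0.0, sigma2_error=1.0), 0.3)
    assert np.isnan(vc4.ratio1) and "ratio1_undefined" in vc4.flags


def test_across_year_partition_recovery(rng):
    df = _partition_data(rng, n_lines=120, s2_g=3.0, s2_gtp=0.5, s2_e=2.0,
                         years=(2019, 2020, 2021))
    vc = across_year_partition(df)
    assert vc.sigma2_g == pytest.approx(3.0, rel=0.3)
    assert vc.sigma2_error == pytest.approx(2.0, rel=0.2)


def test_across_year_partition_handles_unbalanced_timepoints(rng):
    # one year observed at a single (relabelled) timepoint merges cleanly
    df = _partition_data(rng, n_lines=60, years=(2020, 2021))
    extra = _partition_data(rng, n_lines=60, tps=("TP6",), years=(2019,))
    vc = across_year_partition(pd.concat([df, extra], ignore_index=True))
    assert vc.converged


@pytest.mark.parametrize(
    "s2g, s2gtp, s2e, y, expected",
    [(1.0, 0.0, 3.0, 3, 0.5), (0.0, 1.0, 1.0, 2, 0.0), (2.0, 1.0, 3.0, 3, 0.5)],
)
def test_heritability_exact(s2g, s2gtp, s2e, y, expected):
    vc = VarianceComponents({}, sigma2_g=s2g, sigma2_gTP=s2gtp, sigma2_error=s2e)
    assert heritability(vc, y).H2 == pytest.approx(expected, abs=1e-12)


def test_heritability_monotone_and_bounded():
    prev = -1.0
    for s2g in (0.1, 0.5, 1.0, 5.0):
        h = heritability(VarianceComponents({}, sigma2_g=s2g, sigma2_gTP=1.0,
                                            sigma2_error=2.0), 3).H2
        assert 0.0 <= h <= 1.0 and h > prev
        prev = h
    h1 = heritability(VarianceComponents({}, 1.0, 1.0, 2.0), 1).H2
    h3 = heritability(VarianceComponents({}, 1.0, 1.0, 2.0), 3).H2
    assert h3 > h1


def test_heritability_undefined_for_zero_components():
    with pytest.raises(ModelError):
        heritability(VarianceComponents({}, sigma2_g=0.0, sigma2_gTP=0.0, sigma2_error=0.0), 3)
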