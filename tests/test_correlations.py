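import numpy as np
import pandas as pd
import pytest

from conftest import bivariate_plot_data
from phsmalt.correlations import (
    biplot_decomposition,
    classify_mkk3,
    correlation_scan,
    genetic_correlation,
    mkk3_calls,
    phenotypic_correlation_matrix,
)


@pytest.mark.parametrize(
    "e165q, linked, allele",
    [
        ("MUT", "A", "Nstar"),
        ("MUT", "MISSING", "Nstar"),
        ("WT", "A", "N"),
        ("WT", "B", "D"),
        ("WT", "MISSING", "UNKNOWN"),
        ("MISSING", "A", "UNKNOWN"),
        ("HET", "A", "UNKNOWN"),
    ],
)
def test_classify_mkk3_default_map(e165q, linked, allele):
    assert classify_mkk3(e165q, linked) == allele


def test_classify_mkk3_custom_map():
    custom = {("WT", "B"): "N", ("WT", "A"): "D", ("MUT", "A"): "Nstar"}
    assert classify_mkk3("WT", "B", custom) == "N"
    assert classify_mkk3("MUT", "B", custom) == "UNKNOWN"


def test_mkk3_calls_from_marker_table():
    markers = pd.DataFrame(
        [
            ("L1", "MKK3_E165Q", "B"), ("L1", "JHI-Hv50k-2016-367342", "A"),
            ("L2", "MKK3_E165Q", "A"), ("L2", "JHI-Hv50k-2016-367342", "B"),
            ("L3", "MKK3_E165Q", "A"), ("L3", "JHI-Hv50k-2016-367342", "A"),
        ],
        columns=["line_id", "marker_id", "genotype"],
    )
    out = mkk3_calls(markers).set_index("line_id")["allele"]
    assert out["L1"] == "Nstar" and out["L2"] == "D" and out["L3"] == "N"


def test_genetic_correlation_recovers_analytic_value(rng):
    # uB = uA + independent noise: r_g = 2 / sqrt(2*4) = 0.7071
    ests = [
        genetic_correlation(bivariate_plot_data(rng, 250), "A", "B").r_g for _ in range(8)
    ]
    assert np.mean(ests) == pytest.approx(np.sqrt(0.5), abs=0.05)


def test_genetic_correlation_scale_and_sign(rng):
    pairs = bivariate_plot_data(rng, 120)
    base = genetic_correlation(pairs, "A", "B")
    scaled = genetic_correlation(pairs.assign(value_a=3.0 * pairs["value_a"]), "A", "B")
    flipped = genetic_correlation(pairs.assign(value_a=-pairs["value_a"]), "A", "B")
    assert scaled.r_g == pytest.approx(base.r_g, abs=0.02)
    assert flipped.r_g == pytest.approx(-base.r_g, abs=0.02)


def test_genetic_correlation_boundary_for_proportional_traits(rng):
    pairs = bivariate_plot_data(rng, 80)
    pairs["value_b"] = 2.0 * pairs["value_a"]
    res = genetic_correlation(pairs, "A", "B")
    assert res.r_g > 0.99
    assert "boundary" in res.flags


def test_genetic_correlation_low_n_flag(rng):
    res = genetic_correlation(bivariate_plot_data(rng, 20), "A", "B")
    assert "low_n" in res.flags


def test_lrt_stat_zero_when_covariance_zero(rng):
    pairs = bivariate_plot_data(rng, 150, cov=0.0)
    res = genetic_correlation(pairs, "A", "B")
    if abs(res.cov_g) < 1e-6:
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-4)
    else:  # tiny sampling covariance: stat still near zero
        assert res.lrt_stat < 4.0


def _scan_inputs(rng, n_lines=40):
    lines = [f"L{j:02d}" for j in range(n_lines)]
    u = rng.normal(0, 1, n_lines)
    malt, germ = [], []
    for y in (2020, 2021):
        for j, line in enumerate(lines):
            plot = f"{y}-{j:03d}"
            for t in ("FAN", "AA"):
                malt.append(dict(plot_id=plot, line_id=line, year=y, trait=t,
                                 timepoint="TP4", value=u[j] + rng.normal(0, 1)))
            for tp in ("TP1", "TP4"):
                germ.append(dict(plot_id=plot, line_id=line, year=y, timepoint=tp,
                                 GE=0.9, GI=5 + 0.8 * u[j] + rng.normal(0, 0.7)))
    return pd.DataFrame(malt), pd.DataFrame(germ)


def test_correlation_scan_cardinality_and_gaps(rng):
    malt, germ = _scan_inputs(rng)
    res = correlation_scan(malt, germ, ["FAN", "AA"], timepoints=["TP1", "TP4"],
                           groups=["ALL"], min_lines=10, n_starts=1)
    assert len(res) == 4  # 2 traits x 2 TPs x 1 group
    # missing timepoint for a group -> gap, not failure
    res2 = correlation_scan(malt, germ[germ["timepoint"] == "TP1"], ["FAN"],
                            timepoints=["TP1", "TP6"], groups=["ALL"],
                            min_lines=10, n_starts=1)
    assert len(res2) == 1


def test_phenotypic_correlation_hand_values():
    blues = pd.DataFrame(
        {
            "line_id": list("abcde"),
            "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            "y": [2.0, 1.0, 4.0, 3.0, 6.0],
            "z": [5.0, 4.0, 3.0, 2.0, 1.0],
        }
    )
    corr = phenotypic_correlation_matrix(blues, ["x", "y", "z"])
    # hand computation: dev products sum 10, var sums 10 and 14.8, so
    # r(x,y) = 10 / sqrt(10 * 14.8); z = 6 - x so r(x,z) = -1, r(y,z) = -r(x,y)
    rxy = 10.0 / np.sqrt(10.0 * 14.8)
    assert corr.loc["x", "y"] == pytest.approx(rxy, abs=1e-12)
    assert corr.loc["x", "z"] == pytest.approx(-1.0, abs=1e-12)
    assert corr.loc["y", "z"] == pytest.approx(-rxy, abs=1e-12)
    # identical columns -> 1; zero-variance trait excluded
    blues["w"] = blues["x"]
    blues["const"] = 1.0
    c2 = phenotypic_correlation_matrix(blues, ["x", "w", "const"])
    assert c2.loc["x", "w"] == pytest.approx(1.0)
    assert "const" not in c2.columns


def test_biplot_decomposition_analytic_cases():
    ident = pd.DataFrame(np.eye(4), columns=list("abcd"), index=list("abcd"))
    _, ve = biplot_decomposition(ident)
    assert ve == pytest.approx((0.25, 0.25))

    ones = pd.DataFrame(np.ones((3, 3)), columns=list("abc"), index=list("abc"))
    load, ve = biplot_decomposition(ones)
    assert ve[0] == pytest.approx(1.0)
    assert ve[1] == pytest.approx(0.0, abs=1e-12)

    # constructed symmetric matrix with eigenvalues {2.2, 0.6, 0.2}
    rng = np.random.default_rng(0)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    M = Q @ np.diag([2.2, 0.6, 0.2]) @ Q.T
    _, ve = biplot_decomposition(pd.DataFrame(M, columns=list("abc"), index=list("abc")))
    assert ve[0] == pytest.approx(2.2 / 3.0, abs=1e-10)
    assert ve[1] == pytest.approx(0.2, abs=1e-10)

    with pytest.raises(ValueError, match="symmetric"):
        biplot_decomposition(pd.DataFrame([[1.0, 0.5], [0.1, 1.0]]))


def test_plate_based_gi_recovers_generator_correlation():
    """The full germination route (kernel counts -> GI -> plot means) recovers
    a within-allele generator r_g of 0.5 with a malting trait."""
    from phsmalt.germination import plot_germination_means
    from phsmalt.simulate import germination_recovery_scenario, simulate

    cfg = germination_recovery_scenario(0.5, n_lines=150)
    ests = []
    for rep in range(20):
        res = simulate(cfg, 9000 + rep)
        malt = res.phenotypes.groupby(
            ["plot_id", "line_id", "year"], as_index=False
        )["value"].mean()
        germ = plot_germination_means(res.plates)
        g1 = germ[germ["timepoint"] == "TP1"][["plot_id", "line_id", "year", "GI"]]
        pairs = malt.merge(g1, on=["plot_id", "line_id", "year"]).rename(
            columns={"value": "value_a", "GI": "value_b"}
        )
        ests.append(genetic_correlation(pairs, "FAN", "GI_TP1", n_starts=1).r_g)
    assert np.mean(ests) == pytest.approx(0.5, abs=0.1)
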