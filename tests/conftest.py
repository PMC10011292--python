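import logging

import numpy as np
import pandas as pd
import pytest

logging.getLogger("phsmalt").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def balanced_oneway(rng, n_groups=50, n_reps=4, s2_g=2.0, s2_e=1.0, mean=5.0):
    """Balanced one-way layout with known variance components."""
    g = np.repeat(np.arange(n_groups), n_reps)
    u = rng.normal(0.0, np.sqrt(s2_g), n_groups)
    y = mean + u[g] + rng.normal(0.0, np.sqrt(s2_e), n_groups * n_reps)
    return pd.DataFrame({"y": y, "grp": [f"G{k:03d}" for k in g]})


def anova_oneway(df, n_reps):
    """Method-of-moments closed form for the balanced one-way design."""
    means = df.groupby("grp")["y"].mean()
    a = len(means)
    msb = n_reps * float(((means - means.mean()) ** 2).sum()) / (a - 1)
    within = df["y"].to_numpy() - means[df["grp"]].to_numpy()
    msw = float((within**2).sum()) / (len(df) - a)
    return (msb - msw) / n_reps, msw


def bivariate_plot_data(rng, n_lines, var_a=2.0, var_b=4.0, cov=2.0,
                        years=(2020, 2021), sd_a=0.8, sd_b=1.0):
    """Paired plot-level means with known genetic (co)variance."""
    G = np.array([[var_a, cov], [cov, var_b]])
    u = rng.multivariate_normal([0.0, 0.0], G, n_lines)
    rows = []
    for j in range(n_lines):
        for y in years:
            rows.append(
                dict(
                    line_id=f"L{j:04d}",
                    year=y,
                    value_a=10 + u[j, 0] + rng.normal(0, sd_a),
                    value_b=-3 + u[j, 1] + rng.normal(0, sd_b),
                )
            )
    return pd.DataFrame(rows)
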