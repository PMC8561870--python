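"""Independent reference implementations used only to check the package."""

import numpy as np
from scipy import stats


def anova_f_bruteforce(groups):
    """Textbook one-way ANOVA from explicit sums of squares.

    Deliberately naive: explicit Python loops over groups, no shared code
    with the implementation under test.  Groups with < 2 values excluded.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return np.nan, np.nan
    all_values = np.concatenate(groups)
    grand_mean = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand_mean) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    if ss_within == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    return f, float(stats.f.sf(f, df_between, df_within))


def studentized_range_sf_mc(q, k, df, n_draws=1_000_000, seed=0):
    """Monte-Carlo tail probability of the studentized range.

    Draws the range of k standard normals over sqrt(chi2_df/df) and counts
    exceedances; standard error ~ 0.5/sqrt(n_draws).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    ranges = z.max(axis=1) - z.min(axis=1)
    scale = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    return float(np.mean(ranges / scale >= q))
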