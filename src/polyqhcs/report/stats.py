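"""Group-comparison plumbing: ANOVA with Bonferroni-corrected pairwise
t-tests at the 0.05 level.  The statistical unit is the well; nuclei are
never treated as independent replicates."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..errors import DesignError

__all__ = ["compare_groups"]

ALPHA = 0.05


def _check_design(groups: dict) -> None:
    if len(groups) < 2:
        raise DesignError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise DesignError(f"group {name!r} has fewer than 2 replicates")


def compare_groups(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    factor2: str | None = None,
    design: str = "one_way",
    correction: str = "bonferroni",
    alpha: float = ALPHA,
) -> dict:
    """ANOVA plus Bonferroni-adjusted pairwise comparisons.

    Returns a dict with the omnibus ANOVA table and a ``pairwise``
    DataFrame (group1, group2, p_raw, p_adj, significant).  ``two_way``
    fits value ~ C(group) * C(factor2) and runs the pairwise comparisons
    on the primary factor pooled across the second.
    """
    if correction != "bonferroni":
        raise DesignError(f"unsupported correction {correction!r}")
    if design not in ("one_way", "two_way"):
        raise DesignError(f"unsupported design {design!r}")
    groups = {name: grp[value].to_numpy(dtype=float)
              for name, grp in data.groupby(group, sort=True)}
    _check_design(groups)

    if design == "one_way":
        f_stat, p_omni = sps.f_oneway(*groups.values())
        anova = pd.DataFrame(
            [{"effect": group, "F": f_stat, "p": p_omni}]
        )
    else:
        if factor2 is None:
            raise DesignError("two_way design needs factor2")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = data.rename(columns={value: "_y", group: "_a", factor2: "_b"})
        model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        anova = pd.DataFrame([
            {"effect": group, "F": table.loc["C(_a)", "F"],
             "p": table.loc["C(_a)", "PR(>F)"]},
            {"effect": factor2, "F": table.loc["C(_b)", "F"],
             "p": table.loc["C(_b)", "PR(>F)"]},
            {"effect": f"{group}:{factor2}",
             "F": table.loc["C(_a):C(_b)", "F"],
             "p": table.loc["C(_a):C(_b)", "PR(>F)"]},
        ])

    pairs = list(combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        t, p = sps.ttest_ind(groups[g1], groups[g2])
        if not np.isfinite(p):  # zero variance in both groups
            p = 1.0
        p_adj = min(1.0, p * m)
        rows.append({"group1": g1, "group2": g2, "t": t, "p_raw": p,
                     "p_adj": p_adj, "significant": p_adj < alpha})
    pairwise = pd.DataFrame(rows)
    return {"anova": anova, "pairwise": pairwise}
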