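"""Group comparisons applied to pipeline outputs.

Two-group comparisons use the unpaired Student's t test (equal variances;
Welch available as an option). More than two groups are compared by
one-way ANOVA followed by Tukey's all-pairs or Dunnett's many-to-one
adjusted comparisons. Established SciPy routines back every operation;
this module fixes the contracts and the tabular output format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["two_sample_t", "one_way_anova", "posthoc"]


def _check_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise InputError(f"{name} must be 1D with at least {min_n} observations")
    if not np.isfinite(x).all():
        raise InputError(f"{name} contains non-finite values")
    return x


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Unpaired two-sided t test; classical Student's form by default."""
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way fixed-effects F test across >= 2 groups."""
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrs = [_check_sample(g, f"group {i}") for i, g in enumerate(groups)]
    res = stats.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def posthoc(
    groups, method: str = "tukey", control_index: int | None = None
) -> pd.DataFrame:
    """Adjusted pairwise comparisons after a one-way ANOVA.

    ``tukey``: all pairs (Tukey HSD). ``dunnett``: each group against the
    control group at ``control_index``. Returns a table with columns
    ``group_a, group_b, statistic, p_adj``.
    """
    arrs = [_check_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise InputError("need at least 2 groups")
    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*arrs)
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                rows.append(
                    {
                        "group_a": i,
                        "group_b": j,
                        "statistic": float(res.statistic[i, j]),
                        "p_adj": float(np.clip(res.pvalue[i, j], 0.0, 1.0)),
                    }
                )
    elif method == "dunnett":
        if control_index is None or not 0 <= control_index < len(arrs):
            raise InputError("dunnett requires a valid control_index")
        treatments = [a for k, a in enumerate(arrs) if k != control_index]
        res = stats.dunnett(*treatments, control=arrs[control_index])
        others = [k for k in range(len(arrs)) if k != control_index]
        for k, g in enumerate(others):
            rows.append(
                {
                    "group_a": g,
                    "group_b": control_index,
                    "statistic": float(res.statistic[k]),
                    "p_adj": float(np.clip(res.pvalue[k], 0.0, 1.0)),
                }
            )
    else:
        raise InputError(f"unknown post hoc method {method!r}")
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_adj"])
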