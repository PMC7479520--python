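"""CN-specific differential enrichment between patient groups.

For each (CN n, subset c), the linear model

    Y_nc = b0 + b1 * X + b3 * Y_c + e

is fit by ordinary least squares, where Y_nc is the log CN-specific frequency
of subset c in CN n, Y_c its log overall frequency, and X the 0/1 group
indicator. A pseudocount (default 1e-3) is added before taking logs. b1
measures group-differential enrichment of the subset within the CN beyond
what its overall abundance predicts; its two-sided p value is reported
unadjusted (Benjamini-Hochberg available by flag).

Patients lacking any cell in a CN contribute Y_nc = log(pseudocount) by
default (``drop_missing=True`` drops them instead).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .frequencies import FrequencyTables

log = logging.getLogger(__name__)


def differential_enrichment(tables: FrequencyTables, groups: pd.Series,
                            pseudocount: float = 1e-3,
                            drop_missing: bool = False,
                            adjust: bool = False) -> pd.DataFrame:
    """Per-(CN, subset) group coefficient b1 with its p value.

    ``groups``: per-patient 0/1 indicator (second group level coded 1, so
    positive b1 means enriched in that group). Rows require >= 3 usable
    patients per group; otherwise the (CN, subset) is skipped with a log note.
    """
    g = groups.reindex(tables.cn_specific.index).to_numpy(float)
    rows = []
    for (cn, subset) in tables.cn_specific.columns:
        y_nc = tables.cn_specific[(cn, subset)].to_numpy(float)
        y_c = tables.overall[subset].to_numpy(float)
        if drop_missing:
            use = ~np.isnan(y_nc) & ~np.isnan(y_c) & ~np.isnan(g)
        else:
            y_nc = np.nan_to_num(y_nc, nan=0.0)
            use = ~np.isnan(y_c) & ~np.isnan(g)
        if use.sum() == 0 or min((g[use] == 0).sum(), (g[use] == 1).sum()) < 3:
            log.info("skipping (CN %s, %s): fewer than 3 usable patients per group",
                     cn, subset)
            continue
        ly_nc = np.log(pseudocount + y_nc[use])
        ly_c = np.log(pseudocount + y_c[use])
        design = sm.add_constant(np.column_stack([g[use], ly_c]),
                                 has_constant="add")
        fit = sm.OLS(ly_nc, design).fit()
        rows.append({"cn": cn, "subset": subset,
                     "beta0": fit.params[0], "beta1": fit.params[1],
                     "beta3": fit.params[2], "p": fit.pvalues[1],
                     "n_patients": int(use.sum())})
    res = pd.DataFrame(rows)
    if adjust and len(res):
        res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


def enrichment_heatmap_table(result: pd.DataFrame, alpha: float = 0.05,
                             p_col: str = "p") -> tuple[pd.DataFrame, pd.DataFrame]:
    """CN x subset matrices of b1 coefficients and significance flags.

    Positive coefficients mean enrichment in the group coded 1.
    """
    if result.empty:
        raise ValueError("empty enrichment result")
    coef = result.pivot(index="cn", columns="subset", values="beta1")
    flag = (result.pivot(index="cn", columns="subset", values=p_col) < alpha)
    return coef, flag
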