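"""Cohort-level summaries: mean +/- SD tables and paired method comparison.

The statistics are deliberately minimal -- per-metric mean and sample SD,
and a paired two-sided t-test for reference-vs-accelerated MBF -- providing
the machinery for cohort tables without reproducing any patient analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import COMPONENTS, ComponentResult, MBFResult

__all__ = ["result_metrics", "summarize_cohort", "compare_paired"]


def result_metrics(result) -> dict:
    """Flatten a result object into named scalar metrics."""
    if isinstance(result, ComponentResult):
        out = {f"{c}_ml": result.volumes.get(c, 0.0) for c in COMPONENTS}
        out.update(
            {
                "edv_ml": result.edv,
                "inflow_ml": result.inflow,
                "ejected_ml": result.ejected,
                "direct_early_ml": result.direct_flow_split.get("early", 0.0),
                "direct_late_ml": result.direct_flow_split.get("late", 0.0),
            }
        )
        for c, k in result.ke_per_ml_at_ed.items():
            out[f"{c}_ke_ed_uJ_per_ml"] = k
        return out
    if isinstance(result, MBFResult):
        out = {"global_mbf": result.global_mbf}
        if result.pn is not None:
            out["pn"] = result.pn
        if result.tn is not None:
            out["tn"] = result.tn
        return out
    if isinstance(result, dict):
        return dict(result)
    raise TypeError(f"cannot summarise {type(result).__name__}")


def summarize_cohort(results) -> pd.DataFrame:
    """Mean +/- SD per metric over a cohort of results.

    Requires at least two results (dispersion is undefined otherwise).
    Returns a DataFrame indexed by metric with columns ``mean``, ``sd``
    and ``n``.
    """
    if len(results) < 2:
        raise ValueError("cohort summary needs at least 2 results")
    rows = [result_metrics(r) for r in results]
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1),
            "n": df.count().astype(int),
        }
    )
    summary.index.name = "metric"
    return summary


def compare_paired(values_a, values_b) -> dict:
    """Paired two-sided t-test between two methods on the same subjects.

    By convention, identical per-subject values (zero variance of the
    differences with zero mean difference) report p = 1: the data provide
    no evidence of a difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs equal-length value lists")
    if len(a) < 2:
        raise ValueError("paired comparison needs at least 2 subjects")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
        t = 0.0 if p == 1.0 else np.inf
    else:
        t, p = stats.ttest_rel(a, b)
    return {
        "mean_diff": float(diff.mean()),
        "sd_diff": float(diff.std(ddof=1)),
        "t": float(t),
        "p": float(p),
        "n": int(len(a)),
    }
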