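"""Cross-case aggregation: mean ± SE summaries and one-way ANOVA.

Frames are treated as independent observations, so SE = s/√n over
frames; a block-averaged SE is available for series with appreciable
autocorrelation.  Significance across cases uses one-way fixed-effects
ANOVA, reported both omnibus (all cases at once) and pairwise against
a base case, with star annotations at p < 0.001 (***) and p < 0.01 (**).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CaseSummary:
    case_label: str
    n: int
    mean: float
    se: float


def standard_error(values, block_size: int | None = None) -> float:
    """SE of the mean; with ``block_size`` the series is first averaged
    over non-overlapping blocks to blunt temporal autocorrelation."""
    values = np.asarray(values, dtype=float)
    if block_size is not None:
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        n_blocks = values.size // block_size
        if n_blocks < 2:
            raise ValueError("need at least 2 complete blocks")
        values = values[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    if values.size < 2:
        raise ValueError(f"need >= 2 values for a standard error, got {values.size}")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def summarize_case(series, label: str) -> CaseSummary:
    """Mean and SE (sample SD / √n) of a per-frame metric series."""
    values = np.asarray(series, dtype=float)
    if values.size < 2:
        raise ValueError(f"case {label!r}: need >= 2 values, got {values.size}")
    return CaseSummary(case_label=label, n=int(values.size),
                       mean=float(values.mean()), se=standard_error(values))


def anova_across_cases(groups) -> tuple:
    """One-way fixed-effects ANOVA over ≥ 2 metric series.

    Returns (F, p).  Identical groups give F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} values; need >= 2")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pairwise_anova(groups: dict, base_label: str) -> dict:
    """One-way ANOVA of each case against the base case."""
    if base_label not in groups:
        raise ValueError(f"base case {base_label!r} not among {list(groups)}")
    out = {}
    for label, series in groups.items():
        if label == base_label:
            continue
        f, p = anova_across_cases([groups[base_label], series])
        out[label] = {"F": f, "p": p, "stars": significance_stars(p)}
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def summary_table(case_metrics: dict, base_label: str | None = None) -> pd.DataFrame:
    """Long-format table of per-case mean ± SE for every metric, with
    omnibus and pairwise-vs-base ANOVA p-values.

    ``case_metrics`` maps case label -> {metric name -> per-frame values}.
    """
    if not case_metrics:
        raise ValueError("no cases given")
    if base_label is None:
        base_label = next(iter(case_metrics))
    metrics = sorted({m for d in case_metrics.values() for m in d})
    rows = []
    for metric in metrics:
        groups = {
            label: np.asarray(d[metric], dtype=float)
            for label, d in case_metrics.items() if metric in d
        }
        omnibus_p = np.nan
        if len(groups) >= 2 and all(g.size >= 2 for g in groups.values()):
            _, omnibus_p = anova_across_cases(list(groups.values()))
        pairwise = (pairwise_anova(groups, base_label)
                    if base_label in groups and len(groups) >= 2 else {})
        for label, values in groups.items():
            s = summarize_case(values, label)
            pw = pairwise.get(label, {})
            rows.append({
                "metric": metric, "case": label, "n": s.n,
                "mean": s.mean, "se": s.se,
                "anova_omnibus_p": omnibus_p,
                "p_vs_base": pw.get("p", np.nan),
                "stars_vs_base": pw.get("stars", ""),
            })
    return pd.DataFrame(rows)
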