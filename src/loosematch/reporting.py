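"""Rendering of study-style summary tables.

Tables have one row per (OR_age10 panel, caliper d) and one column per
(mu0 panel, model): 16 data rows and 6 value columns for the default grid.
Rounding follows the source tables — 3 decimals for type-I error rates, 2
for power, bias, percent bias and CI width; the tidy CSV always carries full
precision, rounding is display-only.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["render_table", "parse_table", "table_metrics", "METRIC_DECIMALS"]

METRIC_DECIMALS = {
    "type_i_error": 3,
    "power": 2,
    "bias": 2,
    "pct_bias": 2,
    "ci_width": 2,
    "mean_wald_width": 2,
}

#: tidy-frame column backing each rendered metric
_METRIC_SOURCE = {
    "type_i_error": "rejection_rate",
    "power": "rejection_rate",
    "bias": "bias",
    "pct_bias": "pct_bias",
    "ci_width": "ci_width",
    "mean_wald_width": "mean_wald_width",
}

_MODEL_ORDER = ["unconditional", "conditional"]


def table_metrics(hypothesis: str) -> tuple[str, ...]:
    """Metrics rendered for a hypothesis (type-I error/bias under the null;
    power/percent bias under the alternative; widths under both)."""
    if hypothesis == "null":
        return ("type_i_error", "bias", "ci_width")
    return ("power", "pct_bias", "ci_width")


def render_table(tidy: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot tidy metric rows into a study-style table.

    Rows are (or_age_per10, caliper_d); columns are (mu0, model) with mu0
    panels ordered by decreasing mu0 (increasing mean-age gap).  Missing
    cells render as NaN, never as silent zeros.
    """
    if metric not in _METRIC_SOURCE:
        raise ValueError(f"unknown metric {metric!r}; known: {sorted(_METRIC_SOURCE)}")
    source = _METRIC_SOURCE[metric]
    if source not in tidy.columns:
        raise ValueError(f"tidy frame lacks column {source!r}")
    table = tidy.pivot_table(
        index=["or_age_per10", "caliper_d"],
        columns=["mu0", "model"],
        values=source,
        aggfunc="mean",
    ).round(METRIC_DECIMALS[metric])
    mu0s = sorted(tidy["mu0"].unique(), reverse=True)
    cols = [
        (mu0, model)
        for mu0 in mu0s
        for model in _MODEL_ORDER
        if (mu0, model) in table.columns
    ]
    table = table.loc[:, cols]
    table.columns.names = ["mu0", "model"]
    return table


def parse_table(path_or_buf) -> pd.DataFrame:
    """Read back a rendered table CSV with its two-level header and index."""
    return pd.read_csv(path_or_buf, header=[0, 1], index_col=[0, 1])


def read_metrics(path_or_buf) -> pd.DataFrame:
    """Read a tidy metrics CSV, keeping the literal hypothesis label 'null'
    (which pandas would otherwise parse as missing)."""
    return pd.read_csv(path_or_buf, keep_default_na=False, na_values=["", "NaN", "nan"])
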