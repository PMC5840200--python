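#!/usr/bin/env python
"""Render study-style tables from the tidy metrics of a grid run.

Reads results/study/metrics.csv (produced by 03_run_study_grid.py) and
rewrites the per-metric tables — rows (OR_age10 panel, caliper d), columns
(mu0 panel, model) — printing each one.  Pure re-rendering: no simulation.
"""

from pathlib import Path

from loosematch.reporting import read_metrics, render_table, table_metrics

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    metrics_csv = STUDY / "metrics.csv"
    if not metrics_csv.exists():
        raise SystemExit(f"{metrics_csv} not found; run analysis/03_run_study_grid.py first")
    tidy = read_metrics(metrics_csv)
    for hypothesis in tidy["hypothesis"].unique():
        sub = tidy[tidy["hypothesis"] == hypothesis]
        for metric in table_metrics(hypothesis):
            table = render_table(sub, metric)
            path = STUDY / f"table_{hypothesis}_{metric}.csv"
            table.to_csv(path)
            print(f"\n=== {metric} ({hypothesis} hypothesis) -> {path.name} ===")
            print(table.to_string())


if __name__ == "__main__":
    main()
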