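#!/usr/bin/env python
"""Simulate one matched dataset and walk through both analyses.

Uses the strong-confounding cell (20-year mean-age gap, OR_e = 1.5) where
the two models disagree most: fits the unconditional and conditional models,
shows the Mantel-Haenszel odds ratio over 5-year age strata, and writes the
dataset to results/example_dataset.csv.  On a single dataset the matching
distortion is already visible: the unconditional exposure odds ratio sits
below the conditional one.
"""

import math
from pathlib import Path

import numpy as np

from loosematch import (
    Scenario,
    StratumTable,
    fit_conditional,
    fit_unconditional,
    mantel_haenszel_or,
    simulate_matched_dataset,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20180302


def main() -> None:
    scenario = Scenario(mu0=50.0, or_exposure=1.5, or_age_per10=2.0, caliper_d=2, n_cases=900)
    dataset = simulate_matched_dataset(scenario, np.random.default_rng(SEED))
    dataset.validate()
    OUT.mkdir(exist_ok=True)
    dataset.to_csv(OUT / "example_dataset.csv")

    print(f"scenario: {scenario.scenario_id}  (true beta_e = ln 1.5 = {scenario.beta_e_true:.4f})")
    print(f"{dataset.design.n1} matched pairs written to {OUT / 'example_dataset.csv'}\n")

    for result in (fit_unconditional(dataset), fit_conditional(dataset)):
        or_hat = math.exp(result.beta_e_hat)
        print(
            f"{result.model:>14}: beta_e = {result.beta_e_hat:6.4f} "
            f"(OR = {or_hat:.3f}), SE = {result.se:.4f}, p = {result.p_two_sided:.2e}"
        )

    # Mantel-Haenszel over coarse age strata, the classical stratified check
    df = dataset.to_frame()
    bins = (df["age"] // 5) * 5
    tables = []
    for _, g in df.groupby(bins):
        tables.append(
            StratumTable(
                a=int(((g.outcome == 1) & (g.exposure == 1)).sum()),
                b=int(((g.outcome == 0) & (g.exposure == 1)).sum()),
                c=int(((g.outcome == 1) & (g.exposure == 0)).sum()),
                d=int(((g.outcome == 0) & (g.exposure == 0)).sum()),
            )
        )
    print(f"\nMantel-Haenszel OR over {len(tables)} five-year age strata: "
          f"{mantel_haenszel_or(tables):.3f}")
    concord = np.mean(
        dataset.to_stratum_arrays()[0][:, 0] == dataset.to_stratum_arrays()[0][:, 1]
    )
    print(f"case/control exposure concordance within pairs: {concord:.3f} "
          "(matching distortion: well above the ~0.58 expected for independent draws)")


if __name__ == "__main__":
    main()
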