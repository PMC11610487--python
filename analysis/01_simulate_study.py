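#!/usr/bin/env python
"""Generate the synthetic free-running study.

Writes DD and LL expression matrices (12 time points each, CT1-CT45, one
sample per time point), plants 100 fold-2 differentially expressed
transcripts (higher in DD), and stores the ground truth for the recovery
analyses of the later steps.
"""
from pathlib import Path

import numpy as np

from waspclock.core_io import write_expression
from waspclock.synthdata import (SimulationConfig, planted_de, simulate,
                                 write_ground_truth)

SEED = 7
N_TRANSCRIPTS = 10_000
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_transcripts=N_TRANSCRIPTS, seed=SEED)
    dd, ll, truth = simulate(cfg)
    rng = np.random.default_rng(SEED + 1)
    de_ids = rng.choice(dd.transcript_ids, size=100, replace=False)
    dd, ll, truth = planted_de(dd, ll, truth, de_ids, fold=2.0, direction="DD")

    write_expression(dd, OUT / "expression_DD.tsv")
    write_expression(ll, OUT / "expression_LL.tsv")
    write_ground_truth(truth, OUT / "ground_truth.tsv")

    n_rhy = int(truth[truth.condition == "DD"]["rhythmic"].sum())
    print(f"simulated {N_TRANSCRIPTS} transcripts (seed {SEED}): "
          f"{n_rhy} rhythmic ({100 * n_rhy / N_TRANSCRIPTS:.1f}%), "
          f"periods {cfg.period_dd}h (DD) / {cfg.period_ll}h (LL), "
          f"100 planted fold-2 DE transcripts up in DD")
    print(f"wrote {OUT}/expression_{{DD,LL}}.tsv and ground_truth.tsv")


if __name__ == "__main__":
    main()
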