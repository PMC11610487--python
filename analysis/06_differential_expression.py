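#!/usr/bin/env python
"""Differential expression between DD and LL and recovery of the planted
fold-2 transcripts.

With no biological replicates, DE is called on the ratio of per-condition
medians with a 1.5-fold cutoff; transcripts are stratified as DDu / DDh /
LLh / LLu and the planted set from step 01 is scored.
"""
import json
from pathlib import Path

import pandas as pd

from waspclock.core_io import default_designs, read_expression
from waspclock.diffexpr import fold_change_de

DATA = Path("results/data")
OUT = Path("results/diffexpr")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    designs = default_designs()
    dd = read_expression(DATA / "expression_DD.tsv", designs["DD"])
    ll = read_expression(DATA / "expression_LL.tsv", designs["LL"])
    table, counts = fold_change_de(dd, ll, cutoff=1.5, gene_level=False)
    table.to_csv(OUT / "diffexpr.tsv", sep="\t", index=False)

    truth = pd.read_csv(DATA / "ground_truth.tsv", sep="\t")
    planted = set(truth.loc[truth["de_direction"] == "DD", "transcript_id"])
    tab = table.set_index("id")
    rec = float((tab.loc[sorted(planted), "stratum"] == "DDu").mean()) if planted else None
    nulls = tab.index.difference(sorted(planted))
    false = float((tab.loc[nulls, "stratum"] == "DDu").mean())

    print(f"strata: {counts['DDu']} up in DD (>1.5x), {counts['DDh']} higher in DD, "
          f"{counts['LLh']} higher in LL, {counts['LLu']} up in LL "
          f"({counts['excluded']} excluded)")
    if rec is not None:
        print(f"planted fold-2 recovery: {100 * rec:.0f}% called DDu; "
              f"false DDu rate among nulls {100 * false:.2f}%")
    (OUT / "summary.json").write_text(json.dumps(
        {"counts": counts, "planted_recovery": rec, "false_ddu_rate": false},
        indent=2))


if __name__ == "__main__":
    main()
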