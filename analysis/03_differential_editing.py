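#!/usr/bin/env python
"""Differential editing between silenced conditions and the control, plus
per-site specificity signatures and a conservation comparison.

Only sites quantified in at least two replicates per condition are tested
(one-tailed Welch, direction of the observed difference).  Signatures use the
PDS-silenced condition as the general-chlorosis control.  As a conservation
check in the spirit of cross-species site catalogues, the control-called site
set is intersected with the planted truth keyed by (gene, offset).

Writes results/diff_<condition>.tsv, results/signatures.tsv,
results/conservation.tsv and results/editing_bars.png.
"""

from pathlib import Path

import pandas as pd

from plastedit.differential import (classify_signatures, compare_conditions,
                                    conservation_compare, plot_editing_bars,
                                    summarize)
from plastedit.reference import PlastomeReference

RESULTS = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.05


def condition_table(table: pd.DataFrame, cond: str) -> pd.DataFrame:
    sub = table[table["condition"] == cond]
    counts = sub.groupby("site_id")["efficiency"].count()
    return sub[sub["site_id"].isin(counts[counts >= 2].index)]


def main() -> None:
    table = pd.read_csv(RESULTS / "efficiencies.tsv", sep="\t")
    ctl = condition_table(table, "control")
    results = {}
    for cond in ("IPI1", "ISE2", "PDS"):
        res = compare_conditions(ctl, condition_table(table, cond),
                                 alpha=ALPHA)
        res.to_csv(RESULTS / f"diff_{cond}.tsv", sep="\t", index=False)
        results[cond] = res
        print(f"{cond} vs control: {summarize(res)}")

    signatures = classify_signatures(results, stress_control="PDS")
    signatures.to_csv(RESULTS / "signatures.tsv", sep="\t", index=False)
    print(f"signatures: {signatures['label'].value_counts().to_dict()}")

    # conservation-style comparison: called control sites vs planted truth
    ref = PlastomeReference.from_files(RESULTS / "ref.fa",
                                       RESULTS / "genes.gff3")
    truth = pd.read_csv(RESULTS / "truth.tsv", sep="\t")
    truth = truth[truth["condition"] == "control"]
    truth = truth.assign(offset=[
        ref.position_to_coding_offset(g, p)
        for g, p in zip(truth["gene"], truth["position"])
    ])[["gene", "offset"]]
    called = (ctl.groupby(["gene", "position"], as_index=False)
              .first())
    called = called[called["gene"] != "intergenic"]
    called = called.assign(offset=[
        ref.position_to_coding_offset(g, p)
        for g, p in zip(called["gene"], called["position"])
    ])[["gene", "offset"]]
    n_cons, n_called_only, n_truth_only, joined = conservation_compare(
        called, truth)
    joined.to_csv(RESULTS / "conservation.tsv", sep="\t", index=False)
    print(f"conserved (called & planted): {n_cons}; called-only: "
          f"{n_called_only}; planted-only: {n_truth_only}")

    keep = set(truth_site_ids(table))
    plot_editing_bars(table[table["site_id"].isin(keep)],
                      RESULTS / "editing_bars.png",
                      results=results["IPI1"])
    print(f"wrote {RESULTS / 'editing_bars.png'}")


def truth_site_ids(table: pd.DataFrame) -> list[str]:
    truth = pd.read_csv(RESULTS / "truth.tsv", sep="\t")
    pos = set(truth["position"])
    return table.loc[table["position"].isin(pos), "site_id"].unique().tolist()


if __name__ == "__main__":
    main()
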