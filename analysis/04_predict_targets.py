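#!/usr/bin/env python
"""Predict binding sites for the IPI1-like PPR protein on the simulated
plastome.

Builds the PWM from the bundled 13-motif PLS table via the PPR code table,
uses the plastome's own 0-order base frequencies as the scan background, and
reports the ten top-ranking windows by exact p-value.

Writes results/predicted_sites.tsv.
"""

from pathlib import Path

import pandas as pd

from plastedit.pprcode import (build_pwm, default_code_table,
                               estimate_background, parse_motifs, rank_hits,
                               scan_genome)
from plastedit.reference import PlastomeReference

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "src" / "plastedit" / "data"


def main() -> None:
    ref = PlastomeReference.from_files(RESULTS / "ref.fa",
                                       RESULTS / "genes.gff3")
    motifs = parse_motifs(DATA / "ipi1_motifs_synthetic.tsv")
    pwm = build_pwm(motifs, default_code_table(),
                    background=estimate_background(ref.seq))
    print(f"PWM: {len(pwm)} columns, consensus {pwm.consensus()}")
    hits = rank_hits(scan_genome(pwm, ref), k=10)
    hits["gene"] = [
        (ref.gene_at(int(s)) or type("x", (), {"name": "intergenic"})).name
        for s in hits["start"]
    ]
    hits.to_csv(RESULTS / "predicted_sites.tsv", sep="\t", index=False)
    with pd.option_context("display.width", 120):
        print(hits[["rank", "start", "strand", "sequence", "score",
                    "p_value", "gene"]].to_string(index=False))


if __name__ == "__main__":
    main()
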