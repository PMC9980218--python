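#!/usr/bin/env python
"""Simulate the study dataset: a 20 kb plastome with an inverted-repeat ndhB
duplicate, planted C-to-U editing truth for four conditions (control, IPI1-,
ISE2- and PDS-silenced), and 250-nt paired-end libraries per replicate
(3 control / 4 IPI1 / 3 ISE2 / 3 PDS).

Writes: results/ref.fa, results/genes.gff3, results/truth.tsv and
results/reads/<condition>_rep<k>.{sam,R1.fastq,R2.fastq}.
"""

from pathlib import Path

import numpy as np

from plastedit.pipeline import DEFAULT_REPLICATES, DEFAULT_SITE_SCHEME
from plastedit.simulate import (SimConfig, plant_editing_sites,
                                simulate_plastome, simulate_reads,
                                truth_to_tsv)

SEED = 20260924
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = SimConfig(genome_length=20_000, n_genes=10, ir_gene=True,
                    mean_depth=150.0, error_rate=0.001, seed=SEED)
    ref = simulate_plastome(cfg)
    truth = plant_editing_sites(ref, DEFAULT_SITE_SCHEME)
    ref.to_fasta(RESULTS / "ref.fa")
    ref.to_gff3(RESULTS / "genes.gff3")
    truth_to_tsv(truth, RESULTS / "truth.tsv")
    print(f"plastome: {len(ref.seq)} bp, {len(ref.genes)} gene features "
          f"(ndhB duplicated in the IR)")
    print(f"planted truth: {len(truth)} sites "
          f"({sum(t.gene.endswith('_ir') for t in truth)} mirrored into the IR)")

    rng = np.random.default_rng(SEED)
    for cond, n_reps in DEFAULT_REPLICATES.items():
        for rep in range(1, n_reps + 1):
            reads = simulate_reads(
                ref, truth, cfg, condition=cond, outdir=RESULTS / "reads",
                prefix=f"{cond}_rep{rep}",
                seed=int(rng.integers(0, 2**31 - 1)))
            print(f"  {cond} rep{rep}: {reads.n_fragments} fragments")


if __name__ == "__main__":
    main()
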