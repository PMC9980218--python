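"""End-to-end synthetic demo: simulate -> call -> diff -> predict -> tree.

The demo emulates the structure of a VIGS editing study: a control condition
and three silenced conditions (an IPI1-like editing factor, an ISE2-like
helicase, and a PDS-like general-chlorosis control), with planted per-site
editing fractions chosen so every signature class is represented.  All stages
run from a single seed and write plain-text tables plus a run log.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import classify_signatures, compare_conditions, summarize
from .phylo import bootstrap_support, read_alignment, write_newick
from .pprcode import (build_pwm, default_code_table, estimate_background,
                      parse_motifs, rank_hits, scan_genome)
from .quant import (CallThresholds, build_pileup, call_editing_sites,
                    harmonize_site_ids, name_sites)
from .simulate import (SimConfig, plant_editing_sites, simulate_plastome,
                       simulate_reads, truth_to_tsv)

# planted editing truth: (gene, coding offset, {condition: fraction}).
# ndhB-like sites respond only to IPI1 silencing; rpoB responds to both
# factor knockdowns; ndhD is depressed in every chlorotic condition
# (general stress); one site increases specifically under ISE2 silencing;
# rpoA sits at a realistically low efficiency and atpF at full editing.
DEFAULT_SITE_SCHEME: list[tuple[str, int, dict[str, float]]] = [
    ("ndhB", 101, {"control": 0.90, "IPI1": 0.30, "ISE2": 0.90, "PDS": 0.90}),
    ("ndhB", 201, {"control": 0.85, "IPI1": 0.25, "ISE2": 0.85, "PDS": 0.85}),
    ("ndhB", 301, {"control": 0.95, "IPI1": 0.40, "ISE2": 0.95, "PDS": 0.95}),
    ("rpoB", 151, {"control": 0.80, "IPI1": 0.35, "ISE2": 0.35, "PDS": 0.80}),
    ("ndhD", 121, {"control": 0.85, "IPI1": 0.40, "ISE2": 0.40, "PDS": 0.40}),
    ("psbE", 77, {"control": 0.50, "IPI1": 0.50, "ISE2": 0.95, "PDS": 0.50}),
    ("rpoA", 88, {"control": 0.0543, "IPI1": 0.0543, "ISE2": 0.0543,
                  "PDS": 0.0543}),
    ("atpF", 140, {"control": 1.0, "IPI1": 1.0, "ISE2": 1.0, "PDS": 1.0}),
]

# replicate structure of the emulated design: three control libraries, four
# for the primary silenced condition; the stress control gets three (a single
# replicate cannot be tested).
DEFAULT_REPLICATES = {"control": 3, "IPI1": 4, "ISE2": 3, "PDS": 3}


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end demo."""

    outdir: Path = Path("demo_out")
    seed: int = 1
    sim: SimConfig = field(default_factory=lambda: SimConfig(mean_depth=150.0))
    site_scheme: list[tuple[str, int, dict[str, float]]] = field(
        default_factory=lambda: list(DEFAULT_SITE_SCHEME))
    replicates: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES))
    stress_control: str = "PDS"
    alpha: float = 0.05
    thresholds: CallThresholds = CallThresholds()
    top_k: int = 10
    bootstrap_reps: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        self.outdir = Path(self.outdir)


@dataclass
class DemoReport:
    outdir: Path
    truth: pd.DataFrame
    efficiencies: pd.DataFrame
    diff: dict[str, pd.DataFrame]
    signatures: pd.DataFrame
    predicted: pd.DataFrame
    summary: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_demo(config: PipelineConfig) -> DemoReport:
    """Run the full synthetic analysis; see module docstring.

    Writes, under ``config.outdir``: the reference (FASTA + GFF3), the planted
    truth, per-replicate reads and alignments, the per-site efficiency table,
    one differential table per silenced condition, signature labels, the
    top-k predicted binding sites, the bootstrap NJ tree, and a JSON run log.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- simulate -------------------------------------------------------
    sim_cfg = SimConfig(**{**config.sim.__dict__, "seed": config.seed})
    ref = simulate_plastome(sim_cfg)
    truth = plant_editing_sites(ref, config.site_scheme)
    ref.to_fasta(out / "ref.fa")
    ref.to_gff3(out / "genes.gff3")
    truth_to_tsv(truth, out / "truth.tsv")

    # --- per-replicate reads, pileup, calling ---------------------------
    long_rows = []
    reads_dir = out / "reads"
    for cond, n_reps in config.replicates.items():
        for rep in range(1, n_reps + 1):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            reads = simulate_reads(
                ref, truth, sim_cfg, condition=cond, outdir=reads_dir,
                prefix=f"{cond}_rep{rep}", seed=rep_seed,
            )
            pileup = build_pileup(
                reads.sam, ref,
                include_multimapped=config.thresholds.include_multimapped,
            )
            sites = name_sites(
                call_editing_sites(pileup, ref, config.thresholds), ref
            )
            sites["condition"] = cond
            sites["replicate"] = rep
            long_rows.append(sites)
    efficiencies = harmonize_site_ids(pd.concat(long_rows, ignore_index=True),
                                      ref)
    eff_cols = ["site_id", "gene", "position", "strand", "condition",
                "replicate", "efficiency", "edited_count", "unedited_count",
                "depth", "n_multimapped"]
    efficiencies = efficiencies[eff_cols]
    efficiencies.to_csv(out / "efficiencies.tsv", sep="\t", index=False)

    # --- differential editing ------------------------------------------
    def cond_table(cond: str) -> pd.DataFrame:
        sub = efficiencies[efficiencies["condition"] == cond]
        ok = sub.groupby("site_id")["efficiency"].count()
        return sub[sub["site_id"].isin(ok[ok >= 2].index)]

    control_tbl = cond_table("control")
    diff: dict[str, pd.DataFrame] = {}
    for cond in config.replicates:
        if cond == "control":
            continue
        res = compare_conditions(control_tbl, cond_table(cond),
                                 alpha=config.alpha)
        res.to_csv(out / f"diff_{cond}.tsv", sep="\t", index=False)
        diff[cond] = res
    signatures = classify_signatures(diff, stress_control=config.stress_control)
    signatures.to_csv(out / "signatures.tsv", sep="\t", index=False)

    # --- binding-site prediction ---------------------------------------
    data_dir = Path(__file__).parent / "data"
    motifs = parse_motifs(data_dir / "ipi1_motifs_synthetic.tsv")
    pwm = build_pwm(motifs, default_code_table(),
                    background=estimate_background(ref.seq))
    predicted = rank_hits(scan_genome(pwm, ref), k=config.top_k)
    predicted.to_csv(out / "predicted_sites.tsv", sep="\t", index=False)

    # --- phylogeny ------------------------------------------------------
    aln = read_alignment(data_dir / "ipi1_orthologs_synthetic.afa")
    tree = bootstrap_support(aln, n_reps=config.bootstrap_reps,
                             seed=config.seed)
    write_newick(tree, out / "ipi1_orthologs.nwk")

    # --- reconcile truth vs calls --------------------------------------
    truth_df = pd.read_csv(out / "truth.tsv", sep="\t")
    ctl_truth = truth_df[truth_df["condition"] == "control"]
    called_ctl = (
        efficiencies[efficiencies["condition"] == "control"]
        .groupby("position")["efficiency"].mean()
    )
    recon = ctl_truth.assign(
        called_mean=ctl_truth["position"].map(called_ctl)
    )
    recon.to_csv(out / "truth_vs_called.tsv", sep="\t", index=False)

    summary = {
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "n_planted_sites": len(truth),
        "n_called_sites": int(efficiencies["site_id"].nunique()),
        "planted_recovered": int(recon["called_mean"].notna().sum()),
        "per_condition": {c: summarize(d) for c, d in diff.items()},
        "signature_counts": signatures["label"].value_counts().to_dict(),
        "top_hit": predicted.iloc[0][["start", "strand", "p_value"]].to_dict()
        if len(predicted) else None,
        "input_checksums": {
            p.name: _sha256(p)
            for p in [out / "ref.fa", out / "genes.gff3", out / "truth.tsv"]
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return DemoReport(out, truth_df, efficiencies, diff, signatures,
                      predicted, summary)
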