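# Methods

## Scope and model

The package analyses C-to-U RNA editing of chloroplast (plastome-encoded)
transcripts. Editing converts specific cytidines to uridines
post-transcriptionally; in cDNA sequencing an edited transcript reads T
where the genome has C on the coding strand. For a minus-strand gene the
forward reference shows G and the edited evidence is A. All modules share
one coordinate frame: the forward strand of a single plastome sequence,
1-based inclusive (the SAM/GFF3 convention, which both consumed formats
use).

### Editing efficiency

The per-site estimand is the edited transcript fraction, estimated as
T/(C+T) from pileup counts restricted to the two informative bases
(reads showing any other base at the site are excluded from both counts),
or as the same ratio of trace peak heights for Sanger bulk sequencing.
The 0/0 case is reported as *undefined*, deliberately distinct from an
efficiency of 0. Peak *heights* (not areas) are used for traces: the
simpler deterministic choice, since real base-callers report both and the
two are nearly proportional at a single position.

### Site calling

A site is called at position p when

1. the coding-strand reference base is C (forward C in + genes, forward G
   in − genes; intergenic positions are scanned in both orientations and
   labelled `intergenic`),
2. total depth ≥ `min_depth` (default 10),
3. edited reads ≥ `min_edited_reads` (default 2), and
4. efficiency ≥ `min_efficiency` (default 0.01).

The numeric defaults are deliberately permissive — the emulated analysis
used a qualitative "low stringency" SNP filter whose thresholds are not
published — and are all configurable. At these defaults, low-depth
libraries show occasional one-off noise calls (two sequencing errors at the
same position); the catalogue-naming step (below) and the ≥2-replicate
filter before differential testing absorb them. A user-supplied BED mask
(known SNPs, RT artifacts) is honored.

Multi-mapped records (MAPQ 0 or the secondary flag) are **included** by
default and counted once per mapped location. This is what makes editing
sites inside the inverted repeat observable at all: reads from either IR
copy of an ndhB-like gene align to both copies, and excluding them would
blank the whole region. `include_multimapped=False` removes those records
entirely, which lowers depth at IR sites by exactly the number of MAPQ-0
records and leaves efficiencies unchanged when the two copies are edited
identically (which the generator guarantees by mirroring).

### Site naming

Within each gene, sites are numbered 1..k in 5′→3′ transcript order
(descending genome coordinate for minus-strand genes); a single-site gene
keeps its bare name — `ndhD-1`, `ndhD-2`, `psbL`. Because per-replicate
numbering would shift whenever a noise call lands inside a gene with real
sites, multi-replicate tables are re-keyed once over the pooled set of
positions seen in ≥2 libraries; one-off calls get a provisional
`<gene>@<position>` id that cannot perturb the catalogue numbering. The IR
duplicate is a separate feature (`ndhB_ir`) with its own numbering, keeping
ids unique.

### Differential editing

Replicate efficiencies are compared with a one-tailed Welch t-test:
t = (x̄_b − x̄_a) / √(s²_a/n_a + s²_b/n_b) with Satterthwaite df. The tail
is taken in the direction of the *observed* difference by default, because
the emulated analyses declared both significant decreases and significant
increases with a one-tailed test without stating a direction rule; fixed
directions and a two-tailed mode are flags. Under the null, the
auto-direction rule doubles the nominal one-tailed rate (it is a two-tailed
test at 2α); the fixed-direction test is calibrated at α. Zero variance in
both samples with equal means returns (t=0, p=0.5) by convention.

No multiple-testing correction is applied by default, mirroring the
per-site raw p<0.05 asterisk convention of the emulated figures;
Benjamini–Hochberg is available behind a flag, as are arcsine/logit
transforms (efficiencies are tested on the raw [0,1] scale by default).

Leaf-age trends reuse the same test with the oldest leaf (lowest leaf
number — leaves are numbered from the bottom of the plant) as the test
condition against the youngest.

### Specificity signatures

Given per-condition differential results against a common control and a
designated general-chlorosis control (PDS-like), each site receives exactly
one label: significant in the stress control → `general_stress` (editing
loss attributable to chloroplast dysfunction rather than the silenced
factor); otherwise significant in exactly one condition →
`specific:<condition>`; in two or more → `shared`; nowhere → `unaffected`.
Without a stress control the labels are restricted to the last three.
Because one spurious rejection flips a label, the acceptance-level
classification check runs the per-comparison test at α = 0.01 (a
Bonferroni-style tightening of 0.05 across the three conditions); the
pipeline default remains α = 0.05 per comparison.

### PPR-code prediction

A PLS protein's repeat residues at position 6 and 1′ (first residue of the
following motif) map to a nucleotide preference via a code table; one
column per PLS motif in N→C order gives the PWM (the N-terminal motif pairs
with the 5′ base). Design choices:

- **No extra column** for the base 3′ of the last motif: the per-motif
  probability presentation being reproduced assigns columns to motifs only.
- **E/E+/DYW regions** contribute no columns and are dropped at parse time.
- **Unlisted residue pairs and gap residues** get a uniform fallback
  column.
- **Code table**: the published quantitative weighting scheme is not
  redistributable here, so the shipped `ppr_code_synthetic.tsv` encodes the
  canonical qualitative code (T/D→G, T/N→A, S/N→A, S/D→G, N/D→U, N/S→C,
  N/N→pyrimidine) with synthetic weights; the file is an editable TSV and
  any table with the same columns can be substituted.
- **Background**: 0-order frequencies estimated from the scanned genome by
  default (plastomes are AT-rich, ~62%), uniform optional.
- **Both genome strands** are scanned; minus-strand hits are reported in
  forward coordinates. Transcript-only scanning can be emulated by passing
  a transcript sequence.

Scores are log2 odds after a pseudocount of 0.01 (avoids −∞; configurable).
For exact p-values, each column's scores are shifted to a zero minimum and
rounded to multiples of a step equal to 1/1000 of the total attainable
score range; the null pmf of the integer total score under the background
is the convolution of the per-column four-outcome distributions, and the
p-value of a window is the tail sum at its integer score. Discretization
error is bounded by half a step per column. Ambiguous bases take the
background-weighted average column score. Ties in ranked output break by
descending score, then ascending coordinate, plus strand first, making the
top-k table deterministic.

### Phylogeny

p-distance = proportion of differing residues over comparable columns;
pairwise gap deletion by default (complete deletion behind a flag), and a
pair with zero comparable columns is an error naming the pair. Neighbor
joining follows Saitou–Nei: join the pair minimising
Q(i,j) = (n−2)d(i,j) − r_i − r_j, standard branch-length and
distance-update formulas, final three-point join, unrooted tree. Negative
branch lengths (non-additive input) are clamped to zero with a warning —
standard presentation practice. Ties in Q break by lowest index, so taxon
order fixes the output. Bootstrap resamples alignment columns with
replacement; support for each internal bipartition of the full-data tree is
the fraction of replicate trees containing it, reported as a fraction in
[0,1] on the node label (the "per million" phrasing sometimes seen in
figure legends is treated as a typographical artifact; fractions are
unambiguous). Default 1,000 replicates, deterministic under the seed.

## The synthetic-data generator

The generator emulates the deposited experiment's *structure*, not its
sequences: a ~20 kb AT-rich toy plastome (a real plastome is ~160 kb;
scaled down so every stage runs in seconds) with ~10 non-overlapping genes
on both strands, one gene duplicated in reverse complement as an IR pair;
250-nt paired-end reads (the platform's read length in the emulated study);
3 control and 4 silenced-condition replicates where that structure matters;
per-site planted editing fractions spanning the observed range (from ~0.05,
the magnitude of the weakest real site, to 1.0). Libraries are unstranded
— inferred from random-hexamer double-stranded cDNA synthesis — so either
mate is the forward read with probability ½.

Each read overlapping a planted site carries the edited base independently
with the site's planted fraction (the binomial read-sampling model implied
by representing editing as an edited-read fraction); substitution errors
are added per base at `error_rate` (default 0.001), replacing the base
uniformly with one of the other three. Reads are emitted *pre-aligned* as a
truth SAM — the original mapping used commercial software that is out of
scope, and truth alignments remove the aligner as a confound. Reads wholly
inside an IR copy additionally get a MAPQ-0 secondary alignment at the
mirrored position of the other copy (reverse-complemented, strand
flipped), reproducing how an aligner reports IR multi-mappers. Fragment
lengths are N(450, 60) clipped to [300, 600]; base quality is a constant Q40.

Planting substitutes a C at the requested coding-strand offset when needed
and re-synchronises the IR duplicate, mirroring both the substitution and
the truth row, so the two copies stay identical at the transcript level.
Sanger traces are simulated as four channel heights with
T/(T+C) = fraction exactly at zero noise, plus optional Gaussian channel
noise.

What the generator does **not** model — and therefore what passing tests do
not establish about real data: indels and splicing, PCR duplicates,
position- and quality-dependent error profiles, strand bias, coverage
non-uniformity from library chemistry, reverse-transcription artifacts,
partial IR homology (the simulated copies are exact), U-to-C editing, and
origin-spanning reads (fragments are sampled on a linear frame although the
plastome is circular). Recovery results on this generator demonstrate the
correctness of the counting, testing and ranking machinery under the
declared sampling model, not robustness to real-library artifacts.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is byte-reproducible
under it (generator outputs, bootstrap supports, demo tables). The bundled
analysis scripts use a 20 kb genome at mean depth 150 (13 libraries); the
acceptance checks use depth 1000 for caller recovery, 10,000 replicates for
Welch calibration, 50 random PWMs (length ≤ 8, full 4^L enumeration) for
p-value exactness, 100 seeded trials for planted-motif recovery, and 4–8
taxon additive matrices for neighbor-joining recovery — sizes chosen so the
whole suite runs in a couple of minutes on one CPU while keeping
Monte-Carlo error small relative to the tested tolerances.

## Bundled data

All three data files under `src/plastedit/data/` are synthetic stand-ins,
as their filenames state: the PPR code weights (see above), a 13-motif
PLS table for an IPI1-like protein (the real protein's residues are not
redistributable; the table exercises the same structure, including a
trailing gap residue and excluded E/E+/DYW rows), and a C-terminal protein
alignment of 12 IPI1-like orthologs in which a four-taxon monocot-like
clade lacks the terminal DYW triplet — the feature whose phylogenetic
separation the tree stage demonstrates.

## Known limitations

- The caller is substitution-only: indel/splice-aware calling and U-to-C
  editing are out of scope.
- Welch testing on 3–4 replicates has limited power for small effects;
  the pipeline reports raw p-values by design and leaves error-rate control
  across sites to the user (BH available).
- The auto-direction one-tailed test is anti-conservative under the null
  (2α); use a fixed direction or the two-tailed flag when calibration at α
  matters.
- PPR code weights are qualitative stand-ins; predictions should be read as
  a demonstration of the scanning machinery, not as biological predictions
  for any real protein.
- NJ with p-distances is presentation-grade phylogenetics; no rate
  correction or model-based inference is attempted.
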