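# degdet — profiling protein degradation determinants from sequence

Most newly discovered human proteins — noncanonical translation products of
uORFs, lncRNA ORFs and other unannotated reading frames — are suspected to
be unstable: marked for rapid proteasomal or autophagic degradation rather
than folded into functional molecules.  Whether a given sequence carries
such marks can be read, to a useful first approximation, directly from its
primary sequence.  `degdet` is a library for doing exactly that, for anyone
comparing groups of proteins (canonical vs. noncanonical, translated vs.
untranslated, phenotype vs. no phenotype) by their degradation propensity.

## What it computes

For each protein sequence, five classes of degradation determinants:

* **C-terminal tail hydrophobicity (CTTH)** — the mean Kyte–Doolittle
  hydropathy of the last 30 residues,
  `CTTH = (1/30) Σᵢ KD(sᵢ)` over the terminal window, plus the GRAVY of the
  rest of the chain.  Hydrophobic tails trigger proteasomal degradation; a
  quartile-threshold classifier flags proteins whose tail is much more
  hydrophilic (CTTH < −0.963 with a hydrophobic rest) or much more
  hydrophobic (CTTH > −0.110 with a hydrophilic rest, excluding C-terminal
  transmembrane domains) than the rest of the chain.
* **Terminal degrons** — anchored exact matching of ΔPSI-ranked N-end
  motifs (placed after the initiator Met) and C-end motifs (literal
  suffix), with ΔPSI ≤ −0.4 filtering and top-k selection.
* **KFERQ-like motifs** — per-pentapeptide classification into canonical,
  phosphorylation-activated and acetylation-activated chaperone-mediated
  autophagy motifs, with length-normalized densities.
* **Terminal intrinsically disordered regions** — maximal terminal runs of
  per-residue disorder score > 0.5, called at ≥ 30 residues, from
  IUPred-style score files.
* **Tail-anchor architecture and aggregation** — TA classification (single
  C-terminal TMD ≤ 29 aa, tail ≤ 29 aa, no signal peptide) from
  TOPCONS-style topology strings, and the fraction of residues with
  beta-pairing free energy < −5 at probability > 0.01 from PASTA-style
  tables.

Around the scanners sit the pieces that make group claims defensible: a
composition-preserving **shuffle null** (within-sequence residue
permutation, which erases anchored/positional signal while fixing length
and composition), and the **comparison layer** — Wilcoxon rank-sum with
rank-biserial `r = 1 − 2U/(n₁n₂)`, signed-rank on paired deltas, Fisher's
exact test with conditional-MLE odds ratios, McNemar on discordant pairs,
Benjamini–Hochberg adjustment, Wilson continuity-corrected proportion CIs,
Spearman correlation and an exact Poisson rate test for motif densities.

A first-class synthetic-data generator produces canonical-like and
noncanonical-like datasets with controlled composition, log-normal lengths
(floor 60 aa), an exponentially tilted tail composition achieving a chosen
mean-CTTH shift, and planted degrons / KFERQ motifs / TA architectures /
terminal IDR runs at exact prevalences — with ground-truth tables, so every
stage of the pipeline is testable end to end without any external predictor
or download.

## Worked example

```bash
python examples/03_two_group_study.py
```

generates the default two-group study — 5,000 canonical-like sequences
(C-end degron prevalence 8.4%) vs. 5,000 noncanonical-like sequences
(prevalence 16.8%, tail hydropathy shifted +0.15) — profiles both groups
and compares them:

```
true odds ratio      2.202
estimated odds ratio 2.080 (95% CI 1.84-2.36, Fisher p = 1.1e-32)

planted CTTH shift   +0.15
rank-biserial r      -0.146 (rank-sum p = 1.6e-36)
```

The Fisher CI covers the planted odds ratio, and the +0.15 tail-hydropathy
shift surfaces as a rank-biserial magnitude near 0.15 — a small effect that
is nonetheless decisively detected at this sample size.  The sign of `r`
follows the `1 − 2U/(n₁n₂)` convention (negative when the first group
ranks higher).  The other examples (`examples/01`–`05`) cover per-sequence
profiling, the shuffle null, KFERQ scanning and lncRNA localization.

A thin CLI wraps the same entry points:

```bash
degdet simulate --n 200 --seed 1 --out-dir sim/
degdet profile sim/sequences.fasta --degron-c src/degdet/data/degrons_c_toy.tsv \
    --disorder sim/disorder.txt --topology sim/topology.txt \
    --aggregation sim/aggregation.tsv --out-dir out/
degdet null-compare sim/sequences.fasta --seed 1 --out-dir out/
```

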