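# crypticsplice

Detection, quantification and sequence characterization of **cryptic 3'
splice sites** from splice-junction count data, built around the splicing
phenotype of the SF3B1 K700E hotspot mutation.

Mutant SF3B1 shifts branchpoint recognition by the U2 snRNP so that
normally silent intronic AG acceptors — typically 8–14 nt upstream of the
canonical acceptor, behind a weak polypyrimidine tract and an
adenosine-enriched branchpoint region — are used, splicing a short intronic
fragment into the mRNA. The package is for computational biologists who
want to call these events from junction tables (STAR `SJ.out.tab` or a
simple TSV), test them between genotype groups, characterize the cryptic
sites, intersect hits across cohorts, and validate single loci with
targeted amplicon sequencing. A fully deterministic synthetic-cohort
simulator with a machine-readable truth table makes every stage testable
without external data.

## The statistic

For an alternative 3'ss event (shared donor, canonical acceptor *c*,
cryptic acceptor *a*) in one sample, with unique junction reads
*n<sub>a</sub>* and *n<sub>c</sub>*:

```
PSI = n_a / (n_a + n_c)        (missing when n_a + n_c < min_coverage)
```

Differential splicing between WT and MUT groups follows a fixed chain on
the events × samples PSI matrix:

1. transform: ψ ↦ ln(ψ + x), pseudocount x = 0.01;
2. filter: drop events with no variability across samples (or all missing);
3. impute: event-wise mean over all samples for remaining missing cells;
4. standardize: each event row to mean 0, population SD 1;
5. test: two-sided two-sample t-test (pooled variance; Welch optional),
   optional Benjamini–Hochberg adjustment.

An event is significant when |ΔPSI| > 0.1 and p < 0.01 (the mouse-cohort
preset) or |ΔPSI| > 0.05 and p < 1e−10 (the pan-cancer preset); ΔPSI is
mean(MUT) − mean(WT) on the raw PSI scale. Significant A3SS events are then
characterized: cryptic-to-canonical distance (log₂-binned histogram),
position frequency matrices with information content IC = 2 − H(p) bits,
polypyrimidine-tract C/T fraction (offsets −20..−5), branchpoint-window A
fraction (−40..−10), and an NMD-proneness flag (frameshift / in-frame PTC)
for the included intronic sequence.

## Worked example

```bash
crypticsplice simulate --out demo/cohort --seed 1
crypticsplice run --cohort demo/cohort --out demo/run --seed 1
crypticsplice report --run-dir demo/run
```

prints

```
crypticsplice 0.1.0 — preset mouse_kpc
samples: 7 (3 WT vs 4 MUT)
events: 200 detected, 200 tested, 72 significant
event types (significant): {'A3SS': 72, 'A5SS': 0, 'exon_skip': 0}
plurality class: A3SS
cryptic-distance mode bin: [8, 16]
PPT pyrimidine fraction: canonical 0.854…, cryptic 0.552…
branchpoint A fraction: canonical 0.236…, cryptic 0.378…
NMD flags: {'frameshift': 47, 'none': 21, 'ptc_in_frame': 4}
```

Reading the output: the simulated cohort (3 wild-type vs 4 mutant
replicates, 200 genes) plants 160 A3SS events of which half respond with
ΔPSI = 0.3; the pipeline recovers 72 of the 80 responsive events at the
default thresholds, every significant event is an alternative 3'ss, the
cryptic sites cluster 8–16 nt upstream of the canonical acceptor, and the
cryptic acceptors show the weaker pyrimidine tract and upstream adenosine
enrichment the generator planted. Most inclusions are frame-shifting,
i.e. flagged as nonsense-mediated-decay prone. All result tables
(`events.tsv`, `psi_matrix.tsv`, `diff_results.tsv`, motif matrices,
site annotations, `run_manifest.json` with SHA-256 of every output) are in
`demo/run/` and are byte-identical across reruns.

The targeted-assay module works standalone:

```bash
crypticsplice amplicon --fixture murine --seed 3
# assay Map3k7_murine_like: canonical 114 bp, non-canonical 137 bp
# reads: canonical 1956, non_canonical 1044, unassigned 0; misspliced fraction 0.3480
```

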