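# Methods

## Scope and model

The package analyses alternative 3' splice-site (A3SS) usage from
splice-junction counts alone — no read alignment, no exonic coverage. An
A3SS event is a pair of junctions sharing a donor, one ending at an
annotated (canonical) acceptor and one at an unannotated (cryptic)
acceptor. A5SS events are the mirror image on a shared acceptor, and
cassette exons (exon_skip) are junctions exactly bridging the two annotated
introns flanking an annotated internal exon. Intron retention and mutually
exclusive exons are deliberately out of scope: they cannot be quantified
from junction tables, which carry no exon-body coverage.

Coordinates are 1-based inclusive intron intervals
`[first intronic base, last intronic base]`, the SJ.out.tab convention; all
internal arithmetic stays in this convention and converts to 0-based slices
only when sequence is extracted. Junctions with undefined strand are
dropped before detection (3'ss identity is strand-dependent) and only
uniquely mapping read counts are used.

**PSI.** For one event in one sample, PSI = alt/(alt + canonical) over the
unique junction reads; for exon_skip the canonical (inclusion) support is
the mean of the two flanking junction counts, since one inclusion read pair
spans both. The value is missing when alt + canonical < `min_coverage`
(default 10; this is a free choice — junction-based pipelines differ and no
single standard exists). The unbounded alt/canonical read ratio is
available separately (`compute_literal_ratio`) for users who want the raw
two-way ratio, but every statistic in the package uses the bounded PSI.

**Canonical-acceptor rule.** When several annotated acceptors pair with one
donor, the acceptor used by the longest annotated transcript is canonical;
ties break to the most-upstream acceptor in transcript sense. This is a
package convention — annotation-driven detectors need *some* canonicality
rule and none is universal.

## Differential test

The chain is fixed as transform → filter → impute → standardize → test,
mirroring the order in which the steps are naturally stated:

1. ψ ↦ ln(ψ + x); x > 0 guards ln(0), default x = 0.01 (exposed in
   `DiffSpliceConfig`). The transform compresses the right tail and spreads
   the near-zero PSI values where cryptic events live.
2. Events whose observed values are all equal (population variance 0) or
   all missing are removed.
3. Remaining missing cells are imputed with the event-wise mean over **all**
   samples, not group-wise. Group-wise imputation would manufacture group
   separation out of missingness; all-sample imputation is the conservative
   choice (it shrinks the group difference toward 0 for imputed cells).
4. Each event row is scaled to mean 0 and population (ddof = 0) SD 1.
   Standardization cannot change the t statistic (location–scale
   invariance, asserted in the tests); it is kept because it makes rows
   comparable for downstream clustering/visualisation of the matrix.
5. Two-sided two-sample t-test per event, pooled variance by default
   (Welch available), via `scipy.stats.ttest_ind`. ΔPSI is reported on the
   raw PSI scale from the observed (non-imputed) values. Events where
   either group has fewer than two observed values get a missing p and are
   never significant. Benjamini–Hochberg adjusted p-values
   (statsmodels) are always reported; whether significance uses raw or
   adjusted p is a config switch (`adjust`), defaulting to raw p to match
   the threshold presets below.

Significance needs both |ΔPSI| > `delta_psi_min` and p < `p_max`:
`mouse_kpc` preset (0.1, 0.01), `pan_cancer` preset (0.05, 1e−10). The
ΔPSI bound is interpreted as a bound on the absolute group-mean difference;
a per-sample reading would be incompatible with a two-group test.

Note that the t statistic is **not** invariant to the pseudocount x:
ln(ψ + x) for different x are not affine images of each other, so
borderline events can enter or leave the significant set as x moves. Only
the standardization step is exactly t-invariant.

## Synthetic cohorts

The simulator generates what the pipeline consumes — a toy genome (one
gene per contig), GTF annotation with CDS, per-sample junction tables, a
sample sheet and a truth table — and emulates the statistical structure of
a two-genotype junction-count study:

| parameter | default | meaning |
|---|---|---|
| `n_wt`, `n_mut` | 3, 4 | replicates per genotype (the reference design) |
| `n_genes` | 200 | one planted event per gene |
| `background_event_mix` | A5SS 0.1, exon_skip 0.1 | decoy classes; the remaining 80% are A3SS |
| `fraction_responsive` | 0.5 | fraction of A3SS events with a genotype effect |
| `baseline_psi_wt` | 0.05 | cryptic usage in WT (near-silent acceptors) |
| `delta_psi_effect` | 0.3 | PSI shift in responsive MUT events |
| `coverage_mean`, `coverage_dispersion` | 50, 10 | negative-binomial event coverage (var = m + m²/θ) |
| `cryptic_distance_mode`, `cryptic_distance_sigma` | 11, 0.35 | discretized log-normal distance, truncated at ≥ 3 nt |
| `canonical/cryptic_ppt_pyrimidine_fraction` | 0.85 / 0.55 | target C/T fraction over each site's −20..−5 window |
| `branchpoint_a_enrichment` | 0.2 | adds to the baseline 0.25 A probability in the cryptic −40..−10 window |
| `missing_min_coverage` | 10 | threshold that turns low draws into missing PSI |
| `mutant_allele_fraction` | off | optional partial-penetrance scaling of the realized (not true) ΔPSI |

**Count model.** Per event and sample, total support N ~ NB(mean,
dispersion); cryptic reads ~ Binomial(N, ψ_true) with ψ_true = baseline
(WT) or baseline + ΔPSI (responsive MUT); the canonical junction gets the
remainder. Zero-count junctions are not written, so low NB draws become
missing PSI downstream. This overdispersed-total/binomial-split model is
the package's own choice; it is the standard minimal model for junction
counts and is exactly what the type-I/power checks need.

**Distances.** d = round(exp(N(ln mode + σ², σ))), truncated at ≥ 3 and at
what the intron can host (bounded resampling, then a sizing error). σ =
0.35 concentrates about two thirds of the mass in [8, 16) with mode 11,
implementing cryptic acceptors "concentrated 8–14 nt upstream" while
keeping a visible long tail on the log-scale histogram.

**Sequence painting.** Introns are random uniform sequence onto which
splice elements are painted with explicit precedence (donor GT and
acceptor AGs first, then the canonical PPT window, then — for responsive
genes — the cryptic PPT and branchpoint windows into the still-free
positions). Because the canonical and cryptic PPT windows physically
overlap for d ≤ 14 and the cryptic AG sits inside the canonical −20..−5
window for d in [4, 19], windows are painted to an exact pyrimidine-count
target (target fraction ~ N(parameter, 0.02), count = round(target·width),
adjusted for already-locked bases) rather than i.i.d. per-base draws: this
makes the *realized* window composition track the configured parameter,
which is the generator's contract. All A3SS genes carry a cryptic AG; only
responsive genes get the weak-PPT/adenosine signature around it.

**What the simulator does not emulate** — and therefore what passing tests
do not show about real data: mapping artifacts and alignment-dependent
junction errors; shared coverage between events of one gene; expression
differences between genotypes; sequence-dependent splice-site strength
(elements are painted, not scored); multiple transcripts per gene; allelic
imbalance (unless the penetrance knob is switched on, genotype acts
directly on ψ_true). Calibration and power results transfer to real data
only to the extent that junction counts behave like overdispersed
binomial splits.

## Site characterization

Offsets are transcript-sense relative to the 3'ss: −1 is the last intronic
base (the G of AG), +1 the first exonic base, no offset 0. Defaults: motif
window −30..+9 (39 nt, within the 30–40 nt windows typical for acceptor
logos), PPT −20..−5, branchpoint −40..−10 (standard splicing-literature
windows). Windows running off a contig are skipped per event with a log
entry. Information content is IC = 2 − H(p) bits per column, without
small-sample correction by default (profiles are often built from a
handful of events, where the correction would dominate); the correction
3/(2·ln2·n) is available as an option. N bases are excluded per position.

The NMD flag translates the included intronic sequence in the annotated
reading frame: d mod 3 ≠ 0 → `frameshift`; otherwise an in-frame stop →
`ptc_in_frame`, none → `none`; without CDS annotation → `unknown_frame`.
The reading frame is derived from the CDS length upstream of the canonical
acceptor, assuming frame 0 at the CDS 5' end.

## Cohort overlap

Cross-cohort intersection is at the gene level through an ortholog map —
coordinates are not comparable across assemblies/species. `shared` counts
distinct ortholog pairs significant on both sides; genes absent from the
map are cohort-private (logged). The pairs-based definition makes the Venn
exactly symmetric under swapping cohorts and inverting the map. No
positional correspondence within orthologs is required; requiring it would
need a liftover, which is out of scope.

## Amplicon quantification

The two-isoform assay stores both templates, both primers and one
diagnostic k-mer per isoform (default k = 16, centered on the canonical
exon–exon junction and on the non-canonical exon–intron junction). Reads
are classified by exact containment of exactly one diagnostic string in
either orientation; matching both or neither leaves a read unassigned, so
the misspliced fraction non_canonical/(canonical + non_canonical) is
unbiased for error-free reads. No alignment or mismatch tolerance is
implemented — adequate for desk-scale validation of the geometry and the
estimator, not for noisy instrument data. Amplicon lengths are measured
from the forward primer's 5' end to the reverse primer's 5' end inclusive.
The two bundled fixtures are synthetic sequences (real primer/locus
sequences are not reproduced) with the published geometries: 94 bp
canonical + 20 nt insertion → 114 bp, and 114 bp + 23 nt → 137 bp. The
murine sorted-cell assay shares the 94/114 geometry with the human one;
both geometries ship without adjudicating between them.

## Numerical and degenerate-input choices

- Determinism: every stochastic step draws from `numpy.random.default_rng`
  seeded from (config, seed); pipeline outputs are byte-identical across
  reruns and hashed into `run_manifest.json`.
- PSI with zero total support is missing regardless of `min_coverage`.
- Empty event lists, empty histograms and empty PSI matrices are valid
  degenerate outputs, not errors; malformed files raise parse errors naming
  the line, and structural problems (duplicate event ids, ragged matrices)
  raise integrity errors.
- Zero-variance rows reaching standardization raise an internal invariant
  violation — the filter step must have removed them.
- Ties in the distance-histogram mode break to the smaller bin.

## Known limitations

- Power at the reference design (3 vs 4, coverage 50) is moderate; the
  small-cohort tests assert majority recovery, not completeness.
- The pooled t-test on 3–8 discrete, skewed PSI values is only
  approximately calibrated; the simulation checks verify the empirical
  size at the defaults, not for arbitrary configurations.
- Mean imputation shrinks variance and can understate uncertainty for
  events with heavy missingness.
- Count-based tests (beta-binomial, permutation) are out of scope by
  design.
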