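# Methods

## The question and the measurement

A miRNA's targeting specificity is concentrated in its seed, the 7
nucleotides at mature positions 2–8. The package measures the *functional
cost* of seed mutations as the change in the predicted (or observed)
target-gene repertoire between two miRNAs whose seeds differ by a known
number of nucleotides (the Hamming distance, 0–7). The repertoire change
is summarized by cosine similarity of gene sets,

    cos(A, B) = |A ∩ B| / sqrt(|A| · |B|),

which lies in [0, 1], dominates the Jaccard index, and damps the influence
of miRNAs with unusually many targets. All coordinates are 1-based
inclusive; "position 4" means the fourth nucleotide of the mature
sequence. DNA-alphabet input is canonicalized (T→U, uppercased); any
character outside {A, C, G, U} is a hard error rather than being tolerated
as an ambiguity code, because a seed containing N has no defined match
set.

## Target prediction

The scanner reports the canonical site classes, built from the reverse
complement of the seed:

| class   | UTR window (5′→3′)                                | length |
|---------|---------------------------------------------------|--------|
| 7mer-m8 | revcomp(seed 1–7)                                 | 7      |
| 7mer-A1 | revcomp(seed 1–6) + A                             | 7      |
| 8mer    | revcomp(seed 1–7) + A                             | 8      |
| 6mer    | revcomp(seed 1–6)                                 | 6      |

Each occurrence of the 6-nt core is classified into its *strongest* class
(8mer beats both 7mers, which beat 6mer) and reported once; an 8mer is
never additionally counted as its constituent 7mers. The default class
set is {8mer, 7mer-m8, 7mer-A1}; 6mer sites are opt-in. Only the supplied
(sense) strand is scanned, and target sets use gene-level set semantics —
a gene counts once however many sites or transcripts it has, because the
downstream statistic counts overlapping genes. A gene enters a set iff it
has at least `min_sites` qualifying sites (default 1).

Precomputed prediction tables are filtered with a strict inequality at
the score threshold (default −0.2 on the mirSVR scale, more negative =
stronger): a record scoring exactly −0.2 is excluded. The boundary and
threshold are config-exposed.

## Overlap aggregation and comparison

Per-pair overlap is annotated with the pair's seed mismatch class and
summarized per class as box-plot statistics: quartiles by linear
interpolation, whiskers at the most extreme values within 1.5×IQR of the
box (Tukey convention; with zero IQR the whiskers collapse onto the
median). The class median is the headline statistic. Percentages are
printed to one decimal; internal values keep full precision.

Two pairs' overlap/cost proportions are compared with a Pearson χ² test
of association on the 2×2 table [[shared₁, cost₁], [shared₂, cost₂]],
df = 1, no continuity correction (the motivating comparisons involve
thousands of genes per cell, where the correction is negligible). The
"cost" of a pair is defined symmetrically as |A ∪ B| − |A ∩ B| — the genes
targeted by exactly one of the two miRNAs. This is the only symmetric
count consistent with treating overlap and non-overlap as complementary
outcomes for a pair.

## Differential expression

The pipeline assumes a normalized log2-scale matrix (a quantile
normalization utility is provided but not applied implicitly) and applies,
in order:

1. **presence filter** — remove features with fewer than 50% present
   calls across all samples, both groups pooled; strictly fewer, so
   exactly half is kept. Calls are consumed (boolean or P/M/A letters;
   marginal counts as absent), not computed: detection calls require raw
   probe-level data that is out of scope.
2. **annotation filter** — remove features absent from the probe→gene
   map.
3. **SNR collapse** — per gene keep the probe set maximizing mean/sd
   across all samples (ddof = 1); sd = 0 gives SNR = +∞ (a perfectly
   stable probe wins, logged); ties break to the lexicographically
   smallest probe id for determinism.

The test statistic is the SAM-style moderated d:

    d_i = (mean_treated_i − mean_control_i) / (s_i + s0),

with s_i the pooled standard error and s0 a fudge factor stabilizing
low-variance genes. s0 = "auto" uses median(s_i) — a deliberate
simplification of the original percentile search, config-overridable.
The null distribution comes from group-label permutations: all distinct
assignments when there are at most `n_permutations` (a 3 vs 3 contrast has
exactly 20, which are enumerated), otherwise a uniform sample. A gene is
called at |d_i| ≥ δ, and FDR(δ) is estimated as the median over
permutations of the null exceedance count divided by the observed call
count (a 90th-percentile variant would be more conservative; no π0
correction is applied, which makes the estimate conservative when true
effects inflate the permutation null). With an FDR target (default 2%)
the smallest δ meeting the target — the largest call set — is selected.
Significant genes split into up (d > 0) and down (d < 0) lists; DE-set
overlap between contrasts reuses cosine similarity, either on the pooled
up ∪ down sets (default) or on direction-tagged identifiers.

### What recovery simulations show

With 5000 genes, 3 vs 3 samples, 10% planted effects at 3× the noise sd,
the pipeline's recall of planted genes is ≈ 0.4 at FDR target 2%. This is
not an implementation artifact: the standardized contrast is
3/√(2/3) ≈ 3.7, and holding FDR ≤ 2% against a 9:1 null majority forces a
per-null rate so small that even a known-variance oracle caps near 0.70
recall; variance estimation with 4 degrees of freedom lowers it further.
Recall rises steeply with effect size (≈ 1.0 at 8 sd) and with group size,
and on pure-null matrices the procedure calls essentially nothing
(well under 1% of genes). Two-contrast DE overlap equals the planted
overlap fraction when effects are fully recoverable and is attenuated by
roughly the recall factor otherwise.

## Cross-species comparison

Ortholog maps are consumed from two-column TSV (a BioMart-export layout);
many-to-many relations are allowed and flagged. One-to-many orthologs
expand into all partners — the only policy that cannot silently drop true
overlap. For inter-specific overlap, both sets are restricted to genes
with orthologs and the species-B set is mapped into species A's namespace
before comparison (the mirrored direction and a symmetric map-both-and-
average mode are available; with a bijective map all three agree).
Intra-specific overlap never touches the map.

## Synthetic data

The generators define the study conditions and emit exact truth:

- **Panels** (`gen_mirna_panel`): constraint pairs (a, b, k[, positions])
  are satisfied by BFS over the constraint graph — each constrained
  neighbor copies its parent and mutates exactly k seed positions — with
  bounded retries and full verification, so contradictory cyclic specs
  fail loudly. Constrained groups share non-seed regions, isolating seed
  variation the way synthetic miRNA constructs do. By default, panels in
  which one seed's widest complement pattern (m8 + core + A) embeds a
  *different* seed's core are resampled: such shift collisions would make
  every planted site for one miRNA an unavoidable off-target site for the
  other.
- **UTR pools** (`gen_utr_pool`): site windows are placed at random
  non-overlapping offsets and the gene is resampled until, for every
  panel core, the occurrences in the assembled sequence are *exactly* the
  designed ones — no background, junction-spanning, or shifted hit. This
  makes planted-site recovery exact rather than statistical, which is
  deliberately cleaner than biology: real UTRs contain chance matches,
  G:U wobbles and context effects that the generator excludes, so passing
  recovery tests demonstrates correctness of the machinery, not predictive
  accuracy on real transcripts. Backgrounds are uniform over {A, C, G, U}
  (a GC-bias knob exists, defaulted off). The default simulation uses
  2000 UTRs of 200 nt with one 7mer-m8 site per (miRNA, gene) at
  probability 0.15, independently — so distinct-seed miRNAs share targets
  only by chance, and the expected between-class cosine is ≈ the site
  probability, while identical-seed miRNAs overlap completely.
- **Expression** (`gen_expression`): gene baselines uniform on [6, 12]
  (log2 scale), i.i.d. Gaussian noise (default sd 0.25, a typical
  replicate-level dispersion for normalized arrays; the statistic is
  scale-free so this choice is cosmetic), exactly round(fraction·n) DE
  genes shifted ±effect·sd in the treated group with recorded directions,
  emulating triplicate transfection contrasts against a negative control.
  Presence calls are all-present unless absences are planted explicitly.
- **Turnover scenarios** (`gen_ortholog_scenario`): species B starts
  base-identical to species A (bijective ortholog map GA↔GB); each
  planted site window is independently overwritten with clean background
  at the turnover probability. Surviving-site overlap then decays as
  √(1 − turnover), since the shared sites are the retained ones while each
  species' set size shrinks only on one side.

All generators are driven by explicit `numpy.random.default_rng` seeds —
identical seeds give byte-identical outputs — and every recovery test
consumes only (data, truth).

## Problem sizes and numerical conventions

The bundled analyses and the reproduction script use: 2000 UTRs × 200 nt
for the overlap-by-class simulation; 5000 genes × 3 vs 3 for DE (5
planted-truth replicates, 20 null replicates); 500 ortholog pairs per
turnover rate. These sizes give stable means (binomial noise on overlap
≈ 0.01–0.02) while keeping a full run in seconds. Quartiles use numpy's
linear interpolation; χ² p-values come from the χ²₁ survival function;
permutation FDR searches candidate thresholds over the observed |d| values
exactly rather than on a grid. Degenerate inputs fail loudly: empty gene
sets (cosine undefined), zero column totals in the 2×2 table, shorter-
than-seed sequences, zero-variance genes with s0 = 0.

## Known limitations

- The seed-match predictor models canonical sites only: no G:U wobble, no
  3′-supplementary pairing, no context or conservation scoring, so its
  absolute target counts are not comparable to miRanda/TargetScan/PicTar
  output; precomputed tables from those tools can be loaded instead.
- The DE module consumes presence calls and normalized signals; raw CEL
  processing, GCRMA and array QC are out of scope.
- The permutation FDR with triplicate groups rests on only 20 label
  assignments; its resolution is correspondingly coarse.
- Ortholog handling is file-based; no live BioMart queries.
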