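# Methods

## Model

`virhost` treats host prediction as hierarchical multi-class classification
conditioned on virus taxonomy. Each of the 30 virus orders in the default
registry gets an independent classifier, on the reasoning that infection
mechanisms and host ranges differ so much between orders that pooling them
would let large orders dominate and unrelated viruses interfere. The host
label space is a fixed two-layer tree: five branches at kingdom/phylum rank
(Chordata, Invertebrate, Viridiplantae, Fungi, Bacteria), and ten
class/order-rank leaves under Chordata. Layer-2 prediction is only attempted
for queries whose layer-1 call is Chordata; a layer-1 error therefore counts
as a layer-2 error in evaluation.

The underlying assumption is that long-term coevolution shapes viral genomes
toward their host's trait usage (codon, dinucleotide, amino-acid biases), and
that related viruses — detectable by sequence alignment — tend to infect
related hosts. Both signals break down for recent host switches and for
multi-host viruses, which is why the model also carries an explicit rejection
mechanism rather than forcing a label.

### Feature encoding

A query is the concatenation X = [S | H].

**Genomic traits S** (layout version `v1-137`, 137 entries):

| block | entries | definition |
|---|---|---|
| nucleotide preference | 4 | P_x = n_x / Σ n_x over the full genome |
| dinucleotide preference | 16 | odds ratio (n_xy / Σ n_xy) / (P_x P_y), overlapping windows |
| synonymous codon usage | 61 | P_xyz = n_xyz / n_A over predicted genes |
| amino-acid usage | 20 | P_A = n_A / Σ n_A |
| coding nucleotide preference | 4 | P_x restricted to coding regions |
| coding dinucleotide preference | 16 | odds ratio within coding regions |
| bridge dinucleotide preference | 16 | odds ratio at codon-boundary positions |

All values are floored at 1e-4 (zero or unobserved events) and
log2-transformed, so positive entries mark overrepresented traits and
unobserved traits sit at log2(1e-4) ≈ −13.29. The trait dimension is a
versioned configuration: the first four blocks are the plainest reading of
the trait families (4 + 16 + 61 + 20 = 101), and the coding/bridge blocks
(4 + 16 + 16) complete the 137-entry layout while staying individually
auditable. The `bias` variant appends 3,904 codon-pair scores
CPS = n_pair / (n_AB · P_c1 · P_c2) — 61 sense first codons × 64 second
codons, pairs led by a stop excluded; it is kept optional because codon-pair
features are sparse on genomes of a few kilobases and tend to dilute rather
than help.

Counting conventions: nucleotide/dinucleotide counts span the whole genome
(within each segment; segments of a multi-segment virus are pooled without
counting windows across segment boundaries); codon-level counts span the
concatenated predicted genes, stop codons excluded from n_A and from leading
pair positions; ambiguous bases are skipped, never imputed.

**Coding regions** come from a pluggable gene caller. The default built-in
backend scans both strands for complete ORFs (ATG to stop, ≥ 300 nt) and
selects them greedily longest-first without overlap. In partial mode (the
default inside the trait encoder) maximal stop-free in-frame runs are added
as candidates, which recovers the coding frame of fragments whose cut removed
every complete start/stop pair; runs that merely extend a complete ORF
upstream are discarded. An external Prodigal-compatible executable can be
configured instead. An input with no callable gene yields an empty
annotation and codon-level traits at the unobserved floor.

**Homology H**: references are grouped by host label (per classifier scope,
so layer 1 and layer 2 have different group counts m); H is the log10 of the
best local-alignment bitscore per group, with raw score 1 (log 0) when no
alignment is found. The external BLASTN backend (default parameters,
tabular output) is used when available; the built-in fallback runs
Biopython's `PairwiseAligner` in local mode with blastn-like scoring (2/−3
match/mismatch, 5/2 gap open/extend) and converts raw scores to bits with
ungapped Karlin–Altschul parameters (λ = 0.625, K = 0.41). Backends differ
slightly in absolute score; the downstream contract is the per-group
ranking. "Alignment score" is taken as bitscore throughout.

During training, a reference's own sequence is excluded from its homology
features (otherwise every training vector contains its own self-hit and the
features are trivially perfect). The leave-one-genus-out harness extends
this to whole-genus exclusion, since a genuinely novel query has no
same-genus relative in the references; without it the learner leans entirely
on within-genus hits and transfers poorly. At prediction time all references
are used.

### Learning and rejection

The default learner is XGBoost with library-default hyperparameters and a
fixed seed (recorded in the bundle); gradient boosting, random forest, SVM,
logistic regression, k-NN and Gaussian naive Bayes are selectable for
architecture comparisons. Class-probability vectors are renormalized to sum
exactly to one (the float32 output of the booster is off by ~1e-8).

Orders whose screened references carry exactly one leaf host label are
`direct_assign`: queries receive that label with score 1.0 and no model is
trained. Orders with any layer-2 annotation are `two_layer`; a layer with
only one distinct label (e.g. a merged Mammalia node) degrades to direct
assignment at that layer. Everything else is `layer1_only`.

Rejection: for each order and layer, out-of-fold validation top scores are
collected during fitting (5 internal stratified folds) and the smallest
cutoff achieving the configured precision target among accepted predictions
is chosen by exhaustive scan over observed scores; the full
precision/prediction-rate curve is retained. Fewer than 20 validation
points, or a target of 0, disables rejection. A rejected query reports no
labels.

### Label screening

Reference curation, in order: (1) records listing more than one layer-1 host
are removed; (2) within an order whose mammalian layer-2 records number
fewer than 50, the six mammalian classes are relabeled to a single
`Mammalia` node; (3) in orders with more than 30 records, host labels with
fewer than 10 members are dropped. Merging before filtering lets a merged
Mammalia group clear the count threshold its separate classes would fail —
the pattern visible in the packaged host-distribution table. Orders of ≤ 30
records keep all labels and are flagged `small`. Screening is idempotent.

The packaged per-order host-distribution table (30 orders, 14,500 viruses)
is expanded to pseudo-records by largest-remainder rounding, so each order's
counts sum exactly to its printed total; applying the order-mode rule yields
12 direct-assignment and 13 two-layer orders, which is what
`scripts/acceptance.py` recomputes.

## Evaluation harnesses

- **Stratified k-fold** (hand-rolled): per label, shuffled positions are
  dealt round-robin, so per-label fold sizes differ by at most one and labels
  with fewer than k members degrade gracefully with a warning (library
  splitters refuse that case). Folds are disjoint and seeded.
- **Metrics**: accuracy counts rejections as errors; precision is over
  emitted predictions only; prediction rate is the emitted fraction;
  macro F1 averages per-label F1; rank-wise accuracy is the unweighted mean
  of per-order/family/genus accuracies; confusion matrices are
  row-normalized over non-rejected queries.
- **Fragments**: one contiguous contig per sequence per completeness ratio
  (90/75/60/45%), length round(ratio × L), start position uniform under the
  seed.
- **Leave-one-genus-out**: per genus, the order's classifier is retrained on
  the order minus that genus (training homology under genus exclusion) and
  the genus is predicted; disjointness of train and test ids is asserted on
  every split. Null model 1 samples labels from the training distribution;
  null model 2 always emits the dominant training label (ties broken by the
  fixed taxonomy order). Challenging-case tags: case 1, genus-dominant
  layer-1 label differs from the order's; case 2, from the family's; case 3,
  genus spans ≥ 2 layer-1 labels.
- **Family-wise analysis**: host homogeneity r is the fraction of a family's
  members carrying its dominant layer-1 label; families split at r ≥ 0.9
  (the boundary counts as high-homogeneity) and errors are attributed per
  partition.

## Synthetic data

The generator emulates exactly the two signals the predictor uses. Each
host label gets a profile: a preferred synonymous codon per amino acid
(usage interpolates from uniform at bias strength 0 to a point mass at 1),
an amino-acid composition (uniform → label-specific Dirichlet draw), and a
mild first-order Markov tilt for UTR composition. Genomes are 5′ UTR + one
ORF (82–94% of the genome) + 3′ UTR, exact length, with a per-genome
Dirichlet jitter (concentration 150) of the amino-acid composition — real
genomes of one host class are not compositional clones, and without
within-class variance a boosted model memorises razor-thin composition
thresholds that fail on fragments. Two details are deliberate:

- The preferred codons for Ser and Leu are fixed to TCA and TTA, whose
  reverse complements are stop codons. Real coding sequences carry stops in
  their reverse-complement frames at regular density; without this anchor a
  fully biased codon stream can leave the reverse strand stop-free,
  producing kilobase-scale spurious reverse ORFs that no real genome shows
  and that make strand assignment arbitrary.
- Genus ancestry: each genus draws one ancestor from its host profile and
  derives members by point substitutions (default 5% per site, no indels —
  dereplicated reference sets retain comparable within-genus diversity, and
  substitution-only mutation keeps the built-in ORF caller valid on
  descendants). Same-genus sequences are therefore alignable, making
  homology features informative; different genera are unrelated sequences,
  so cross-genus homology is absent — a harsher setting than real data,
  where family-level homology persists.

Default conditions: one order, the five layer-1 labels, one family and five
genera per label, 12 genomes per genus (60 per label, 300 total, 25 genera —
about the genus diversity a single order contributes in curated reference
sets), bias strength 1, genome lengths 1,200–2,400 nt. A `planted`
assignment mode places case-1 genera for challenging-case round-trips.

What passing tests on this generator do and do not show: they verify the
pipeline recovers planted signal of the assumed form (trait mimicry +
genus-level homology), remains at chance on signal-free shuffled data, and
degrades gracefully with sequence completeness. They do not certify accuracy
on real viruses, where host signal is weaker, multi-host and host-switch
cases exist, and homology structure is richer.

## Numerical choices and degenerate inputs

- Unobserved-event floor 1e-4 before log2; raw alignment score floor 1
  before log10; negative trait inputs raise.
- Probability vectors renormalized to machine-exact sum 1; per-layer scores
  are non-negative.
- Ties: dominant-label ties break by the fixed taxonomy label order; ORF
  candidates of equal length break by (start, strand); argmax over host
  groups takes the first group in index order.
- Degenerate inputs: sequences shorter than 60 nt, empty record lists, empty
  host groups, and fragments shorter than 100 bp raise; inputs with no
  callable gene fall back to the unobserved floor for codon-level traits;
  orders absent from a bundle yield an explicit "unsupported order" result.
- Determinism: every stochastic step (simulation, folds, fragment starts,
  learner seeds) flows from an explicit seed; repeated runs with identical
  inputs produce byte-identical prediction tables.

## Problem sizes

The shipped tests and harness runs use one simulated order of 300 genomes
(1.2–2.4 kb) for cross-validation, fragment and no-signal checks, and
30–60-genome datasets for unit-level properties; these sizes were chosen so
the full characterization of the method (separability, chance-level
sanity, monotone completeness degradation, leave-one-genus-out recovery) is
demonstrated crisply while any single harness run stays in the tens of
seconds on one CPU.

## Known limitations

- The 137-trait layout is a versioned package default; alternative trait
  enumerations of the same dimension exist, and models are only portable
  across identical layout versions (bundles refuse to load on mismatch).
- The built-in aligner is O(n·m) per pair and meant for testing and small
  references; BLASTN is the practical backend.
- The naive ORF caller does not model frameshifts, overlapping genes on
  opposite strands, or non-ATG starts; the external gene-caller backend is
  preferable for real genomes.
- No multi-label (multi-host) prediction, no ranks below host class/order,
  no neural architectures, and no automated curation of reference databases
  (inputs are assumed pre-validated against the metadata schema).
- Rejection cutoffs are empirical per-order estimates from out-of-fold
  scores; with few validation points they default to accepting everything.
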