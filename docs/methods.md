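# Methods

## K-mer profiles

A sample's profile maps each canonical k-mer (the lexicographically
smaller of a k-mer and its reverse complement, under A < C < G < T) to its
count over all sliding windows of the sample's sequences. Multi-record
FASTA files (chromosomes) are pooled into one profile per sample. Windows
containing a non-ACGT symbol are skipped, not errors — consensus genomes
routinely contain N — and soft-masked lowercase is uppercased first.
Counting is exact: each window is 2-bit packed into a 64-bit integer
(hence k ≤ 31), the packed forward and reverse-complement codes are
compared numerically (numeric order equals lexicographic order under the
2-bit encoding), and counts come from sorting the canonical codes.

Filtering and intersection order matters: profiles are filtered to
`min_count` (default 2, dropping singletons) **first** and intersected
across samples second, so every retained feature has count ≥ 2 in every
sample. Retaining a k-mer that is a singleton in some sample would force
an arbitrary 0/1 count for that sample; excluding such k-mers avoids that
ambiguity.

### Choosing k

`select_k` implements the spectrum-symmetry rule: among candidate k, pick
the one whose filtered count spectrum has the smallest |skewness|. The
mean per-k-mer count is roughly L / (4^k/2) for genome length L, so too
large a k piles all mass at the filter boundary (right-skew) while too
small a k saturates the k-mer space. For L = 10⁷ this rule lands at k ≈ 11
and k = 9 is also serviceable; for the scaled L = 10⁵ used in the test
scenarios it selects k = 7, and k = 9 is the smallest k whose *presence*
still varies between samples (all 8,192 canonical 7-mers occur in every
100 kb genome — relevant for the sketch route, which sees presence only).

## Frequency-PCA pipeline

Counts are z-scored per feature with the population standard deviation;
zero-variance features become all-zero columns (counted, not dropped).
Min-max scaling to [0, 1] is available behind a flag for comparison, but
z-scoring is the default: it is what the standard scaler of the usual ML
stack computes, and PCA axes should not be dominated by high-count
features.

PCA uses a full SVD; component signs are fixed so the largest-|loading|
entry of each component is positive, making score tables reproducible
across platforms. Clustering runs on the first two PCs by default. The
80%-cumulative-variance component choice (`target_variance=0.8`) is
exposed but not the default: on genome-scale k-mer matrices the variance
is spread almost uniformly across components, reaching 80% can take tens
of components, and K-means in that space is unstable, while the two
leading components carry the between-population signal.

K-means uses k-means++ initialisation with 10 restarts and a fixed seed;
output labels are canonicalised by first appearance in sample order so
repeated runs and reordered inputs produce comparable label vectors.

### Elbow selection

The inertia curve (best K-means inertia for k = 1…10) is summarised by
its elbow, the point after which the decrease is roughly linear. The
selection rule is the standard knee formalisation: the interior k whose
inertia lies farthest below the chord joining the curve's endpoints. A
naive alternative — maximising the discrete second difference — fails a
common geometry: when one population is far more diverged than the rest
(the usual case with a deeply drifted ancestral deme), the k=1→2 inertia
drop dwarfs every later drop and the second difference peaks at k=2 even
when three clean clusters are visible. The chord rule handles that case
and agrees with the second-difference rule on curves with a single sharp
bend.

The reported elbow *strength* is the discrete second difference at the
chosen k divided by the k=1 inertia; curves that are already near-linear
give strength ≈ 0 and are flagged weak below 0.05 (an arbitrary but
documented threshold). Degenerate inputs (no variance at all) yield zero
scores, a weak flag, and K from a flat curve rather than an error.

Accuracy against known labels is scored with adjusted mutual information
under the permutation model with max-entropy normalisation; 1 means the
partitions agree up to renaming.

## Simulator

Haploid Wright–Fisher with non-overlapping generations: a deme of
"effective size N" holds 2N haplotypes (the genome count of N diploids),
and sampled genomes are haplotypes. Per generation each offspring picks a
source deme from its deme's migration row, two parents uniformly from that
source, a Poisson(rec·L) number of crossovers at uniform positions
(alternating parents between breakpoints), and Poisson(mu·L) new
mutations at uniform positions, each changing the site to a uniformly
chosen different base. Sites may mutate repeatedly and later mutations
overwrite earlier ones (finite sites). Genomes are stored as sparse
position→base overlays on the random ancestral sequence and materialised
only at sampling; a mutation that restores the ancestral base deletes the
overlay entry.

Calibration: for a single neutral deme the coalescent predicts pairwise
diversity π = 2·(2N)·mu per site; the test suite verifies the simulator
reproduces this within Monte-Carlo tolerance (10 seeds, N = 100,
θ = 0.005), and `scripts/acceptance.py` reports the measured π/θ ratio.

### Scenarios

All scenarios share genome length 10⁷ bp, mutation rate 10⁻⁷ and
recombination rate 10⁻⁸ per site per generation at full scale.

- **three-pop**: one deme of N=500, grown to 1,000 at generation 2,000; a
  second deme of N=180 splits off at 3,500; a third of N=180 splits *from
  the second* at 4,500; sampling of 6 genomes per deme at 7,000. The
  serial (out-of-Africa-like) topology follows the human demographic
  model this scenario imitates, and is what makes the growth variant
  behave as observed (below).
- **three-pop-early**: sampling at 5,500 instead.
- **three-pop-growth**: exponential growth of demes 2 and 3 after the
  third deme is established. The growth rate is not a printed quantity
  anywhere; the package default is 0.5% per generation, capped at 10× the
  size at growth onset.
- **four-pop-admix**: a fourth deme of N=180 founded at 5,500 by equal
  admixture from demes 2 and 3 (each founding parent drawn from either
  source with probability 1/2) and isolated one generation later.
- **hybrid-migration**: demes of N=500, 500 and 200 from a common
  ancestral sequence; the small deme spends its first 10 generations of
  entirely equal origin from the two large demes (migration row 0.5/0.5 —
  migration rows may sum to 1, meaning complete replacement), after which
  symmetric migration at rate m (default 0.02%, sweep values 0.2% and 2%)
  connects it to each large deme; sampling at 5,500.

"Minimal migration" among extant demes in the three-pop family is not
quantified anywhere; the package default is 10⁻⁴ per offspring per
generation, configurable.

### Rescaling

`scenario_library(name, scale)` multiplies genome length, deme sizes and
generation counts by `scale` and divides mu, rec and the growth rate by
`scale`. This preserves the population-scaled diversity θ = 2(2N)mu and
recombination ρ, so scaled scenarios are statistically comparable to the
full-size ones; the test suite checks θ-preservation directly on a
half-scaled neutral deme. Per-generation migration *probabilities* are
left unscaled (the 2% sweep value cannot be multiplied by 1/scale without
exceeding 1). Scaled deme sizes are floored at
max(2, ⌈samples_per_deme/2⌉) so every sampled deme can supply its 6
haplotypes. The default test scale is 0.01 (L = 10⁵), at which a full
scenario simulates in well under a second.

### What the scaled scenarios do and do not show

Faithful down-scaling preserves coalescent-unit geometry but not
everything:

- Mutation counts shrink 100-fold, so Poisson noise relative to signal is
  10× larger; per-seed outcomes are noisier than a chromosome-scale run.
- Sampling 6 haplotypes from a floored deme of 6 means any recent migrant
  lineage is certainly sampled, whereas at N=180 a migrant family is
  rarely among 6 sampled out of 360. Occasional label mismatches under
  the minimal-migration default are expected at desk scale.
- The growth scenario's signature outcome — populations 2 and 3 merging
  into one K-means cluster while population 1 splits in two — is the
  modal behaviour across seeds at scale 0.01 (pops 2 and 3 mostly or
  fully share a cluster in ~8/10 seeds) but the textbook full-merge event
  occurs in a minority of seeds: growth freezes incomplete lineage
  sorting, and a single relict deme-3 lineage often claims the third
  cluster instead of population 1's internal split. A single
  chromosome-scale replicate is subject to the same mechanism.
- Passing tests on these simulations say nothing about sequencing error,
  reference bias, repeat content or uneven coverage in real genomes; the
  generator emits error-free genomes of identical length.

## Sketch route

Sketches are bottom-s: the s smallest values of a stable 64-bit hash
(keyed blake2b digest truncated to 8 bytes, hash seed 42 by default) over
the sample's filtered canonical k-mer set. Jaccard is estimated Mash-style
from the s smallest hashes of the merged sets; the Mash distance is
−(1/k)·ln(2j/(1+j)), with j = 0 mapped to the saturation value 1.0 and
j = 1 to 0. Sketches are only comparable under identical
(k, s, min_count, hash_seed); no cross-parameter rescaling is attempted,
and no significance model (p-values) is provided.

Neighbor joining follows Saitou–Nei with ties broken toward the
lowest-index pair and negative branch lengths clamped to zero; trees are
unrooted (basal trifurcation) and newick-serialisable. Monophyly of a
label group is evaluated on the unrooted tree: the group must equal one
side of some edge-induced bipartition (so the complement of a clade also
counts); singletons and the full leaf set are trivially monophyletic.

## Numerical and interface choices

- Errors name the offending item (position of a bad base, sample and
  k-mer of a missing feature, generation of an extinct deme).
- Empty results that are scientifically meaningful (no valid windows,
  empty intersection, empty sketch) warn rather than raise.
- All randomness flows through explicit integer seeds; identical
  configuration and seed give byte-identical FASTA and TSV output.
- CLI subcommands write a provenance JSON with the resolved configuration
  and seed; a flat key=value config file can supply defaults, with
  explicit flags winning.

## Known limitations

Exact in-memory counting targets desk-scale genomes (≤ tens of Mb per
sample); human-scale profiles need external counters and out-of-core
handling that are out of scope here. The pipeline assigns hard cluster
memberships only — no fractional admixture proportions. The simulator has
no selection, no diploid genotypes or VCF output, and no tree-sequence
recording. The elbow heuristic, however formalised, remains a heuristic:
continuous clines produce weak elbows, and the strength score should be
consulted before trusting K.
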