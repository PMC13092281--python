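# Methods

## Problem and model

`phagedefense` classifies each protein-coding gene of an annotated
prokaryotic genome as anti-phage-defensive or not. The working assumptions
are the empirical signatures of defense genes: sequence features learnable
by a protein embedder, GC content depressed relative to the host genome
(a lateral-transfer signature), and co-location with other defense genes in
islands and multi-gene operons. The classifier is deliberately
context-aware: the unit of encoding is a 5-gene window, so a gene's
neighbors contribute both their protein embeddings and their geometry
(distances, orientations).

### Feature vector

For embedding width *d*, the vector has 5·*d* + 119 slots, laid out by an
explicit registry (`features.feature_layout`) in which every block carries
a category and a window position:

| block | slots | notes |
|---|---|---|
| embedding, positions −2…+2 | 5·*d* | mean-pooled per-residue vectors |
| mononucleotide freqs × 5 genes | 20 | A,C,G,T on the coding strand; N excluded |
| dinucleotide freqs × 5 genes | 80 | overlapping windows; windows containing N dropped |
| GC relative × 5 genes | 5 | gene GC − genome GC |
| gene length × 5 genes | 5 | raw bp (no transform) |
| intergenic distances | 4 | signed bp between consecutive window genes; 0 = abutting, < 0 = overlap |
| neighbor orientations | 4 | strand product with the center gene (±1) |
| genome GC | 1 | genome-wide baseline |

The named feature families total 118; the genome-GC slot closes the
committed 119. Distance slots are attributed to the non-center gene of
their pair for position roll-ups; the genome-GC slot carries no position.
Missing window positions at contig edges contribute zeros in every slot
they own (embedding, per-gene block, adjacent distance, orientation); no
explicit missingness indicator is added, since the all-zero embedding is
outside the mock backend's realizable range. Sequence features are
computed on the coding strand, making them invariant under
reverse-complementing the genome — a property the test suite checks
directly. Features are stored raw, not z-scored: gradient-boosted trees
are insensitive to monotone transforms, and raw values stay interpretable.

### Embedding backends

A backend is any deterministic map from amino-acid sequence to an
(L, *d*) matrix; pooling is the arithmetic mean over residue rows (special
tokens a real model emits are excluded). The default mock backend hashes
the 3-mer centred on each residue (clipped at sequence ends) into a row of
a seeded Gaussian matrix, so the pooled vector is a linear image of the
protein's 3-mer composition — enough for a planted motif to shift the
vectors of its carriers, which is the property the synthetic studies rely
on. Unknown residue characters map to X before hashing. A real
protein-language-model backend (640-dimensional per-residue embeddings) is
loaded lazily behind the same interface and records its checkpoint id in
model metadata; long sequences are truncated to the model's context window
with a logged warning and pooled over the retained prefix.

### Dataset construction

Redundancy reduction is greedy incremental clustering, longest sequence
first, joining a protein to the first cluster whose founder it matches at
≥ 30% identity and ≥ 80% reciprocal coverage under BLOSUM62 local
alignment (identity = identical columns over all alignment columns;
coverage = aligned span over sequence length). A shared-4-mer prefilter
skips alignments that cannot reach the identity floor — the same
acceleration the field's standard clustering tools use — and can be
disabled. The cluster representative is drawn uniformly at random per
cluster from a seeded generator. Processing order is length-then-id, so
membership is independent of input order.

Cross-validation folds are assigned to whole connected components of the
homology graph (consumed as a precomputed pair table; the profile search
producing it is external). Components carrying positives are sorted by
(positive count desc, size desc, smallest id) and placed greedily into the
fold with the fewest positives (ties: smallest total, lowest index).
Components with no positives cannot affect positive balance, so they are
spread by smallest total count instead; placing them by the
fewest-positives rule would funnel every control into a single fold and
leave training sides single-class on small datasets. Because components
are atomic, zero homology edges cross folds — `leakage_check` enforces
this as a hard invariant rather than an empirical observation. Validation
splits for tuning move whole components until the requested fraction of
each class is covered; when a giant component makes stratification
unattainable the closest achievable split is returned with a warning.

### Training and scoring

One LightGBM binary classifier is trained per held-out fold on the other
four folds, with deterministic single-threaded settings and a per-member
seed derived from the run seed. Hyperparameters may be tuned per fold
(random search over a documented space of learning rate, leaves,
estimators, subsampling and regularization, maximizing validation AP); a
Bayesian strategy is available behind the same interface when optuna is
installed, and tuning defaults to off (`budget=0`) with fixed defaults.
Class reweighting is off by default. No probability calibration is
applied.

Held-out evaluation scores each labeled row with the member whose held-out
fold matches the row's tag; scoring a row whose fold has no member is
refused outright, so training rows can never leak into the evaluation
path. For new genomes the ensemble probability is the arithmetic mean of
the five members — the standard bagging combination, chosen as the
committed rule. Probabilities are clamped to [1e−9, 1−1e−9] before the
log-odds transform so saturated trees stay finite. Feature attributions
come from LightGBM's additive tree attribution (`pred_contrib`); the
package's own contribution is the roll-up over the layout registry into
(category × window position) and per-neighbor sums, whose additivity is
tested against row sums.

### Evaluation protocol

Discovery-mode metrics operate on deduplicated rankings: one top-scoring
entry per dedup group, ties broken to the smallest gene id. The
precision-recall curve groups tied scores into one rank block before
stepping; AP is the sum of ΔRecall × Precision over blocks, AUROC the
Mann-Whitney rank statistic with half-credit ties. Both are verified
against brute-force oracles (mean precision at each positive; exhaustive
pair counting) and cross-checked against scikit-learn on tie-free
rankings. Guilt-by-association marks a gene "near defense" when a known
defense gene lies within ±10 genes on its contig — excluding neighbors
from the gene's own system, and optionally its own fold — and ranks
clusters by one-sided Fisher exact enrichment (verified against explicit
hypergeometric tail sums). The neighborhood radius matches the
defense-island definition and is configurable. No multiple-testing
correction is applied: the screen ranks by raw significance.

### Genome analyses

Transcriptional units are maximal same-strand runs with every intergenic
gap ≤ 30 bp (inclusive), called per contig by a single scan and verified
against a run-enumeration oracle; TU score is the max member log-odds. No
manual boundary curation is modeled. Island flags use the ±10-gene rule;
prophage/plasmid flags require ≥ 1 bp overlap with an interval from a
BED-like table (detection itself is external). Context frequencies carry
95% percentile bootstrap intervals over 200 genome-level resamples.
Pangenome occupancy counts distinct genomes per cluster (accessory ≤ 5
genomes, core = all); accumulation curves resample genomes without
replacement 10 times per grid point (grid: 1, then multiples of the step,
always including the full collection). The validation-rate curve estimates,
at each TU's log-odds L, the mean outcome over TUs within ±2 log-odds
(inclusive), with percentile intervals from 1,000 TU resamples and the
Pearson r between log-odds and estimated rate; r is NaN with a warning
when either axis is constant.

## Synthetic cohorts

`synth.generate_cohort` emits multi-contig genomes whose defense genes
carry three planted, independently tunable signals: a −0.10 GC shift
(achieved by calibrated codon sampling — the synonymous-codon bias is
numerically inverted so realized gene GC hits the target; reachable
targets span roughly 0.35–0.72 because first/second codon positions are
fixed by the protein), the motif WWHHWW re-stamped after mutation, and
island/operon placement (systems of 1–3 genes inserted adjacent to
existing defense blocks with probability 0.6, operonic gaps ≤ 20 bp).
Homology is simulated by copy-with-mutation (10% per site) from ancestral
proteins; the homology graph connects family members, the label table
carries system and dedup-group ids, and all emitted files use the
pipeline's real formats. Defaults (10% defense prevalence, genome GC 0.52,
80–220-residue proteins) describe the study conditions; the reference
study used throughout tests and the acceptance script is a 2,000-gene,
20-genome cohort at these defaults.

What the cohorts do **not** emulate: phylogenetic correlation between
genomes, realistic amino-acid composition or codon usage beyond GC,
defensive non-coding RNAs (out of scope — the model takes protein
sequences), circular-genome wrap-around CDSs (skipped on read with a
warning), and any real phage biology. Passing tests therefore demonstrate
that the pipeline recovers the signals it is designed to exploit when they
are present and calibrated — not field performance on real genomes, which
additionally depends on the embedding backend and label quality.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; GenBank/GFF3 (1-based
  inclusive) are converted on read. Neighbors never cross contigs.
* Translation uses the bacterial code (table 11); provided translations
  take precedence, and CDSs without a clean product (pseudogenes, internal
  stops, compound locations) are skipped with a warning.
* Desk-scale runs use the mock backend at *d* = 16–64; the geometry
  contracts (3,200/119/3,319) are exercised at *d* = 640. Tests and the
  acceptance script use a 2,000-gene cohort, 5 folds, tuning off.
* Determinism everywhere: generator, clustering representative choice,
  tuning trials, LightGBM fits (`deterministic`, single thread, fixed
  seed) and bootstraps reproduce bit-identical outputs for a fixed seed.
* Ties are broken deterministically throughout (smallest id; defense-first
  for baseline hits) so evaluation is reproducible.
* No-hit queries in the signed-bit-score baseline score 0, ranking below
  every scored protein; zero-vector embedding queries likewise score 0
  with a warning.

## Known limitations

Greedy clustering with a k-mer prefilter can split borderline pairs near
the 30% identity floor that exhaustive alignment would join, exactly as
the field's standard heuristic clusterers can. The fold balancing is
greedy bin packing, optimal only up to the largest component's positive
count. The guilt-by-association count is per gene instance, not per
cluster occurrence. Hyperparameter tuning per fold is the default; shared
parameters across folds are available via `shared_params`.
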