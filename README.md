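# phagedefense

Machine-learning prediction of anti-phage defense genes in prokaryotic
genomes.

Bacteria defend themselves against bacteriophages with a large and still
mostly uncharted arsenal of defense systems (restriction-modification,
CRISPR-Cas, abortive infection, and many newer families). Classical
discovery relies on homology search or on "guilt by association" with known
defense islands, which by construction cannot find systems that are neither
homologous to known ones nor island-resident. `phagedefense` implements the
complementary, learning-based route: classify every gene from its sequence
and genomic context, evaluate the classifier so that held-out genes share
no homology with the training set, and rank candidates for experimental
follow-up.

The package is aimed at computational microbiologists: the primary
interface is the Python API (see `examples/`), with a thin `phagedefense`
CLI for the standard simulate → featurize → train → predict → call-tus
workflow.

## The model

Each gene *g* (the "center gene") is encoded from a 5-gene window
(positions −2, −1, 0, +1, +2 in genomic order, never crossing contigs):

* **Protein features.** Every window protein is embedded by a pluggable
  per-residue embedding backend of width *d* and mean-pooled over residues;
  the five pooled vectors are concatenated (5·*d* slots, 3,200 at the
  default *d* = 640). A deterministic hashed-3-mer mock backend is provided
  for desk-scale work; a real protein-language-model backend plugs into the
  same interface.
* **Genomic features (119 slots).** Per window gene: mono- and
  dinucleotide frequencies on the coding strand, GC content relative to
  the genome, gene length (22 × 5 = 110); plus the four signed intergenic
  distances between consecutive window genes, the four neighbor strand
  orientations relative to the center, and the genome-wide GC fraction.

The full vector has 5·*d* + 119 slots (3,319 at *d* = 640). Labeled genes
are deduplicated by sequence clustering (30% identity, 80% reciprocal
coverage), split into five cross-validation folds such that **no homology
edge crosses folds**, and one LightGBM gradient-boosting classifier is
trained per held-out fold. The five members form the ensemble: held-out
evaluation scores each gene with the member that never saw its fold; new
genomes are scored with the mean member probability *p*, reported as
log-odds ln(*p*/(1−*p*)) with cutoffs 0 (*p* = 0.5) and 4 (*p* ≈ 0.98).

Evaluation mimics discovery: rankings keep only the top-scoring gene per
dedup group (defense HMM cluster / functional group), and average precision
(AP), AUROC and top-k precision are computed on the deduplicated ranking,
alongside three baselines (signed cosine nearest-neighbor on embeddings,
signed best-hit bit-score, and Fisher-exact guilt-by-association).
Downstream tools call transcriptional units (same-strand runs with ≤ 30 bp
gaps, TU score = max member log-odds), flag defense islands (±10 genes of a
known defense gene) and prophage/plasmid residency, compute pangenome
occupancy and accumulation curves, and estimate the experimental
validation rate as a function of TU log-odds.

## Worked example

`examples/predict_defense_genes.py` trains on 19 synthetic genomes and
scores the held-back 20th:

```
genome G019: 100 genes scored
  predicted defensive at log-odds > 0 (p > 0.5):  9
  predicted defensive at log-odds > 4 (p ~ 0.98): 8
  true defense genes in this genome: 10; recovered at the stringent cutoff: 8/8 predictions correct

top 5 genes by log-odds (higher = more confidently defensive):
  G019_g0040  p=1.0000  log-odds=+14.12  truth=defense
  ...
```

Eight of the genome's ten planted defense genes clear the stringent
log-odds-4 cutoff with zero false positives; the remaining signal sits just
below the cutoff. `examples/heldout_evaluation.py` prints the held-out
deduplicated AP of the classifier (≈ 1.0 on the synthetic cohort) against
the cosine-NN (≈ 0.14) and signed-bit-score (≈ 0.29) baselines, with a
random-ranking AP (prevalence) of ≈ 0.05; `examples/feature_attribution.py`,
`examples/transcriptional_units.py` and `examples/pangenome_context.py`
cover attribution roll-ups, TU calling with the validation-rate curve, and
pangenome/island analyses.

The same workflow from a shell:

```bash
phagedefense simulate --out data --seed 7
phagedefense train --genomes data --labels data/labels.tsv --pairs data/pairs.tsv \
    --dim 32 --seed 7 --out model
phagedefense predict --model model --genome data/G001.gbk --out preds.tsv
phagedefense call-tus --genome data/G001.gbk --predictions preds.tsv --out tus.tsv
```

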