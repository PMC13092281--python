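"""Transcriptional-unit calling and the validation-rate curve.

Calls TUs (maximal same-strand gene runs with intergenic gaps <= 30 bp) on
a predicted genome, scores each TU by the max log-odds of its members, then
simulates experimental outcomes whose success probability rises with the
TU's log-odds and estimates the validation rate in a +/-2 log-odds window
around each TU, with bootstrap confidence intervals. A high Pearson r
between log-odds and estimated rate means the score is an honest guide to
what will validate at the bench.
"""

import numpy as np

from phagedefense import (
    SynthConfig,
    build_dataset_from_genomes,
    call_tus,
    featurize_genomes,
    generate_cohort,
    mock_backend,
    predict_genes,
    train_ensemble,
    validation_rate_curve,
)

cohort = generate_cohort(SynthConfig(n_genomes=12, genes_per_genome=80, seed=3), cluster=False)
backend = mock_backend(dim=16, seed=3)
dataset = build_dataset_from_genomes(
    cohort.genomes, cohort.labels, cohort.homology, backend, k=5, seed=3
)
model = train_ensemble(dataset, k=5, budget=0, seed=3)

all_tus = []
for genome in cohort.genomes:
    gene_ids, X = featurize_genomes([genome], backend)
    records = {r.gene_id: r for r in predict_genes(model, gene_ids, X, mode="ensemble")}
    all_tus.extend(call_tus(genome, records))

sizes = [len(tu.genes) for tu in all_tus]
print(f"called {len(all_tus)} TUs over {sum(sizes)} genes "
      f"(mean {np.mean(sizes):.2f} genes/TU, max {max(sizes)})")

# simulate plaque-assay outcomes: success probability is a logistic
# function of the TU's log-odds, mimicking score-dependent validation
rng = np.random.default_rng(3)
outcomes = [
    (tu.tu_log_odds, bool(rng.random() < 1 / (1 + np.exp(-0.6 * tu.tu_log_odds))))
    for tu in all_tus
]
table, r = validation_rate_curve(outcomes, half_window=2, boot_reps=1000, seed=3)
print(f"\nvalidation rate vs log-odds over {len(outcomes)} TUs, Pearson r = {r:.2f}")
print("log-odds   rate   95% CI")
for _, row in table.iloc[:: max(1, len(table) // 8)].iterrows():
    print(f"  {row.log_odds:+6.2f}  {row.rate:.2f}  [{row.ci_low:.2f}, {row.ci_high:.2f}]")
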