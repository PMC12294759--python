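"""Simulate a cohort, build the pathway masks, train and cross-validate.

Generates a small four-class synthetic transcriptome cohort over a known
gene → pathway → superpathway hierarchy, turns the hierarchy into binary
connectivity masks, reports how many parameters the masked network saves
over a dense one, trains the classifier, and prints stratified 5-fold
cross-validated weighted precision / recall / F1.
"""

from frbinn import (
    SyntheticSpec,
    TrainConfig,
    build_masks,
    crossval_evaluate,
    parameter_count,
    simulate,
)
from frbinn.hierarchy import dense_parameter_count

spec = SyntheticSpec(
    n_genes=40, n_pathways=10, n_superpathways=5, genes_per_pathway=4,
    samples_per_class=50, planted_per_class=6,
    effect_size=2.0, noise_sd=0.5, seed=7,
)
dataset = simulate(spec)
masks = build_masks(dataset.hierarchy)

print(f"cohort: {dataset.expression.shape[0]} samples x {spec.n_genes} genes, "
      f"{spec.n_pathways} pathways, {spec.n_superpathways} superpathways")
print(f"masked parameters: {parameter_count(masks, 4)} "
      f"(dense equivalent: {dense_parameter_count(masks, 4)})")

report = crossval_evaluate(
    dataset.expression, dataset.labels, masks,
    TrainConfig(epochs=200, batch_size=32, learning_rate=1e-3, seed=0),
    k_folds=5,
)
m = report.pooled_metrics
print(f"5-fold weighted precision {m['precision']:.3f}, "
      f"recall {m['recall']:.3f}, F1 {m['f1']:.3f}")
# Values near 1.0 mean the masked network separates the four classes from
# the planted expression shifts; chance level for balanced classes is 0.25.
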