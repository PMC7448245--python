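"""Train and validate one per-target activity classifier.

Builds a synthetic two-class descriptor dataset with a strong class signal,
fits the 250-tree Random Forest on a stratified 80/20 split, and prints the
external-test and 10-fold cross-validated metric panels plus ESP (the mean
specificity across the two validation modes, later used as the consensus
weight).
"""

from multiscreen.qsar import (
    ForestSpec, SplitSpec, cross_validate, model_esp, stratified_split,
    train_forest, validate_on_test,
)
from multiscreen.synthdata import SimSpec, make_qsar_dataset

dataset = make_qsar_dataset(
    SimSpec(n_active=200, n_inactive=200, n_descriptors=20, separation=6.0,
            seed=1)
)
train, test = stratified_split(dataset, SplitSpec(train_fraction=0.8, seed=1))
model = train_forest(train, ForestSpec(n_trees=250, seed=1))

test_report = validate_on_test(model, test)
cross_report = cross_validate(dataset, ForestSpec(n_trees=250, seed=1), k=10)

for rep in (test_report, cross_report):
    panel = {k: round(v, 2) for k, v in rep.as_dict().items() if v is not None}
    print(f"{rep.validation_mode:>5}: {panel}")
esp = model_esp(test_report, cross_report)
print(f"ESP (mean specificity) = {esp:.3f}")
print("A 6-pooled-SD class separation is easily learnable: expect MCC near 1 "
      "and AUC near 1 in both validation modes.")
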