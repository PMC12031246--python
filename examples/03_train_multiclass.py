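"""Train the CNN on a small synthetic five-class dataset and score it.

Uses 80 images per class (a scaled-down run; the acceptance script uses
200), label-aware size-7 Sobel filtering, an 80/20 stratified holdout and
three training epochs, then prints the per-class one-vs-rest metrics table.
"""

import numpy as np

from dolphinet import (
    TrainConfig,
    apply_policy_filter,
    build_model,
    confusion_from_predictions,
    images_to_array,
    make_folds,
    make_multiclass_dataset,
    metrics_from_confusion,
)

images, labels = make_multiclass_dataset(80, seed=3)
x = images_to_array(apply_policy_filter(images, size=7))
split = make_folds(labels.size, n_folds=5, seed=3, stratify_labels=labels)[0]

clf = build_model(seed=3)
clf.fit(x[split.train_indices], labels[split.train_indices],
        TrainConfig(max_epochs=3, val_fraction=0.0, seed=3))

predicted = clf.predict(x[split.test_indices])
cm = confusion_from_predictions(labels[split.test_indices], predicted)
report = metrics_from_confusion(cm)

print("confusion matrix (rows = true class 0..4, columns = predicted):")
print(cm.counts)
print("\nper-class one-vs-rest metrics (percent):")
print(report.to_frame().round(1))
print(f"\nmicro-accuracy: {report.micro_accuracy:.1f}%")
print(
    "\nClasses: 0 noise, 1 whistle, 2 echolocation click, 3 burst pulse,\n"
    "4 feeding buzz. The 'mean' row is the unweighted macro average."
)
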