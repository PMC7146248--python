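"""Featurize sessions and train the step classifier.

Takes one participant's sessions, extracts the windowed feature bank from
the right-forearm armband, selects the top-100 features by split
occurrences, trains the boosted-tree classifier on three sessions and
reports held-out window accuracy on the fourth.  The held-out accuracy is
the raw (unsmoothed) per-window figure.
"""

import numpy as np

from scrubstep import (
    PipelineConfig,
    SimulationConfig,
    apply_selector,
    frame_accuracy,
    generate_cohort,
    predict_stream,
    prepare_session,
    select_top_features,
    train_classifier,
)
from scrubstep.evaluate import FeatureCache, _train_matrix

cohort = generate_cohort(
    SimulationConfig.desk_scale(n_participants=1, sessions_per_condition=1, seed=7))
config = PipelineConfig.desk_scale(seed=0)
cache = FeatureCache()

features = [prepare_session(s, config, cache) for s in cohort]
train_fm = _train_matrix(features[:3], config.train_stride)
print(f"training windows: {train_fm.values.shape[0]}, "
      f"features: {train_fm.values.shape[1]}")

selector = select_top_features(train_fm, k=100,
                               boosting_params=config.selection_params)
print("top 5 features by split occurrences:")
for idx, occ in selector.ranked_features[:5]:
    print(f"  {train_fm.feature_names[idx]:40s} {occ} splits")

model = train_classifier(apply_selector(train_fm, selector),
                         params=config.classifier_params)
stream = predict_stream(model, apply_selector(features[3], selector))
acc = frame_accuracy(stream.argmax_labels, features[3].window_labels)
print(f"\nheld-out session accuracy (raw windows): {acc:.3f}")
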