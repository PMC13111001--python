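"""Train the attention model on phantoms and evaluate a held-out set.

Uses the micro preset so the example finishes in well under a minute; the
tiny preset (width/8, 64-pixel input, full 50-layer depth) is the
CPU-realistic configuration used by the longer-running tests.
"""

import numpy as np

from hmcnet.data import generate_phantoms, preprocess
from hmcnet.experiment import PRESETS
from hmcnet.network import TrainConfig, build_model, predict_labels, train
from hmcnet.stats import confusion

samples = generate_phantoms(n=90, size=32, seed=5)
train_set, test_set = samples[:72], samples[72:]

model = build_model("hmc", PRESETS["micro"](), seed=1)
history = train(
    model, train_set,
    TrainConfig(learning_rate=1e-3, epochs=25, batch_size=16, seed=2, val_fraction=0.1),
)
print("final-epoch training loss: %.3f, accuracy: %.2f"
      % (history["train_loss"][-1], history["train_acc"][-1]))

X = np.stack([preprocess(s.image, 32) for s in test_set])
y = np.array([s.label_index for s in test_set])
pred = predict_labels(model, X)
print("held-out accuracy: %.2f on %d phantoms" % ((pred == y).mean(), len(y)))
print("confusion (rows true normal/benign/malignant, cols predicted):")
print(confusion(y, pred, 3).counts)
# Expect normals separated first (texture cue); benign-vs-malignant needs
# longer training since it rests on boundary shape.
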