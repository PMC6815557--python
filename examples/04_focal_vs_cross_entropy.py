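"""Why focal loss: minority recall on a 200:1 imbalanced task.

Trains the same small LSTM on 600 normal vs 3 bundle-branch-block beats —
once with focal loss (γ=2), once with plain cross-entropy — and compares
recall of the minority class on a balanced held-out set, over five seeds.
With 3 training examples neither model is reliable, but focal loss rescues
minority recall on some seeds while cross-entropy essentially never does.
Takes a few minutes on one CPU.
"""

import dataclasses

import numpy as np

from ecgbeat import (
    BeatDataset,
    NoiseSpec,
    TrainConfig,
    denoise_db6,
    gen_dataset,
    predict,
    train,
    zscore,
)


def preprocess(ds):
    return BeatDataset(
        [zscore(dataclasses.replace(b, samples=denoise_db6(b.samples, 360.0)))
         for b in ds]
    )


for loss in ("focal", "cross_entropy"):
    recalls = []
    for s in range(5):
        tr = preprocess(gen_dataset({0: 600, 1: 3}, noise=NoiseSpec.mild(),
                                    seed=1000 + s))
        te = preprocess(gen_dataset({0: 100, 1: 100}, noise=NoiseSpec.mild(),
                                    seed=2000 + s))
        cfg = TrainConfig(epochs=25, batch_size=128, gamma=2.0, loss=loss,
                          hidden_size=8, fc_width=16, n_classes=2, seed=s)
        params, _ = train(tr, None, cfg)
        labels, _ = predict(params, te)
        y = te.labels()
        recalls.append(float(np.mean(labels[y == 1] == 1)))
    print(f"{loss:>14}: minority recall per seed {recalls}, "
          f"mean {np.mean(recalls):.3f}")
print("-> focal loss downweights the flood of easy normal beats; on the")
print("   seeds where the three minority examples get traction at all, it")
print("   is the focal model that finds them.")
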