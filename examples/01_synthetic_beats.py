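"""Generate an imbalanced synthetic beat dataset and check its structure.

Builds 1,000 beats with the MIT-BIH eight-class proportions (~80% normal),
then verifies by template correlation that each beat still identifies its
generating class despite jitter.
"""

import numpy as np

from ecgbeat import (
    CLASS_NAMES,
    NoiseSpec,
    gen_dataset,
    nearest_template_class,
    scale_counts,
)

counts = scale_counts(1000)
dataset = gen_dataset(counts, noise=NoiseSpec(), seed=1)

print("class distribution of 1,000 generated beats:")
for c, n in dataset.class_distribution.items():
    print(f"  {CLASS_NAMES[c]:>6}: {n:4d}")

hits = sum(nearest_template_class(b.samples) == b.label for b in dataset)
print(f"\nnearest-template classification: {hits}/{dataset.n} correct")
print("-> the classes are separable by construction; the heavy skew toward")
print("   the normal class mirrors the real database's imbalance.")
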