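"""Generate a toy crop-disease VQA corpus with a skewed answer prior.

Builds 200 training scenes whose spot-color questions are answered "brown"
90% of the time, plus an anti-biased test split drawn from the
complementary prior, and prints the realized answer frequencies — the
quantitative signature of unimodal bias a debiasing method must remove.
"""

import numpy as np

from cropvqa.experiments import empirical_marked_frequency
from cropvqa.synthetic import BiasSpec, generate_biased_corpus

train, val, test, images, specs = generate_biased_corpus(
    200, BiasSpec(bias_strength=0.9), seed=0)

print(f"train/val/test questions: {len(train)}/{len(val)}/{len(test)}")
print(f"scenes rendered: {len(images)} (64x64 RGB)")
print(f"'brown' frequency on spot-color questions, train: "
      f"{empirical_marked_frequency(train):.2f}  (target 0.90)")
print(f"'brown' frequency on spot-color questions, test:  "
      f"{empirical_marked_frequency(test):.2f}  (complementary prior)")

# A model that answers spot-color questions with the training mode ("brown")
# scores ~90% on train but near zero on the anti-biased test.
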