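"""Apply the image/text augmentation protocol to a small corpus.

Each image spawns derived copies: Gaussian noise at two variances,
multiscale Retinex (color-restored and chromaticity-preserving), and a
random rotation in [60, 120] degrees; questions gain lowercased and
punctuation-stripped variants.  Labels are carried unchanged and every
derived record logs its provenance.
"""

from cropvqa.augmentation import AugmentationPlan, expand_dataset
from cropvqa.synthetic import generate_biased_corpus

train, _, _, images, _ = generate_biased_corpus(30, seed=2)
train_images = {t.image_id: images[t.image_id] for t in train}

plan = AugmentationPlan(seed=2)
expanded, expanded_images, provenance = expand_dataset(
    train, train_images, plan)

print(f"image operations enabled: {plan.enabled_image_ops()}")
print(f"questions: {len(train)} -> {len(expanded)}")
print(f"images:    {len(train_images)} -> {len(expanded_images)}")
print("sample provenance records:")
for record in provenance[:3]:
    print(" ", record)
# The factor between input and output image counts is 1 + the number of
# enabled image operations; text variants add further question records.
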