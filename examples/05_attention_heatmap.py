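"""Visualize where the model looks for different questions.

Trains a small model briefly, then renders the final guided-attention
weights (question stream over image grid cells), averaged over heads and
words, as a heatmap blended over the scene.
"""

from pathlib import Path

from cropvqa.encoders import GridExtractor
from cropvqa.model import ModelConfig, TrainConfig, build_model, train_model
from cropvqa.synthetic import generate_biased_corpus
from cropvqa.viz import visualize_attention

train, _, test, images, _ = generate_biased_corpus(40, seed=3)
config = ModelConfig(seed=3)
model = build_model(train, config)
extractor = GridExtractor(grid=config.grid, d_v=config.d_v,
                          resize_to=config.resize_to, seed=config.seed)
train_model(model, train, images,
            TrainConfig(epochs=12, batch_size=64, seed=3), extractor=extractor)

image_id = test[0].image_id
out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)
for question in ("what color is the spot?", "what shape is the fruit?"):
    grid_map = visualize_attention(
        model, images[image_id], question,
        out_dir / f"heatmap_{question.split()[1]}.png", extractor)
    peak = grid_map.max()
    print(f"{question:32s} peak grid weight {peak:.3f} "
          f"(uniform would be {1.0 / grid_map.size:.3f})")
print(f"heatmaps written to {out_dir}/")
# The grid map sums to 1; a peak well above uniform means the question
# concentrated the model's attention on a few image regions.
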