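"""The bias-recovery experiment at reduced scale (one seed).

Trains matched models with and without the bias-balancing branch on a
corpus whose spot-color answers are 90% "brown", then scores both on an
anti-biased test split and prints the question-only branch diagnostics:
the branch alone scores about 0.9 on biased training questions but near
chance on the anti-biased test — proof the corpus carries a language
shortcut for the branch to absorb.
"""

import dataclasses

from cropvqa.experiments import run_bias_recovery

result = run_bias_recovery(seed=11, n_train_triples=600)
for key, value in dataclasses.asdict(result).items():
    print(f"{key:38s} {value}")

# biba_* vs nobiba_*: anti-biased test accuracy with/without the branch;
# *_template_*: accuracy restricted to the skewed spot-color template;
# branch_train/test: the question-only classifier's accuracy, whose drop
# from ~0.9 to near chance quantifies the unimodal bias itself.
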