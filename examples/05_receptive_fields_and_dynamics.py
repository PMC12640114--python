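"""Compare first-layer receptive fields under decreasing vs constant LR.

Two developmental (D2F, grayscale-to-color) runs share one weight
initialization and differ only in the learning-rate schedule.  Per-filter
color-tuning scores are paired by filter index; a point below the diagonal
means that filter is less color-tuned under the decreasing LR.  At desk
scale the first layer barely moves once the easy task saturates, so the
scatter hovers near the diagonal — the clear retention signature here is
behavioral (grayscale-test accuracy) and dynamical: adjacent-epoch weight
correlations show the network freezing once the LR drops.

Takes about a minute on one CPU.
"""

import numpy as np

from plastinet import ArchConfig, TrainConfig, generate_dataset, train
from plastinet.presets import desk_spec
from plastinet.representations import (
    below_diagonal_count, color_tuning_score, dynamics_profile, extract_first_layer,
)
from plastinet.schedules import make_lr_schedule, make_regimen

train_set, test_set = generate_dataset(desk_spec(seed=1))
runs = {}
for schedule in ("dec1", "const1"):
    runs[schedule] = train(
        ArchConfig(), train_set, test_set,
        make_regimen("D2F", 10, degraded_kind="grayscale"),
        make_lr_schedule(schedule, 10),
        TrainConfig(epochs=10, seed=1),
    )

pairs = [
    (color_tuning_score(fd), color_tuning_score(fc))
    for fd, fc in zip(
        extract_first_layer(runs["dec1"].final_checkpoint()),
        extract_first_layer(runs["const1"].final_checkpoint()),
    )
]
below, total = below_diagonal_count(pairs)
print(f"filters strictly less color-tuned under decreasing LR: {below} of {total}")
print(f"mean color score  dec1: {np.mean([p[0] for p in pairs]):.3f}   "
      f"const1: {np.mean([p[1] for p in pairs]):.3f}")

records, stab = dynamics_profile(runs["dec1"])
print("\nfirst epoch with adjacent-epoch weight correlation >= 0.99:")
for layer, epoch in stab.items():
    print(f"  {layer}: {epoch}")
pre = [r.correlation for r in records if r.epoch_pair[1] <= 5]
post = [r.correlation for r in records if r.epoch_pair[0] >= 5]
print(f"mean adjacent-epoch correlation before LR drop: {np.mean(pre):.6f}, "
      f"after: {np.mean(post):.6f}")
print("(early conv layers stabilize no later than the final fc layer, and"
      "\n correlations sit closer to 1 once the LR drops at the midpoint)")
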