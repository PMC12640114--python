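"""Inspect training regimens and learning-rate schedules.

Regimens order degraded vs full-fidelity input phases over epochs; LR
schedules model plasticity: constant presets keep it high, decreasing
presets model a time-limited critical period.
"""

from plastinet.schedules import (
    degradation_at_epoch, initial_plateau_state, lr_at_epoch,
    make_lr_schedule, make_regimen, matched_pairs, plateau_update,
)

reg = make_regimen("D2F", 100, degraded_kind="blur")
print("D2F phases:", [(spec.label(), n) for spec, n in reg.phases])
print("epoch 50 ->", degradation_at_epoch(reg, 50).label(),
      "| epoch 51 ->", degradation_at_epoch(reg, 51).label())

stair = make_regimen("gradual_blur", 100)
print("gradual blur staircase:", [(spec.label(), n) for spec, n in stair.phases])

for name in ("const1", "dec1", "gradual"):
    sch = make_lr_schedule(name, 100)
    trace = {e: lr_at_epoch(sch, e) for e in (1, 41, 50, 51, 61, 100)}
    print(f"{name:8s}:", trace)

print("matched pairs (by initial LR):",
      [(d, c) for d, c, _ in matched_pairs("initial")])

# reduce-on-plateau: six flat epochs (patience 5, min_delta 0) halve the LR
sch = make_lr_schedule("plateau", 100)
state = initial_plateau_state(sch)
for epoch in range(8):
    state = plateau_update(state, sch.plateau_params, 0.5)
    print(f"plateau epoch {epoch + 1}: monitored=0.5 lr={state.current_lr}")
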