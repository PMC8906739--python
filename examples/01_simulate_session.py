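"""Generate a synthetic joystick session and inspect its behavior.

Builds a full session (joystick trace, detected reaches, Poisson spikes,
optotagging block) from one seed and prints the reach statistics: block-
wise mean amplitudes should track the block thresholds (low-high-low),
and the overall distribution should be broad and right-skewed.
"""

import numpy as np

from reachpop import SessionConfig, generate_session

config = SessionConfig(seed=7)
session = generate_session(config)

amps = np.array([ev.amplitude for ev in session.events])
blocks = np.array([ev.block_id for ev in session.events])

print(f"{len(session.events)} reaches, {session.truth.units.shape[0]} units, "
      f"{len(session.spikes)} task spikes")
print(f"amplitude mean +- SD: {amps.mean():.1f} +- {amps.std():.1f} mm "
      f"(max {amps.max():.1f} mm)")
for b, thr in enumerate(config.block_thresholds):
    m = amps[blocks == b].mean()
    print(f"  block {b} (threshold {thr} mm): mean amplitude {m:.2f} mm "
          f"over {np.sum(blocks == b)} reaches")
print(f"fraction rewarded: {np.mean([ev.rewarded for ev in session.events]):.2f}")
# The middle block's higher threshold should pull its mean amplitude up:
# the simulated subject adapts reach amplitude to the current threshold.
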