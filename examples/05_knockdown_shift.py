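"""Test whether fusion knockdown moves tumor samples along the trajectory.

Simulates paired control/knockdown tumor samples (knockdown reduces the
latent fusion dosage by 80%), embeds them jointly with the compendium, and
applies a one-tailed Welch t-test on axis-1 position. Lower dosage means
higher pseudotime, so the knockdown arm should sit higher on axis 1
(toward the mesodermal pole).
"""

import ewstraj as e
import ewstraj.workflows as w

chain = w.bulk_chain(e.SimConfig(seed=0))
rep = w.knockdown_shift(chain, n_pairs=6, dosage_drop=0.8)

print(f"control arm mean axis-1:   {rep['mean_control']:8.2f}")
print(f"knockdown arm mean axis-1: {rep['mean_treatment']:8.2f}")
print(f"one-tailed Welch t = {rep['t']:.2f}, p = {rep['p']:.2e} ({rep['direction']})")
print("\np <= 0.01 with the knockdown arm higher reproduces the expected"
      " direction: depleting the fusion pushes tumor cells toward the"
      " mesodermal end of the developmental axis.")
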