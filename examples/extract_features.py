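"""Extract the three gait feature banks from one participant's segment.

The spatiotemporal bank holds 10 interpretable stride-level quantities; the
time bank holds 4 moment statistics for each of the 75 joint-axis channels
(300 features); the frequency bank holds the DC component plus 5 amplitude
and 5 phase statistics per channel (825 features).
"""

import numpy as np

from gaitdep import CohortConfig, GaitParams, extract_all_features, synthesize_recording
from gaitdep.preprocess import preprocess_recording

config = CohortConfig(duration=60.0, seed=0)
params = GaitParams(arm_swing_left=0.27, arm_swing_right=0.23,
                    walking_speed=0.99, noise_sd=0.0, jitter_amplitude=0.0)
rec = synthesize_recording(params, config, np.random.default_rng(3))
segment = preprocess_recording(rec)

banks = extract_all_features(segment)
for block, fv in banks.items():
    print(f"{block:15s}: {len(fv)} features")

st = banks["spatiotemporal"]
print("\nstride-level features (averaged over the two cycles):")
for name in st.names:
    print(f"  {name:20s} {st[name]: .3f}")

# On this noiseless walker the features recover the generator's parameters:
# left-arm swing ~0.27 m, right ~0.23 m, walking speed ~0.99 m/s.
freq = banks["frequency"].to_series()
print(f"\nleft-wrist Z: DC {freq['j10_z_dc']: .3f} m, "
      f"amplitude-distribution skewness {freq['j10_z_amp_skew']:.2f}")
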