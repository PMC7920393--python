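"""From SEEG traces to a model-ready seizure observation.

Synthetic bipolar channels carry a ten-fold band-power step at their
region's onset.  The pipeline detects per-channel onsets from baseline-
normalized band log-power, maps channels to regions (here one channel per
region), aggregates, aligns the first onset to t1 = 30 s and applies the
t_lim = 90 s cut.
"""

import numpy as np

import seizprop as sp
from seizprop.mapping import RegionObservation

true_onsets = {"amyg": 200.0, "hippo": 210.0, "insula": 245.0, "occ": np.inf}
records = sp.generate_seeg_signal(true_onsets, fs=256.0, duration=420.0,
                                  gain=10.0, seizure_end=330.0, seed=5)

region_obs = []
print("channel  detected  true")
for rec in records:
    seizing, onset = sp.detect_channel_onset(rec, delta=5.0)
    shown = f"{onset:7.1f}" if seizing else "   none"
    print(f"{rec.channel_id:>7}  {shown}  {true_onsets[rec.channel_id]:6.1f}")
    region_obs.append(
        sp.aggregate_region_observation(rec.channel_id,
                                        [onset if seizing else np.inf])
    )

seizure = sp.finalize_seizure(region_obs, list(true_onsets) + ["unexplored"])
print("\nregion      status       aligned_onset_s")
for r, s, t in zip(seizure.region_ids, seizure.status, seizure.onset_s):
    print(f"{r:>10}  {s:<11}  {t:7.1f}")
print("\nThe earliest onset is aligned to 30 s; channels without a sustained "
      "five-fold power rise are non-seizing; unexplored regions stay hidden.")
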