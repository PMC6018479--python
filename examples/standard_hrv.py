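"""The conventional HRV battery on one 2.5-min epoch of an RR series.

These are the comparator indices: time domain (SDNN, RMSSD, triangular
index), Lomb-Scargle frequency domain (LF 0.1-1 Hz, HF 1-3.5 Hz, their
ratio), Poincaré SDs, DFA exponents, and sample entropy.
"""

import numpy as np

from hrvperiod import generate_rr_cmv
from hrvperiod.ecg import segment_epochs
from hrvperiod.pipeline import analyze_epoch

rr = generate_rr_cmv(n_beats=2000, mod_depth_ms=8.0, jitter_ms=2.0,
                     rng=np.random.default_rng(5))
epoch = segment_epochs(rr, epoch_length_s=150.0)[0]
record = analyze_epoch(epoch, epoch_id=0)

for name in ("SDNN", "RMSSD", "TriIdx", "LF", "HF", "LHR",
             "SD1", "SD2", "SDRatio", "alpha1", "alpha2", "SampEn"):
    if name in record.values:
        print(f"{name:>8} = {record.values[name]:8.3f}")
    else:
        print(f"{name:>8}   missing ({record.missing[name]})")

print()
print("SDNN/RMSSD/SD1/SD2 in ms; LF and HF are fractions of 0.1-3.5 Hz power.")
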