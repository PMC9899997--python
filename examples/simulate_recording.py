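"""Simulate a dual-rate ABP/NIRS recording with known ground truth.

Builds a 10-minute scenario with two channels — one pressure-passive
(coupling +0.9, impaired reactivity) and one decoupled (0.0, intact) —
and writes the recording in the merged CSV dialect.
"""

from pathlib import Path

import numpy as np

from cvrmap import SimulationConfig, simulate_recording, write_recording

cfg = SimulationConfig(
    duration=600.0,
    reactivity_coupling=(0.9, 0.0),
    scalp_fraction=0.3,
    sensor_noise_sd=0.05,
    seed=42,
)
record = simulate_recording(cfg)

out = Path("scratch")
out.mkdir(exist_ok=True)
files = write_recording(record.abp, list(record.channels.values()), out / "recording.csv")

abp = record.abp
print(f"niABP: {abp.n} samples at {abp.rate:.0f} Hz, "
      f"mean {np.mean(abp.values):.1f} mmHg, sd {np.std(abp.values):.1f} mmHg")
for cid, ch in record.channels.items():
    print(f"{cid}: HbO_norm mean {np.mean(ch.HbO_norm.values):.2f} a.u., "
          f"short-channel mean {np.mean(ch.HbO_short.values):.2f} a.u. "
          f"at {ch.HbO_norm.rate:.0f} Hz")
print(f"wrote {files[0]}")
# The NIRS content leads the ABP stream by the simulated 3.24-s device
# lag; the processing stage will correct it with the fixed 3.22-s shift.
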