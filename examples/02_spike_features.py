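"""Extract spike and passive-membrane parameters from current-clamp sweeps.

Generates a bursting external-tufted-type cell (irregular inter-spike
intervals, fast rise / slow decay spikes) and measures the physiological
parameters used for clustering.
"""

import numpy as np

from glomcluster import CohortSpec, detect_spikes
from glomcluster.ephys_features import (
    average_spike_shape,
    characterize_spike,
    cv_isi,
    input_resistance,
    membrane_time_constant,
)
from glomcluster.synthetic_data import generate_sweeps

rng = np.random.default_rng(1)
sweeps, truth = generate_sweeps("B", CohortSpec(), rng, cell_id="demo_ETC")

events, trains = [], []
for s in sweeps.sweeps:
    peaks = detect_spikes(s, sweeps.sampling_rate)
    if len(peaks):
        trains.append(peaks / sweeps.sampling_rate)
    events += [e for p in peaks
               if (e := characterize_spike(s, p, sweeps.sampling_rate))]

print(f"{len(events)} spikes detected across {len(sweeps.sweeps)} sweeps")
print(f"  input resistance  {input_resistance(sweeps):6.2f} GOhm   (drawn {truth['input_resistance']:.2f})")
print(f"  time constant     {membrane_time_constant(sweeps):6.1f} ms     (drawn {truth['time_constant']:.1f})")
print(f"  AP half-width     {np.mean([e.half_width for e in events]):6.2f} ms     (drawn {truth['half_width']:.2f})")
print(f"  AP amplitude      {np.mean([e.amplitude for e in events]):6.1f} mV     (drawn {truth['amplitude']:.1f})")
print(f"  AP speed ratio    {np.mean([e.speed_ratio for e in events]):6.2f}        (drawn {truth['speed_ratio']:.2f})")
print(f"  CV of ISI         {cv_isi(trains):6.2f}        (drawn {truth['cv_isi']:.2f})")
shape = average_spike_shape(sweeps)
print(f"  average spike shape: {len(shape.waveform)} samples, peak at index {shape.alignment_index}")

# The drawn values are the generator's ground truth; the extracted values
# come back through the same analysis applied to real recordings.
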