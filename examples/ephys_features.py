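"""Patch-clamp feature extraction from simulated current-clamp sweeps.

Simulates medium-spiny-neuron recordings (leaky integrate-and-fire with
stamped action potentials, 20 kHz) for a small cohort, extracts passive
membrane and spike properties, and normalizes evoked-EPSC series by each
neuron's own baseline to quantify long-term depression (LTD).
"""

import pandas as pd

from csdskit import (
    analyze_ltd,
    generate_ephys_recordings,
    measure_passive,
    measure_spike_properties,
)
from csdskit.synthetic import GroupDesign, default_effects

design = GroupDesign(n_per_group=2)
sweeps, epsc, truth = generate_ephys_recordings(
    design, default_effects(), seed=17, neurons_per_cell=2,
)

rows = []
for ss, es in zip(sweeps, epsc):
    passive = measure_passive(ss)
    spike = measure_spike_properties(ss)
    ltd = analyze_ltd(es)
    rows.append({
        "neuron": ss.neuron_id,
        "diet": truth.neuron_params[ss.neuron_id]["diet"],
        "RMP (mV)": round(passive.rmp_mV, 1),
        "Rin (MOhm)": round(passive.input_resistance_MOhm, 0),
        "C (pF)": round(passive.capacitance_pF, 0),
        "rheobase (pA)": passive.rheobase_pA,
        "AP amp (mV)": round(spike.ap_amplitude_mV, 1),
        "LTD late": round(ltd.late_mean, 2),
    })

print(pd.DataFrame(rows).to_string(index=False))
print()
print("Capacitance is tau/Rin; 'LTD late' is the mean EPSC amplitude")
print("30-40 min after the 10 Hz/10 min protocol, normalized to each")
print("neuron's baseline (1.0 = no depression, ~0.7 = typical LTD).")
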