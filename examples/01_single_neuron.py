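"""Single-neuron behaviour: resting potential and step-current response.

Integrates an isolated projection neuron (PN) and local neuron (LN) with the
reference integrator and prints their resting potentials and firing rates
under a depolarizing step.  The resting potentials (~-70 mV) and the LN's
lower rheobase are the baseline sanity checks for every network experiment.
"""

import numpy as np

from alnet import neurons

for role in ("PN", "LN"):
    _, v_rest = neurons.integrate_single_neuron(role, 0.0, 800.0, 0.04)
    amp = 1.5e-3 if role == "PN" else 3e-4
    _, v_step = neurons.integrate_single_neuron(role, amp, 500.0, 0.04)
    spikes = neurons.detect_spikes(v_step, 0.04)
    rate = len(spikes) / 0.5
    print(f"{role}: rest = {v_rest[-1]:.1f} mV (no spikes), "
          f"step {amp * 1e3:.1f} nA -> {rate:.0f} Hz")

# The PN rests near -70 mV and stays silent without input; a ~1 nA step
# drives repetitive spiking at a few tens of Hz, matching the operating
# range used for odor responses.
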