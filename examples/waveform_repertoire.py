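"""Spike-waveform taxonomy: units, phase classes and the repertoire table.

Generates a labelled bank of 2000 extracellular snippets at the repertoire
proportions measured on mature cultures (41/15/26/18%), classifies each by
its positive/negative peak amplitudes, and prints the recovered repertoire.
Also demonstrates unit isolation (PCA + Gaussian mixture, 1-3 units).
"""

import numpy as np

import hdmea
from hdmea import synthetic as syn
from hdmea.synthetic import waveform_template

snippets, labels = syn.gen_waveform_bank((0.41, 0.15, 0.26, 0.18), 2000, seed=5)
table = hdmea.repertoire_table(snippets)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# two units of different shape/amplitude on one electrode
rng = np.random.default_rng(6)
a = waveform_template(0, 7800.0, amplitude=90.0)
b = waveform_template(3, 7800.0, amplitude=30.0)
mixed = np.vstack([a + rng.normal(0, 2, (200, a.size)), b + rng.normal(0, 2, (200, b.size))])
units = hdmea.sort_units(mixed)
print(f"units isolated    : {units.n_units} (two templates injected)")
# The proportions recover the programmed mix within a few percentage
# points; the three negative classes sum to ~82%, the remainder being
# positive biphasic spikes.
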