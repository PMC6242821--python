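"""Fit the model to data simulated from a known network.

Generates spike counts from a planted ground-truth network, fits a fresh
sigmoid/NegBin model by maximum likelihood (iRprop+), and measures how well
the inferred synaptic-kernel areas match the planted ones.  A short fit on
a small network for illustration; longer records tighten the recovery.
"""

import numpy as np
from scipy.stats import pearsonr

from spikeglm import FitConfig, SynthConfig, generate_dataset, irprop_fit, make_ground_truth

rng = np.random.default_rng(11)
truth, _ = make_ground_truth(SynthConfig(n_neurons=8, probe_bins=15_000), rng)
data, _ = generate_dataset(truth, 40_000, rng)  # 400 s

result = irprop_fit(data, FitConfig(variant="sig_negbin", max_epochs=120))
print(f"fit: {result.n_epochs} epochs, best log-likelihood {result.best_ll:.1f}, "
      f"converged={result.converged}")

off = ~np.eye(truth.n_neurons, dtype=bool)
c, _ = pearsonr(truth.kernel_areas()[off], result.params.kernel_areas()[off])
print(f"kernel-area correlation (inferred vs planted): r = {c:.3f}")
print(f"inferred SFA timescales (s): {np.round(result.params.tau_sfa, 3)}")
print(f"inferred SFA gains:          {np.round(result.params.g_sfa, 2)}")
# The gains concentrate on timescales near the planted pair (0.1 s, 2 s);
# r above ~0.8 means the synaptic structure is essentially recovered.
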