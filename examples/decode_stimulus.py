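"""Decode odorant identity from ensemble dF/F with leave-one-out LDA.

Generates a proficient session, computes dF/F, extracts odorant-window
period means and reports: decoding accuracy, the shuffled-label control,
participation-ratio dimensionality, and accuracy with a single ROI.
"""

import numpy as np

from mlipop import decode, dff, synth
from mlipop.config import (EnsembleConfig, LearningCurve, PeriodWindows,
                           SessionConfig)

session = synth.generate_session(
    SessionConfig(n_trials=100, seed=2),
    EnsembleConfig(n_rois=50, n_latents=4),
    LearningCurve(start_pc=85, asymptote_pc=95, inflection_trial=0, slope=1.0),
)
d = dff.compute_dff(session.F, [t.t_start for t in session.trials],
                    session.imaging_rate)
tensor = dff.align_trials(d, session.trials, "odor_on", (-1.0, 5.0),
                          session.imaging_rate)
X = dff.period_means(tensor, PeriodWindows().odorant)
labels = tensor.labels(session)

acc = decode.loo_lda_accuracy(X, labels)
rng = np.random.default_rng(0)
shuffled = np.mean([decode.loo_lda_accuracy(X, rng.permutation(labels))
                    for _ in range(10)])
dim = decode.dimensionality(d)
curve = decode.subsample_decoding(X, labels, sizes=(1, 5, 20, 50), n_draws=50)

print(f"odorant-window decoding accuracy : {acc * 100:5.1f}%")
print(f"shuffled-label control           : {shuffled * 100:5.1f}%")
print(f"participation-ratio dimensionality: {dim:4.2f}")
for size, mean in zip(curve.subset_sizes, curve.accuracy_mean):
    print(f"  {size:3d} ROIs -> {mean * 100:5.1f}%")
# A valence-coupled ensemble decodes far above the ~50% shuffled control,
# and because the signal is low-dimensional (redundant across ROIs) even
# small ROI subsets stay close to the full-ensemble accuracy.
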