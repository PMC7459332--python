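"""Generate a synthetic go-no go session and score its behavior.

Builds a 100-trial session with a learning curve crossing from naive to
proficient, scores every trial from the lick train, and prints the
sliding-window percent correct at a few milestones.
"""

import numpy as np

from mlipop import behavior, synth
from mlipop.config import EnsembleConfig, LearningCurve, SessionConfig

session = synth.generate_session(
    SessionConfig(n_trials=100, seed=1),
    EnsembleConfig(),
    LearningCurve(start_pc=50, asymptote_pc=95, inflection_trial=40),
)

outcomes = session.outcomes()
pc = behavior.percent_correct(outcomes, window=20)
epochs = behavior.classify_epoch(pc)

counts = {o: outcomes.count(o) for o in ("Hit", "Miss", "CR", "FA")}
print(f"outcomes: {counts}")
for trial in (19, 49, 99):
    print(f"trial {trial + 1:3d}: percent correct = {pc[trial]:5.1f}  "
          f"epoch = {epochs[trial]}")
print(f"trials at proficient level (>=80%): "
      f"{int(np.sum(epochs == behavior.PROFICIENT))}")
# The percent-correct trace should start near chance (many FAs early) and
# end above the 80% proficiency threshold as S- licking is suppressed.
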