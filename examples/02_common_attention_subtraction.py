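"""Expose group-specific attention by subtracting the common gaze pattern.

Generates a small synthetic cohort in which every stimulus shares the same
eyes/nose/mouth attention plus one planted stimulus-specific feature, then
shows that the common-attention-subtracted residual map localizes that
planted feature on each stimulus.
"""

import numpy as np

from visattn import CohortConfig, Group, gen_cohort, preprocess_group

cfg = CohortConfig(
    n_clinicians=8, n_non_clinicians=8, n_stimuli=6, n_affected=4,
    image_px=160, seed=0,
)
stimuli, sequences, _ = gen_cohort(cfg)

clinician_seqs = [s for s in sequences if s.group is Group.CLINICIAN]
residuals = preprocess_group(clinician_seqs, Group.CLINICIAN, cfg.image_px, cfg.image_px)

print("stimulus   planted feature   residual argmax   distance (px)")
for stim in stimuli:
    res = residuals[stim.stimulus_id]
    y, x = np.unravel_index(res.values.argmax(), res.shape)
    cx, cy = stim.specific_profiles[Group.CLINICIAN].components[0].center_xy
    d = np.hypot(x - cx, y - cy)
    print(f"{stim.stimulus_id}    ({cx:5.0f}, {cy:5.0f})   ({x:5d}, {y:5d})    {d:6.1f}")
# Distances are a few pixels: after removing the shared face-viewing pattern,
# what remains of each group-average map is the stimulus-specific attention.
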