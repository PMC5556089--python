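"""Simulate one subject's BOLD runs and recover per-trial amplitudes.

A single-trial ("beta series") GLM estimates one amplitude per trial per
voxel: each trial gets its own 3-s boxcar regressor convolved with the
canonical HRF, fit jointly with 24 motion-derived nuisance regressors plus
run intercepts and drifts.  Trials whose variance inflation factor against
the nuisance set reaches 2.5 are flagged for exclusion.
"""

import numpy as np

from mlmed.design import DesignSpec
from mlmed.glm import build_single_trial_design, estimate_betas
from mlmed.synth import SimConfig, SubjectParams, mediator_mask, simulate_subject

cfg = SimConfig(grid_shape=(6, 6, 6), n_mediator_voxels=7)
subject = SubjectParams(a_i=0.6, b_i=0.4, cprime_i=0.2, intercept_i=5.0,
                        moderator_w_i=0.6)
data = simulate_subject(DesignSpec(), subject, cfg, seed=11)

runs, motions = data["bold"], data["motion"]
design = build_single_trial_design(data["trials"], tr_s=2.5,
                                   run_lengths=[r.n_scans for r in runs],
                                   motion6=np.vstack(motions))
series = estimate_betas(np.vstack([r.data2d for r in runs]), design)

mask = mediator_mask(cfg).ravel()
recovered = series.betas[:, mask].mean(axis=1)
r = np.corrcoef(recovered, data["mediator"])[0, 1]
print(f"design: {design.matrix.shape[0]} scans x {design.matrix.shape[1]} regressors")
print(f"correlation(recovered betas, planted amplitudes) = {r:.3f}")
print(f"VIF range: {series.vif.min():.3f} - {series.vif.max():.3f}; "
      f"excluded trials: {series.excluded_count}/{len(series.vif)}")
# high correlation = the GLM separates single-trial responses from nuisance
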