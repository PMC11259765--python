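"""Repeated-measures correlation on simulated paired temperatures.

Each subject contributes several (estimated, reference) temperature pairs
around their own baseline; rmcorr estimates the common within-subject
association while ignoring between-subject level differences.
"""

import numpy as np

from ovutherm.diagnostics import rmcorr

rng = np.random.default_rng(0)
rho = 0.6
subjects, est, ref = [], [], []
for s in range(20):
    baseline = rng.normal(36.5, 0.22)
    bias = rng.normal(-0.3, 0.1)  # estimated CBT sits below the reference
    x = baseline + rng.normal(0, 0.2, size=10)
    y = (
        baseline
        - bias
        + rho * (x - baseline)
        + np.sqrt(1 - rho**2) * rng.normal(0, 0.2, size=10)
    )
    subjects += [f"s{s:02d}"] * 10
    est += list(x)
    ref += list(y)

res = rmcorr(subjects, est, ref)
print(f"r_rm = {res.r_rm:.3f}  (generating within-subject correlation {rho})")
print(f"df   = {res.df}   95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]   p = {res.p_value:.2e}")
print(
    "\nPer-subject offsets (the systematic bias of the estimate) do not\n"
    "affect r_rm: it measures only how the two series move together within\n"
    "each subject."
)
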