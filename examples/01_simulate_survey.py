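"""Simulate a GYTS-like adolescent smoking survey and inspect its marginals.

The generator reproduces the published sample's structure: 640 students in
grades 7-9 (shares 39.8/32.5/27.7%), ~40 binary and 0..6-coded covariates at
their published means, and a Bernoulli intention-to-quit outcome whose
intercept is calibrated so prevalence lands near 63.3%.
"""

import hierlogit as hl

data, truth = hl.generate_dataset(hl.gyts_config(seed=1))
frame = data.to_frame()

print(f"rows: {data.n}, covariates: {data.n_covariates}, grades: {data.n_groups}")
print(f"intention-to-quit prevalence: {data.y.mean():.3f}  (calibration target 0.633)")
print(f"grade shares: {frame['grade'].value_counts(normalize=True).sort_index().round(3).to_dict()}")
print(f"gender mean: {frame['gender'].mean():.3f}  (published 0.492)")
print(f"calibrated intercept alpha0 = {truth.alpha0:.3f} on the logit scale,")
print(f"grade intercept deviations {truth.group_deviations.round(3)} (sigma_mu={truth.sigma_mu})")
print("Each row is one simulated student; the truth record above is what a")
print("recovery study scores posterior estimates against.")
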