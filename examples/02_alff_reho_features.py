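"""ALFF and ReHo feature extraction from 4-D time series.

Builds a tiny two-site cohort of synthetic time series whose in-band
oscillation amplitude differs by site, runs the two feature pipelines
(smoothing before ALFF, after ReHo), and shows the site amplitude ordering
in the resulting feature matrix.
"""

import numpy as np

from harmodp import feature_pipeline, generate_timeseries_cohort, stack_feature_maps

TR = 2.0
vols, cov = generate_timeseries_cohort(
    shape=(5, 5, 5), n_timepoints=128, tr=TR,
    site_amplitudes={"siteA": 1.0, "siteB": 2.0},
    n_per_site=3, components=((0.05, 1.0),), noise_sd=0.1, seed=0,
)
mask = np.ones((5, 5, 5), bool)

alff_maps = [feature_pipeline(v, TR, "alff", fwhm_mm=6.0, voxel_size_mm=3.0, mask=mask)
             for v in vols]
reho_maps = [feature_pipeline(v, TR, "reho", fwhm_mm=6.0, voxel_size_mm=3.0, mask=mask)
             for v in vols]

fm_alff = stack_feature_maps(alff_maps, mask, cov.subject_ids, modality="ALFF")
fm_reho = stack_feature_maps(reho_maps, mask, cov.subject_ids, modality="ReHo")

codes = cov.site_codes()
for fm in (fm_alff, fm_reho):
    m0 = fm.values[codes == 0].mean()
    m1 = fm.values[codes == 1].mean()
    print(f"{fm.modality}: site A mean {m0:.3f}, site B mean {m1:.3f}")
print("-> ALFF doubles with the injected in-band amplitude (a site effect on the")
print("   spectral measure); ReHo, a rank-concordance measure, is amplitude-")
print("   invariant and barely moves — two modalities, different site sensitivity.")
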