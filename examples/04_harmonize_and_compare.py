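"""The three harmonization methods head to head on site-effect removal.

Harmonizes one cohort-scale synthetic dataset with single-projection ICA,
dual-projection ICA and ComBat, then counts the features a covariate-
adjusted site ANOVA still flags (Bonferroni-corrected p < 0.05).
"""

import warnings

from harmodp import (
    abide_like_spec,
    generate_multisite_features,
    harmonize,
    run_ica,
    site_effect_test,
)

spec = abide_like_spec(base_seed=3, n_features=400)
fm, cov, _ = generate_multisite_features(spec)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = run_ica(fm, n_components=20, seed=3)  # shared by SP and DP
    results = {"non-denoised": fm}
    for method in ("ica-sp", "ica-dp", "combat"):
        results[method], _ = harmonize(fm, cov, method=method, ica_model=model)

for name, mat in results.items():
    res = site_effect_test(mat, cov)
    print(f"{name:>13}: {res.n_significant:4d}/{mat.n_features} features "
          f"site-significant (FWE p < 0.05)")
print("-> SP removes only pure-noise courses and leaves the site variance that")
print("   hides in mixed components; DP and ComBat drive residual site effects")
print("   to (near) zero, mirroring the group-level F-test comparison on real data.")
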