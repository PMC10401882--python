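"""Signal preservation: the site-masked age effect and the t-SNE picture.

Generates a cohort where a broad negative age effect is obscured by
between-site offsets, harmonizes with each method, and reports (a) the
Pearson correlation between the per-subject median-ROI summary and age and
(b) the silhouette of the site labelling in a 2-D t-SNE embedding.
"""

import warnings

from harmodp import (
    age_masking_spec,
    embed_and_score,
    generate_multisite_features,
    harmonize,
    make_parcellation,
    median_roi_correlation,
    run_ica,
)

spec = age_masking_spec(base_seed=4)
fm, cov, _ = generate_multisite_features(spec)
parc = make_parcellation(spec.n_features, 100)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = run_ica(fm, n_components=20, seed=4)
    mats = {"non-denoised": fm}
    for method in ("ica-sp", "ica-dp", "combat"):
        mats[method], _ = harmonize(fm, cov, method=method, ica_model=model)

    for name, mat in mats.items():
        _, r, _ = median_roi_correlation(mat, parc, cov)
        emb = embed_and_score(mat, cov, seed=4)
        print(f"{name:>13}: median-ROI age correlation r = {r:+.4f}, "
              f"t-SNE site silhouette = {emb.silhouette['site']:+.3f}")
print("-> a more negative r means the true (injected) negative age effect is")
print("   better visible; a site silhouette near zero means the embedding no")
print("   longer clusters by scanner. DP and ComBat both unmask the age effect")
print("   here; SP leaves site clustering behind because it ignores mixed courses.")
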