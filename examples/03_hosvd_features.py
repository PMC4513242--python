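"""Decompose a cohort tensor by HO-SVD and extract reduced features.

The cohort tensor (subjects x regions x regions) is decomposed into an
all-orthogonal core and per-mode orthogonal factors; truncating the two
region modes to rank k gives each subject a k x k reduced matrix, which is
stacked into a k^2-dimensional feature vector.
"""

import numpy as np

from conntensor import extract_hosvd, extract_raw, extract_svd, hosvd, worked_fixture

cohort, _ = worked_fixture()          # 12 subjects, 6 regions
print(f"cohort tensor: {cohort.mode_sizes}")

result = hosvd(cohort.data)
print("mode-2 singular values:", np.round(result.mode_singular_values[1], 3))
recon = result.reconstruct()
print(f"full HO-SVD reconstruction error: {np.linalg.norm(recon - cohort.data):.2e}")

raw = extract_raw(cohort)
svd = extract_svd(cohort, k=3)
hos = extract_hosvd(cohort, k=3)
print(f"raw features:    {raw.values.shape}  (all 15 upper-triangle edges)")
print(f"SVD/PCA scores:  {svd.values.shape}  (top 3 principal components)")
print(f"HO-SVD features: {hos.values.shape}  (3 x 3 reduced slice per subject)")
# The leading mode singular values dominate: most cohort structure lives in
# a few tensor components, which is what makes truncation useful.
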