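"""Plant two latent covariance patterns and recover them with PLS.

Generates a default phantom (n=150 subjects, 16 nucleus metrics, three
NODDI condition maps sharing planted latent structure), runs the
multi-condition PLS correlation with permutation inference, and compares
the recovered voxel saliences with the planted ground truth.
"""

import numpy as np

from qmripls import phantom, pls

n = 150
truth = phantom.make_phantom(phantom.PhantomSpec(n_subjects=n, seed=1))
brain = {c: truth.noddi_maps[c].reshape(n, -1) for c in phantom.CONDITIONS}
behavior = truth.behavior.to_numpy()

result = pls.run_pls(behavior, brain, n_perm=500, n_boot=200, seed=1, n_keep=2)

v_true = truth.voxel_saliences.reshape(2, -1)
print("latent variable summary:")
for l in range(2):
    r = abs(np.corrcoef(result.v[:, l], v_true[l])[0, 1])
    print(f"  LV{l + 1}: {result.cov_fraction[l]:5.1f}% of crossblock covariance, "
          f"perm p = {result.perm_p[l]:.4f}, "
          f"|corr(recovered, planted salience)| = {r:.3f}")
    contrib = result.contributions[l]
    print("       condition contributions: "
          + ", ".join(f"{c} {contrib[c]:.1f}%" for c in phantom.CONDITIONS))

n_reliable = int((np.abs(result.bootstrap.bsr[:, 0]) > 2).sum())
print(f"voxels with |bootstrap ratio| > 2 on LV1: {n_reliable} "
      f"of {result.v.shape[0]}")
# A recovery correlation near 1 means the SVD found the planted spatial
# pattern; the permutation p tells whether it beats chance covariance.
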