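"""Simulate a small multi-echo phantom, fit every depot voxel, and compare
the recovered depot fatty-acid composition with the planted truth.

The phantom plants NDB ~ 2.1 in the SAT-like ring and ~ 1.9 in the VAT-like
blobs, which correspond to fSFA ~ 0.44 and ~ 0.47.
"""

import numpy as np

from adipocomp import (
    DEFAULT_PROTOCOL,
    PhantomSpec,
    fit_volume,
    fractions_from_ndb,
    make_phantom,
    render_multiecho,
    summarize_depot,
)

spec = PhantomSpec(grid=(48, 48, 3), sat_radii=(17.0, 21.0), vat_axes=(6.0, 4.5), seed=7)
truth = make_phantom(spec)
echoes = render_multiecho(truth, DEFAULT_PROTOCOL, noise_sd=0.5, seed=8)
maps = fit_volume(echoes, [truth.sat_mask, truth.vat_mask], DEFAULT_PROTOCOL)

print(f"fitted voxels: {int(np.isfinite(maps.ndb).sum())}, "
      f"convergence rate: {maps.convergence_rate:.3f}")
for label, mask in (("SAT", truth.sat_mask), ("VAT", truth.vat_mask)):
    s = summarize_depot(maps, mask, label)
    interior = mask & ~truth.rim_mask
    truth_fsfa = fractions_from_ndb(truth.ndb[interior])[0].mean()
    print(
        f"{label}: kept {s.n_voxels_after_ff_filter}/{s.n_voxels_initial} voxels "
        f"after erosion + 20% fat-fraction filter; "
        f"mean fSFA = {s.mean_f_sfa:.3f} (truth field: {truth_fsfa:.3f}), "
        f"fMUFA = {s.mean_f_mufa:.3f}, fPUFA = {s.mean_f_pufa:.3f}"
    )
print("The three fractions sum to 1 by construction; the fitted depot means "
      "should track the truth-field means to a few thousandths.")
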