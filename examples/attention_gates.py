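"""Inspect the two attention branches of the dual-perception head.

The spatial branch (large-kernel separable + dilated depthwise chain)
produces a per-pixel gate in (0,1); the channel branch (pooled multi-head
attention) produces one weight per channel. Both multiply the input, so
gated outputs are always bounded by the input under the default sigmoid
configuration.
"""

import numpy as np

from organodet import LGPM, PCSM, Tensor, fuse

rng = np.random.default_rng(0)
x = rng.normal(size=(1, 16, 32, 32)).astype(np.float32)

lgpm = LGPM(16, kernel_size=11, rng=np.random.default_rng(1))
z_sp, gate = lgpm(Tensor(x))
print(f"spatial gate: shape {gate.shape}, range "
      f"[{gate.data.min():.3f}, {gate.data.max():.3f}] (sigmoid -> (0,1))")

pcsm = PCSM(16, heads=4, rng=np.random.default_rng(2))
z_ch, weights = pcsm(Tensor(x))
print(f"channel weights: shape {weights.shape}, range "
      f"[{weights.data.min():.3f}, {weights.data.max():.3f}]")

fused = fuse(z_sp.data, z_ch.data)
print(f"fused feature: shape {fused.shape}; |fused| <= 2|x| holds: "
      f"{bool(np.all(np.abs(fused) <= 2 * np.abs(x) + 1e-6))}")
# The fused map feeds the parallel classification / box-regression
# branches; each branch sees both the spatially re-weighted and the
# channel re-weighted view of the same feature pyramid level.
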