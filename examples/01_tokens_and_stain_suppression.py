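"""Extract token features from a synthetic tile and factorise them.

Renders one OSCC-like tile, runs the mini backbone to get an 8x8 token grid,
and applies the stain-suppression module.  The printed gate statistics show
the per-token mixing weight alpha between the morphology-dominant component
(alpha -> 1) and the stain-related component (alpha -> 0); at initialisation
the gate is neutral (alpha = 0.5 everywhere) and moves only once trained.
"""

import numpy as np

from histomorph import (
    MiniBackbone,
    MorphologySpec,
    DomainStyle,
    StainSuppression,
    extract_tokens,
    render_image,
)

rng = np.random.default_rng(0)
image, nuclei_count = render_image(
    MorphologySpec(), DomainStyle(gain=(1.18, 0.88, 1.06)), label=1, rng=rng, side=64
)
print(f"rendered a 64x64 OSCC-like tile with {nuclei_count} nuclei")

backbone = MiniBackbone(seed=0)
tokens = extract_tokens((image - 0.5) / 0.5, backbone)
print(f"token grid: {tokens.grid_shape}, {tokens.n_tokens} tokens x "
      f"{tokens.channels} channels")

sda = StainSuppression(tokens.channels, window=4, seed=1)
fused = sda.sda_forward(tokens)
print(f"gate alpha: min={fused.alpha.min():.3f} max={fused.alpha.max():.3f} "
      f"(0 = stain component, 1 = morphology component)")
print(f"fused features: {fused.fused.shape}, every row a convex mix of the "
      "morphology and stain rows")
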