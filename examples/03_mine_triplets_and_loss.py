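"""Online triplet mining and the ACA loss on one batch.

Mines every conditional activity-cliff triplet from a batch of labels
under the cliff cut-offs, shows the per-triplet soft margins, and
evaluates the combined ACA loss for aligned and random latent spaces.
"""

import numpy as np

from cliffaware import ACALossConfig, CliffCutoffs, aca_loss, mine_conditional_triplets

labels = np.array([5.0, 5.05, 7.5, 7.4, 5.2])
triplets = mine_conditional_triplets(labels, CliffCutoffs(cl=0.3, cu=1.0))
print(f"batch labels: {labels}")
print(f"mined M = {len(triplets)} conditional triplets (anchor, positive, negative, margin):")
for t in list(triplets)[:6]:
    print(f"  A={t.anchor} P={t.positive} N={t.negative} margin={t.margin:.2f}")

config = ACALossConfig(alpha=1.0, cl=0.3, cu=1.0)
pred = labels + np.array([0.1, -0.1, 0.2, 0.0, -0.05])

aligned = labels[:, None]  # 1-D latents equal to the labels
out = aca_loss(pred, labels, aligned, config)
print(f"\nlatents aligned with labels: total={out.total:.4f} "
      f"(regression {out.regression_term:.4f} + alpha*contrastive {out.contrastive_term:.4f}), "
      f"M'={out.m_high_value}")
# With latent distances matching label distances every hinge is zero:
# the contrastive term vanishes and only the regression error remains.

rng = np.random.default_rng(0)
out = aca_loss(pred, labels, rng.normal(size=(5, 8)), config)
print(f"random latents:              total={out.total:.4f} "
      f"(regression {out.regression_term:.4f} + alpha*contrastive {out.contrastive_term:.4f}), "
      f"M'={out.m_high_value}")
# Random latents violate most triplets (M' > 0) and the triplet
# soft-margin term dominates the loss, pushing the encoder to reorganize.
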