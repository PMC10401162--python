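"""The pretraining loss formulas on worked inputs.

Shows the multiclass cross-entropy on a one-hot target, and how the
equalized focal loss up-weights an imbalanced category: at equal
confidence 0.5, a category with balance g=0.5 gets focusing factor
gamma = gamma_b + s(1-g) = 4 and weight gamma/gamma_b = 2, so its loss
differs from the balanced (g=1) focal form.
"""

import math

from otfrm import EFLParams, cross_entropy, equalized_focal_loss, focal_loss

print(f"CE(one-hot, uniform over 4) = {cross_entropy([1,0,0,0], [0.25]*4):.5f}"
      f"  (= log 4 = {math.log(4):.5f})")
print(f"CE((1,0), (0.8,0.2))        = {cross_entropy([1,0], [0.8,0.2]):.5f}")

balanced = EFLParams(alpha_t=1.0, gamma_b=2.0, s=4.0, g={"j": 1.0})
imbalanced = EFLParams(alpha_t=1.0, gamma_b=2.0, s=4.0, g={"j": 0.5})
print(f"\nEFL at p=0.5, balanced g=1   = {equalized_focal_loss({'j': 0.5}, balanced):.5f}"
      f"  (= focal form {focal_loss(0.5, 1.0, 2.0):.5f})")
print(f"EFL at p=0.5, imbalanced g=0.5 = {equalized_focal_loss({'j': 0.5}, imbalanced):.5f}"
      f"  (weight 2, focusing factor 4)")
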