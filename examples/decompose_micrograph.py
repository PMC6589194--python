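"""Cartoon-texture decomposition of a synthetic micrograph.

Renders one micrograph-like scene, splits it into cartoon (u) and texture
(v) components with the nonlinear LTV filter, and shows how blurring the
scene drains energy out of the texture component.
"""

import numpy as np

from semsharp import SceneSpec, decompose, make_blur_series

series = make_blur_series(SceneSpec(seed=7))

print("blur sigma | texture energy fraction | max |f-(u+v)|")
for img, sigma_b in zip(series.images, series.blur_sigmas):
    f = img.to_canonical()
    dec = decompose(f, sigma=3.0)
    frac = np.sum(dec.texture ** 2) / np.sum(f ** 2)
    err = np.max(np.abs(f - (dec.cartoon + dec.texture)))
    print(f"{sigma_b:10.1f} | {frac:23.5f} | {err:.2e}")

print()
print("The texture fraction shrinks as blur removes oscillatory content;")
print("the reconstruction error stays at machine precision because v is")
print("defined as the exact residual f - u.")
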