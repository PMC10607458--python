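"""Compute the eye aspect ratio (EAR) from six eye landmarks.

Builds an open-eye landmark set, closes it gradually, and shows that the
ratio is invariant to camera distance (uniform scaling).
"""

from blinkscore import compute_ear
from blinkscore.synthetic import landmarks_for_ear

open_eye = landmarks_for_ear(0.25)
print(f"open eye          EAR = {compute_ear(open_eye):.3f}")

for target in (0.18, 0.10, 0.02):
    print(f"closing eye       EAR = {compute_ear(landmarks_for_ear(target)):.3f}")

# moving the camera twice as far just scales all landmarks: EAR is unchanged
far = open_eye.transformed(scale=0.5, offset=(120.0, 80.0))
print(f"same eye, farther EAR = {compute_ear(far):.3f}")

# EAR ~0.25 means an open eye; values near 0 mean closed lids. Scale
# invariance is why a single threshold can work across recording setups.
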