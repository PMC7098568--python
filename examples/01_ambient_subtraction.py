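"""Ambient subtraction: recover flash-only color from a flash/no-flash pair.

Renders a grey patch under strong fluorescent-like ambient light, measures
the ROI with and without subtraction, and compares the native rg
chromaticity to a zero-ambient reference capture.
"""

from chromacal import (
    CaptureSettings,
    make_grey_scene,
    measure_pair,
    render_pair,
    rect_mask,
    rg_distance,
    to_rg,
)
from chromacal.simulate import auto_exposure_time
from chromacal.standards import fluorescent_ambient
from chromacal.studies import phone_a

camera = phone_a()
scene = make_grey_scene(reflectance_value=0.35, shape=(64, 64))
roi = rect_mask(scene.shape, (8, 8, 48, 48))
t = auto_exposure_time(scene, camera, target_fraction=0.4)

flash, noflash = render_pair(
    scene, camera, CaptureSettings(t, seed=1), fluorescent_ambient().scaled(0.2)
)
m = measure_pair(flash, noflash, roi)

ref_flash, ref_noflash = render_pair(scene, camera, CaptureSettings(t, seed=2), None)
ref = measure_pair(ref_flash, ref_noflash, roi)

rg_raw = to_rg(m.f_flash_ambient)
rg_sub = to_rg(m.f_flash_only)
rg_ref = to_rg(ref.f_flash_only)

print(f"rg of raw flash frame (ambient-contaminated): ({rg_raw[0]:.4f}, {rg_raw[1]:.4f})")
print(f"rg after flash/no-flash subtraction:          ({rg_sub[0]:.4f}, {rg_sub[1]:.4f})")
print(f"rg of a zero-ambient reference capture:       ({rg_ref[0]:.4f}, {rg_ref[1]:.4f})")
print(f"distance to reference before subtraction: {rg_distance(rg_raw, rg_ref):.4f}")
print(f"distance to reference after subtraction:  {rg_distance(rg_sub, rg_ref):.4f}")
print()
print("Subtraction removes the fluorescent tint: the subtracted rg lands on")
print("the flash-only reference to within shot noise (~1e-3), while the raw")
print("flash frame is biased by the ambient spectrum.")
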