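"""Pre-configured simulation studies exercising the full pipeline.

Each function runs one self-contained in-silico experiment — ambient
invariance, mapping recovery in the Luther limit, exposure independence,
intensity non-uniformity correction, SSNR-threshold determination, CAMP
classification, sensor noise statistics, custom-card benefit — under fixed
study conditions (card sizes, patch geometry, exposure targets, ambient
levels) and returns a small dict of summary numbers. Seeds control every
stochastic component; deterministic studies ignore them.

These are the conditions the test suite and the reproduction script both
run; they are chosen to put signals in the sensor mid-range where the
linear, shot-noise-limited model holds.
"""

from __future__ import annotations

import numpy as np

from .ambient import measure_pair, subtract_pair
from .calibration import (
    PatchMatrix,
    apply_mapping,
    calibrate_device,
    fit_linear_mapping,
    grey_intensity,
    inuc_correct,
)
from .cards import (
    classic24_reflectances,
    random_reflectances,
    reference_card_from_reflectances,
    yellow_test_reflectances,
    yellow_training_reflectances,
)
from .chroma import rg_distance, to_xy, xy_distance
from .evaluate import camp, camp_curve, measure_card_rg, run_ssnr_threshold_experiment
from .frames import demosaic, linearize, rect_mask, roi_median_rgb
from .simulate import (
    CameraModel,
    CaptureSettings,
    auto_exposure_time,
    make_card_scene,
    make_grey_scene,
    render_frame,
    render_pair,
)
from .standards import (
    d50_flash,
    daylight_ambient,
    fluorescent_ambient,
    gaussian_camera_sensitivity,
    led_flash,
    luther_camera_sensitivity,
    screen_flash,
)

__all__ = [
    "phone_a",
    "phone_b",
    "luther_phone",
    "ambient_invariance_study",
    "luther_recovery_study",
    "normal_equations_agreement",
    "exposure_independence_study",
    "inuc_study",
    "threshold_study",
    "camp_hand_cases",
    "camp_pipeline_study",
    "sensor_statistics_study",
    "custom_card_study",
]


def phone_a() -> CameraModel:
    """Simulated rear-camera phone: Gaussian-band sensor, LED-like flash."""
    return CameraModel(gaussian_camera_sensitivity(), led_flash(), device_id="phoneA")


def phone_b() -> CameraModel:
    """Second simulated phone: shifted Gaussian bands, screen-backlight flash."""
    return CameraModel(
        gaussian_camera_sensitivity((610.0, 545.0, 455.0), (50.0, 55.0, 40.0)),
        screen_flash(),
        device_id="phoneB",
    )


def luther_phone() -> CameraModel:
    """Luther-condition camera with a D50-shaped flash.

    Its sensitivities are linear combinations of the CIE observer, and its
    flash matches the XYZ reference illuminant, so an exact 3×3 RGB→XYZ
    mapping exists — the limit case in which calibration should be perfect.
    """
    return CameraModel(
        luther_camera_sensitivity(), d50_flash(), device_id="luther-phone"
    )


def _calibrate(
    camera: CameraModel,
    seed: int | None,
    noise: bool = True,
    shading_profile: str = "uniform",
    falloff_strength: float = 0.3,
    target_fraction: float = 0.45,
):
    """One-time calibration of a camera on the 24-patch general card."""
    bank = classic24_reflectances()
    card = reference_card_from_reflectances("classic24", bank)
    scene = make_card_scene(
        bank, (4, 6), shading_profile=shading_profile, falloff_strength=falloff_strength
    )
    grey = make_grey_scene(
        shape=scene.shape,
        shading_profile=shading_profile,
        falloff_strength=falloff_strength,
    )
    t = auto_exposure_time(scene, camera, target_fraction=target_fraction)
    s1 = CaptureSettings(t, seed=seed, noise=noise)
    s2 = CaptureSettings(t, seed=None if seed is None else seed + 1, noise=noise)
    mapping = calibrate_device(
        render_pair(scene, camera, s1),
        render_pair(grey, camera, s2),
        scene.patch_rois(margin=6),
        card,
    )
    return mapping, card, scene, t


def ambient_invariance_study(seed: int = 0, n_patches: int = 24) -> dict:
    """Subtracted chromaticity under two different ambient spectra.

    A test card is imaged (flash/no-flash) under daylight-like and
    fluorescent-like ambient light at the same flash exposure; the ambient
    level is set so every patch clears SSNR 10. After subtraction the
    per-patch native rg values of the two conditions should coincide up to
    shot noise.
    """
    camera = phone_a()
    bank = random_reflectances(n_patches, seed=seed + 1000, prefix="test")
    rows = int(np.ceil(n_patches / 6))
    scene = make_card_scene(bank, (rows, 6))
    t = auto_exposure_time(scene, camera, target_fraction=0.4)
    rg_day, ssnr_day = measure_card_rg(
        scene, camera, CaptureSettings(t, seed=seed), daylight_ambient().scaled(0.10)
    )
    rg_flu, ssnr_flu = measure_card_rg(
        scene,
        camera,
        CaptureSettings(t, seed=seed + 1),
        fluorescent_ambient().scaled(0.10),
    )
    # the invariance claim is scoped to well-exposed patches (SSNR > 10)
    qualified = [
        p for p in bank if min(ssnr_day[p], ssnr_flu[p]) > 10.0
    ]
    dists = [rg_distance(rg_day[p], rg_flu[p]) for p in qualified]
    return {
        "mean_rg_distance": float(np.mean(dists)),
        "max_rg_distance": float(np.max(dists)),
        "min_ssnr": float(min(min(ssnr_day[p], ssnr_flu[p]) for p in qualified)),
        "n_patches": len(qualified),
        "n_rendered": n_patches,
    }


def luther_recovery_study() -> dict:
    """Noiseless calibration of the Luther camera: training-patch xy error."""
    camera = luther_phone()
    mapping, card, scene, _ = _calibrate(camera, seed=None, noise=False)
    t = auto_exposure_time(scene, camera, target_fraction=0.45)
    flash, noflash = render_pair(scene, camera, CaptureSettings(t, noise=False))
    errs = []
    for pid, rect in scene.patch_rois(margin=6).items():
        roi = rect_mask(scene.shape, rect)
        m = measure_pair(flash, noflash, roi)
        xy = to_xy(apply_mapping(m.f_flash_only, mapping))
        errs.append(xy_distance(xy, to_xy(card.xyz[pid])))
    return {"max_xy_error": float(np.max(errs)), "n_patches": len(errs)}


def normal_equations_agreement(seed: int = 0, n_instances: int = 20) -> dict:
    """Least-squares solver vs the explicit normal-equations formula.

    Random well-conditioned N=24 design matrices with H = R·M_true; reports
    the worst elementwise disagreement between the two solution paths and
    the worst recovery error of M_true.
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    max_recovery = 0.0
    for _ in range(n_instances):
        R = rng.uniform(0.1, 1.0, size=(24, 3))
        M_true = rng.uniform(-1.0, 1.0, size=(3, 3)) + 2.0 * np.eye(3)
        H = R @ M_true
        ids = tuple(f"p{i}" for i in range(24))
        fitted = fit_linear_mapping(PatchMatrix(ids, R), PatchMatrix(ids, H)).matrix
        normal_eq = np.linalg.inv(R.T @ R) @ R.T @ H
        max_diff = max(max_diff, float(np.abs(fitted - normal_eq).max()))
        max_recovery = max(max_recovery, float(np.abs(fitted - M_true).max()))
    return {
        "max_solver_disagreement": max_diff,
        "max_recovery_error": max_recovery,
        "n_instances": n_instances,
    }


def exposure_independence_study(n_holdout: int = 12, seed: int = 0) -> dict:
    """Reported xy must not move when exposure time doubles (noiseless).

    Calibrates the phone once, then measures held-out patches at exposure t
    and 2t with the same mapping; also re-runs the calibration at 2t and
    compares the fitted matrices (the grey-card division removes the global
    intensity scale, so they should be identical).
    """
    camera = phone_a()
    mapping, card, scene, t = _calibrate(
        camera, seed=None, noise=False, target_fraction=0.25
    )
    bank = random_reflectances(n_holdout, seed=seed + 2000, prefix="held")
    rows = int(np.ceil(n_holdout / 6))
    test_scene = make_card_scene(bank, (rows, 6))
    t_test = auto_exposure_time(test_scene, camera, target_fraction=0.25)

    def xy_at(exposure):
        flash, noflash = render_pair(
            test_scene, camera, CaptureSettings(exposure, noise=False)
        )
        out = {}
        for pid, rect in test_scene.patch_rois(margin=6).items():
            m = measure_pair(flash, noflash, rect_mask(test_scene.shape, rect))
            out[pid] = to_xy(apply_mapping(m.f_flash_only, mapping))
        return out

    xy1, xy2 = xy_at(t_test), xy_at(2 * t_test)
    max_shift = max(xy_distance(xy1[p], xy2[p]) for p in bank)

    bank24 = classic24_reflectances()
    card24 = reference_card_from_reflectances("classic24", bank24)
    cal_scene = make_card_scene(bank24, (4, 6))
    grey = make_grey_scene(shape=cal_scene.shape)

    def calibrate_at(exposure):
        s = CaptureSettings(exposure, noise=False)
        return calibrate_device(
            render_pair(cal_scene, camera, s),
            render_pair(grey, camera, s),
            cal_scene.patch_rois(margin=6),
            card24,
        )

    m1, m2 = calibrate_at(t), calibrate_at(2 * t)
    return {
        "max_xy_shift": float(max_shift),
        "max_mapping_difference": float(np.abs(m1.matrix - m2.matrix).max()),
        "n_holdout": n_holdout,
    }


def inuc_study(falloff_strength: float = 0.5) -> dict:
    """Grey-card intensity correction under strong radial flash falloff.

    The same reflectance is placed at a corner and at the centre of a card
    rendered with quadratic vignetting (noiseless). Before correction the
    two measured RGB rows differ by the shading ratio; after division by the
    grey-card intensity map they should agree per channel.
    """
    camera = phone_a()
    bank = classic24_reflectances()
    dup = bank["orange-yellow"]
    spectra = {"corner-dup": dup}
    others = {p: r for p, r in bank.items() if p != "orange-yellow"}
    ids = list(others)
    for k, pid in enumerate(ids[:22]):
        spectra[pid] = others[pid]
        if k == 8:  # duplicate lands at grid index 10 (row 1, col 4), near centre
            spectra["center-dup"] = dup
    scene = make_card_scene(
        spectra, (4, 6), shading_profile="radial", falloff_strength=falloff_strength
    )
    grey = make_grey_scene(
        shape=scene.shape, shading_profile="radial", falloff_strength=falloff_strength
    )
    t = auto_exposure_time(scene, camera, target_fraction=0.45)
    s = CaptureSettings(t, noise=False)
    flash, noflash = render_pair(scene, camera, s)
    gflash, gnoflash = render_pair(grey, camera, s)

    rois = scene.patch_rois(margin=6)
    img_f, img_a = demosaic(linearize(flash)), demosaic(linearize(noflash))
    rows = {}
    for pid, rect in rois.items():
        roi = rect_mask(scene.shape, rect)
        rows[pid] = subtract_pair(roi_median_rgb(img_f, roi), roi_median_rgb(img_a, roi))
    R = PatchMatrix(tuple(rows), np.array(list(rows.values())))

    gf, ga = demosaic(linearize(gflash)), demosaic(linearize(gnoflash))
    from .frames import RGBImage

    grey_only = RGBImage(r=gf.r - ga.r, g=gf.g - ga.g, b=gf.b - ga.b)
    intensity = grey_intensity(grey_only, rois)
    corrected = inuc_correct(R, intensity)

    def row(pm, pid):
        return pm.values[pm.patch_ids.index(pid)]

    before = row(R, "corner-dup") / row(R, "center-dup")
    after = row(corrected, "corner-dup") / row(corrected, "center-dup")
    return {
        "max_channel_mismatch_before": float(np.abs(before - 1).max()),
        "max_channel_mismatch_after": float(np.abs(after - 1).max()),
    }


def threshold_study(seed: int = 0) -> dict:
    """Simulated SSNR-threshold determination on the 24-patch card.

    The flash exposure is deliberately weak (≈5% of sensor range on the
    brightest patch) and the daylight-like ambient is stepped through a
    geometric intensity ladder, spanning SSNR from below 1 to ≈30 without
    saturating. Ground truth and the repeatability baseline come from three
    zero-ambient sessions.
    """
    camera = phone_a()
    bank = classic24_reflectances()
    scene = make_card_scene(bank, (4, 6))
    t = auto_exposure_time(scene, camera, target_fraction=0.05)
    ambient = daylight_ambient()
    base = auto_exposure_time(scene, camera, ambient=ambient, flash_on=False,
                              target_fraction=0.05)
    # ambient-to-flash signal ratios from 0.3 to 15 at the flash exposure t;
    # keeps the brightest flash+ambient pixel below saturation
    scales = base / t * np.geomspace(0.3, 15.0, 8)
    result = run_ssnr_threshold_experiment(
        scene,
        camera,
        CaptureSettings(t, noise=True),
        ambient,
        ambient_scales=scales,
        n_baseline_sessions=3,
        seed=seed,
    )
    ssnrs = np.array([s.ssnr for s in result.samples])
    dists = np.array([s.rg_distance_to_gt for s in result.samples])
    # mean rg error in SSNR quartile bins, highest SSNR last
    edges = np.quantile(ssnrs, [0.0, 0.25, 0.5, 0.75, 1.0])
    binned = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (ssnrs >= lo) & (ssnrs <= hi)
        binned.append(float(dists[sel].mean()))
    return {
        "ssnr_threshold": result.ssnr_threshold,
        "baseline_mean": result.baseline_mean,
        "baseline_plus_sd": result.baseline_plus_sd,
        "binned_rg_error": binned,
        "n_samples": len(result.samples),
        "ssnr_range": [float(ssnrs.min()), float(ssnrs.max())],
        "result": result,
    }


def camp_hand_cases() -> dict:
    """Hand-checkable CAMP kernels: identity, total confusion, 3-point case."""
    gt = {"p0": (0.0, 0.0), "p1": (1.0, 0.0), "p2": (0.0, 1.0)}
    ident = camp(gt, [dict(gt), dict(gt)], d_min=0.0, n_permutations=10, seed=0)
    # one phone cyclically confused: every patch classifies to another patch's
    # ground truth, so the all-phones conjunction zeroes the accuracy even
    # though the other phone is exact
    shifted = {"p0": gt["p1"], "p1": gt["p2"], "p2": gt["p0"]}
    zeroed = camp(gt, [dict(gt), shifted], d_min=0.0, n_permutations=10, seed=0)
    # phone B displaces p0's point to (0.6, 0): nearest ground truth becomes
    # p1, so exactly one of three patches fails -> 66.7%
    phone_b_maps = {"p0": (0.6, 0.0), "p1": (1.0, 0.0), "p2": (0.0, 1.0)}
    two_phone = camp(gt, [dict(gt), phone_b_maps], d_min=0.0, n_permutations=10, seed=0)
    return {
        "identity_camp": ident.camp,
        "zeroed_camp": zeroed.camp,
        "two_phone_camp": two_phone.camp,
    }


def camp_pipeline_study(
    seed: int = 0,
    n_patches: int = 48,
    d_min_values=(0.01, 0.02, 0.05, 0.1),
    n_permutations: int = 1000,
) -> dict:
    """End-to-end two-camera CAMP₂ on a synthetic held-out card.

    Both simulated phones are calibrated on the general card, then measure
    the same held-out patches with no ambient light; mapped xy values are
    classified against the spectrophotometer-style ground truth over a grid
    of minimum separations.
    """
    cams = [phone_a(), phone_b()]
    mappings = [_calibrate(cam, seed=seed + 10 * k)[0] for k, cam in enumerate(cams)]
    bank = random_reflectances(n_patches, seed=seed + 3000, prefix="dc")
    card = reference_card_from_reflectances("dc-like", bank)
    rows = int(np.ceil(n_patches / 8))
    scene = make_card_scene(bank, (rows, 8))
    gt = {pid: to_xy(card.xyz[pid]) for pid in bank}

    per_phone = []
    for k, (cam, mapping) in enumerate(zip(cams, mappings)):
        t = auto_exposure_time(scene, cam, target_fraction=0.45)
        flash, noflash = render_pair(
            scene, cam, CaptureSettings(t, seed=seed + 100 + k)
        )
        mapped = {}
        for pid, rect in scene.patch_rois(margin=6).items():
            m = measure_pair(flash, noflash, rect_mask(scene.shape, rect))
            mapped[pid] = to_xy(apply_mapping(m.f_flash_only, mapping))
        per_phone.append(mapped)

    curve = camp_curve(
        gt, per_phone, d_min_values, n_permutations=n_permutations, seed=seed
    )
    return {
        "d_min_values": list(d_min_values),
        "camp_values": [p.camp for p in curve.points],
        "mean_min_separations": [p.mean_min_separation for p in curve.points],
        "per_phone": per_phone,
        "gt": gt,
        "n_patches": n_patches,
    }


def sensor_statistics_study(seed: int = 0) -> dict:
    """Shot-noise statistics and exposure linearity of the simulator.

    A flat grey frame (10⁴ photosites) yields realized electron counts whose
    variance/mean ratio should be ≈1; a noiseless exposure ramp checks that
    the mean signal is strictly proportional to exposure time.
    """
    camera = phone_a()
    scene = make_grey_scene(reflectance_value=0.35, shape=(100, 100))
    t = auto_exposure_time(scene, camera, target_fraction=0.2)
    frame = render_frame(
        scene, camera, CaptureSettings(t, flash_on=True, seed=seed), ambient=None
    )
    counts = (np.asarray(frame.dn, float) - camera.black_level) * camera.gain
    chan = frame.channel_map()
    ratios = []
    means = []
    for ch in (0, 1, 2):
        c = counts[chan == ch]
        ratios.append(float(c.var() / c.mean()))
        means.append(float(c.mean()))

    base = render_frame(
        scene, camera, CaptureSettings(t, flash_on=True, noise=False), ambient=None
    )
    sig0 = np.asarray(base.dn, float) - camera.black_level
    devs = []
    for k in (2.0, 3.0, 5.0):
        fk = render_frame(
            scene, camera, CaptureSettings(k * t, flash_on=True, noise=False), ambient=None
        )
        sig = np.asarray(fk.dn, float) - camera.black_level
        devs.append(float(np.abs(sig / (k * sig0) - 1.0).max()))
    return {
        "variance_mean_ratio": float(np.mean(ratios)),
        "variance_mean_ratios": ratios,
        "min_mean_electrons": float(min(means)),
        "n_pixels": int(counts.size),
        "max_linearity_deviation": float(max(devs)),
    }


def custom_card_study(seed: int = 0) -> dict:
    """General vs custom-card calibration on a narrow target color region.

    A Luther-violating phone is calibrated twice — once on the 24-patch
    general card, once on a 30-patch yellows+neutrals card — and both
    mappings measure a held-out yellows card from a different spectral
    family. Reports the mean xy error of each mapping on the test patches;
    a calibration focused on the target region should do strictly better
    there.
    """
    camera = phone_a()
    general_mapping, _, _, _ = _calibrate(camera, seed=seed)

    # The two yellows cards are fixed artifacts of the study (like physical
    # cards from two manufacturers); the run seed varies only capture noise.
    ytrain = yellow_training_reflectances()
    ycard = reference_card_from_reflectances("yellows-training", ytrain)
    yscene = make_card_scene(ytrain, (5, 6))
    grey = make_grey_scene(shape=yscene.shape)
    t = auto_exposure_time(yscene, camera, target_fraction=0.45)
    yellow_mapping = calibrate_device(
        render_pair(yscene, camera, CaptureSettings(t, seed=seed + 1)),
        render_pair(grey, camera, CaptureSettings(t, seed=seed + 2)),
        yscene.patch_rois(margin=6),
        ycard,
    )

    ytest = yellow_test_reflectances()
    tcard = reference_card_from_reflectances("yellows-test", ytest)
    tscene = make_card_scene(ytest, (4, 6))
    tt = auto_exposure_time(tscene, camera, target_fraction=0.45)
    flash, noflash = render_pair(tscene, camera, CaptureSettings(tt, seed=seed + 3))

    errs = {"general": [], "yellows": []}
    for pid, rect in tscene.patch_rois(margin=6).items():
        m = measure_pair(flash, noflash, rect_mask(tscene.shape, rect))
        gt_xy = to_xy(tcard.xyz[pid])
        for label, mapping in (("general", general_mapping), ("yellows", yellow_mapping)):
            xy = to_xy(apply_mapping(m.f_flash_only, mapping))
            errs[label].append(xy_distance(xy, gt_xy))
    general = float(np.mean(errs["general"]))
    yellows = float(np.mean(errs["yellows"]))
    return {
        "mean_xy_error_general": general,
        "mean_xy_error_yellows": yellows,
        "improvement_ratio": yellows / general,
        "n_test_patches": len(errs["general"]),
    }
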