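"""Evaluation procedures: SSNR-threshold determination and CAMP accuracy.

Two protocol-level experiments sit on top of the measurement pipeline.

**SSNR threshold.** A colorcard is imaged under increasing ambient light at
fixed flash; each patch yields an SSNR and an rg-chromaticity distance to
its zero-ambient ground truth. The intrinsic repeatability floor (mean
same-patch rg distance across repeated zero-ambient sessions, plus one
standard deviation) defines "good enough": the recommended SSNR threshold is
the smallest SSNR above which every patch stays under that ceiling.

**CAMP_n** (Classification Accuracy for Multiple Phones). For a given
minimum chromaticity separation, random subsets of ground-truth points at
least that far apart are drawn; each phone's mapped value for each subset
patch is classified to the nearest ground-truth subset point, and a patch
counts as correct only if *every* phone classifies it correctly. The
percentage correct, averaged over many unique subset permutations, measures
how finely separated colors can be distinguished across devices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ambient import measure_pair
from .chroma import rg_distance, to_rg
from .errors import InsufficientDataError, SubtractionError
from .frames import rect_mask
from .simulate import (
    CameraModel,
    CaptureSettings,
    SceneModel,
    render_pair,
)
from .spectra import IlluminantSPD

__all__ = [
    "ThresholdSample",
    "ThresholdExperimentResult",
    "CampPoint",
    "CampCurve",
    "intrinsic_baseline",
    "find_ssnr_threshold",
    "select_subset",
    "camp",
    "camp_curve",
    "measure_card_rg",
    "run_ssnr_threshold_experiment",
]


@dataclass(frozen=True)
class ThresholdSample:
    """One patch under one ambient level: its SSNR and rg error vs ground truth."""

    patch_id: str
    ssnr: float
    rg_distance_to_gt: float


@dataclass(frozen=True)
class ThresholdExperimentResult:
    samples: tuple[ThresholdSample, ...]
    baseline_mean: float
    baseline_plus_sd: float
    ssnr_threshold: float


@dataclass(frozen=True)
class CampPoint:
    """CAMP at one minimum-separation setting."""

    mean_min_separation: float
    camp: float  # percentage in [0, 100]
    n_permutations: int
    n_phones: int
    n_skipped: int = 0
    d_min: float = 0.0


@dataclass(frozen=True)
class CampCurve:
    points: tuple[CampPoint, ...]


def intrinsic_baseline(
    repeat_sessions: list[dict[str, tuple[float, float]]],
) -> tuple[float, float]:
    """Repeatability floor from same-patch rg distances across sessions.

    Returns (mean, mean + 1 SD) over all same-patch pairs of distinct
    sessions. Population SD (ddof = 0) so a single pair is well-defined.
    """
    if len(repeat_sessions) < 2:
        raise InsufficientDataError("need at least two sessions for a baseline")
    ids = set(repeat_sessions[0])
    for sess in repeat_sessions[1:]:
        if set(sess) != ids:
            raise InsufficientDataError("sessions must share one patch id set")
    dists = [
        rg_distance(repeat_sessions[i][pid], repeat_sessions[j][pid])
        for i in range(len(repeat_sessions))
        for j in range(i + 1, len(repeat_sessions))
        for pid in ids
    ]
    mean = float(np.mean(dists))
    sd = float(np.std(dists))
    return mean, mean + sd


def find_ssnr_threshold(samples, baseline_plus_sd: float) -> float:
    """Smallest SSNR above which every sample's rg error is within the ceiling.

    Samples with SSNR ≥ the returned value all satisfy
    rg_distance ≤ baseline_plus_sd. If even the highest-SSNR sample violates
    the ceiling, +inf is returned with a warning.
    """
    records = [
        (s.ssnr, s.rg_distance_to_gt) if isinstance(s, ThresholdSample) else (s[1], s[2])
        for s in samples
    ]
    if not records:
        raise InsufficientDataError("no samples provided")
    ssnrs = np.array([r[0] for r in records])
    dists = np.array([r[1] for r in records])
    if not np.all(np.isfinite(ssnrs)):
        raise InsufficientDataError("samples contain non-finite SSNR")
    violators = ssnrs[dists > baseline_plus_sd]
    if violators.size == 0:
        return float(ssnrs.min())
    worst = float(violators.max())
    above = ssnrs[ssnrs > worst]
    if above.size == 0:
        warnings.warn(
            "no SSNR level clears the rg-distance ceiling; retake the sweep",
            stacklevel=2,
        )
        return float("inf")
    return float(above.min())


def select_subset(
    points, d_min: float, rng: np.random.Generator | int | None = None
) -> tuple[list[int], float]:
    """Random-order greedy selection of points pairwise at least d_min apart.

    Returns (accepted indices in original order, minimum pairwise distance of
    the accepted set; inf for fewer than two points).
    """
    if d_min < 0:
        raise ValueError("d_min must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pts = np.asarray(points, dtype=float)
    order = rng.permutation(len(pts))
    accepted: list[int] = []
    for idx in order:
        if accepted:
            diffs = pts[idx] - pts[accepted]
            if np.hypot(diffs[:, 0], diffs[:, 1]).min() < d_min:
                continue
        accepted.append(int(idx))
    accepted.sort()
    if len(accepted) < 2:
        return accepted, float("inf")
    sub = pts[accepted]
    diffs = sub[:, None, :] - sub[None, :, :]
    dist = np.hypot(diffs[..., 0], diffs[..., 1])
    min_sep = float(dist[np.triu_indices(len(accepted), k=1)].min())
    return accepted, min_sep


def camp(
    gt: dict[str, tuple[float, float]],
    per_phone_mapped: list[dict[str, tuple[float, float]]],
    d_min: float,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> CampPoint:
    """CAMP at one minimum-separation level, averaged over subset permutations.

    Per permutation a separated ground-truth subset is drawn; each phone's
    mapped point for each subset patch is nearest-neighbour classified to the
    ground-truth subset, and a patch is correct only if all phones agree with
    its own ground truth. Subset uniqueness is enforced by hashing index
    sets, re-drawing on collision up to 50× n_permutations attempts; when the
    subset space is smaller than requested (e.g. d_min = 0 admits only the
    full set) the unique subsets found are used. Ties in the classification
    break to the lowest patch index. Subsets below two points are skipped and
    counted.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    ids = list(gt.keys())
    for phone in per_phone_mapped:
        missing = [p for p in ids if p not in phone]
        if missing:
            raise InsufficientDataError(f"phone data missing patches {missing}")
    gt_pts = np.array([gt[p] for p in ids])
    phone_pts = np.array([[phone[p] for p in ids] for phone in per_phone_mapped])
    rng = np.random.default_rng(seed)

    seen: set[frozenset] = set()
    subsets: list[tuple[list[int], float]] = []
    n_skipped = 0
    attempts = 0
    stagnant = 0
    max_attempts = 50 * n_permutations
    max_stagnant = max(200, n_permutations // 5)  # subset space exhausted
    while len(subsets) + n_skipped < n_permutations and attempts < max_attempts:
        attempts += 1
        accepted, min_sep = select_subset(gt_pts, d_min, rng)
        if len(accepted) < 2:
            n_skipped += 1
            continue
        key = frozenset(accepted)
        if key in seen:
            stagnant += 1
            if stagnant >= max_stagnant:
                break
            continue
        stagnant = 0
        seen.add(key)
        subsets.append((accepted, min_sep))
    if not subsets:
        raise InsufficientDataError(
            "no usable subset of size >= 2 could be drawn at this separation"
        )

    camps = []
    seps = []
    for accepted, min_sep in subsets:
        sub_gt = gt_pts[accepted]  # ascending index order: ties -> lowest index
        sub_phones = phone_pts[:, accepted, :]
        d = np.linalg.norm(sub_phones[:, :, None, :] - sub_gt[None, None, :, :], axis=-1)
        nn = np.argmin(d, axis=-1)
        correct = np.all(nn == np.arange(len(accepted))[None, :], axis=0)
        camps.append(100.0 * correct.mean())
        seps.append(min_sep)
    return CampPoint(
        mean_min_separation=float(np.mean(seps)),
        camp=float(np.mean(camps)),
        n_permutations=len(subsets),
        n_phones=len(per_phone_mapped),
        n_skipped=n_skipped,
        d_min=d_min,
    )


def camp_curve(
    gt,
    per_phone_mapped,
    d_min_values,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> CampCurve:
    """CAMP as a function of the minimum allowed chromaticity separation."""
    points = tuple(
        camp(gt, per_phone_mapped, d, n_permutations=n_permutations, seed=seed)
        for d in d_min_values
    )
    return CampCurve(points=points)


# ---------------------------------------------------------------------------
# Simulator-driven experiment runners


def measure_card_rg(
    scene: SceneModel,
    camera: CameraModel,
    settings: CaptureSettings,
    ambient: IlluminantSPD | None = None,
    roi_margin: int = 6,
) -> tuple[dict[str, tuple[float, float]], dict[str, float]]:
    """Render a pair of a card scene and measure per-patch subtracted rg + SSNR."""
    flash, noflash = render_pair(scene, camera, settings, ambient)
    rgs: dict[str, tuple[float, float]] = {}
    ssnrs: dict[str, float] = {}
    for pid, rect in scene.patch_rois(margin=roi_margin).items():
        roi = rect_mask(flash.shape, rect)
        try:
            m = measure_pair(flash, noflash, roi, roi_id=pid)
        except SubtractionError:
            # Flash failed to dominate this patch (a retake condition in the
            # field); the patch simply contributes no sample here.
            continue
        rgs[pid] = to_rg(m.f_flash_only)
        ssnrs[pid] = m.ssnr
    return rgs, ssnrs


def run_ssnr_threshold_experiment(
    scene: SceneModel,
    camera: CameraModel,
    settings: CaptureSettings,
    ambient: IlluminantSPD,
    ambient_scales,
    n_baseline_sessions: int = 3,
    seed: int = 0,
) -> ThresholdExperimentResult:
    """Full simulated SSNR-threshold determination for one device.

    Repeated zero-ambient captures of the card give the ground-truth rg
    values (first session) and the intrinsic repeatability baseline (all
    sessions). The card is then imaged under the ambient source scaled
    through ``ambient_scales`` at fixed flash exposure; each patch
    contributes an (SSNR, rg distance to ground truth) sample, and the
    threshold is the smallest SSNR above which all samples sit within the
    baseline-plus-one-SD ceiling.
    """
    if n_baseline_sessions < 2:
        raise InsufficientDataError("need at least two zero-ambient sessions")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_baseline_sessions + len(list(ambient_scales)))]

    sessions = []
    for k in range(n_baseline_sessions):
        sess_settings = CaptureSettings(
            settings.exposure_time, settings.iso_scale, True, seeds[k], settings.noise
        )
        rgs, _ = measure_card_rg(scene, camera, sess_settings, ambient=None)
        sessions.append(rgs)
    gt = sessions[0]
    baseline_mean, baseline_plus_sd = intrinsic_baseline(sessions)

    samples = []
    for k, scale in enumerate(ambient_scales):
        sweep_settings = CaptureSettings(
            settings.exposure_time,
            settings.iso_scale,
            True,
            seeds[n_baseline_sessions + k],
            settings.noise,
        )
        rgs, ssnrs = measure_card_rg(scene, camera, sweep_settings, ambient.scaled(scale))
        for pid, rg in rgs.items():
            samples.append(
                ThresholdSample(pid, ssnrs[pid], rg_distance(rg, gt[pid]))
            )
    threshold = find_ssnr_threshold(samples, baseline_plus_sd)
    return ThresholdExperimentResult(
        samples=tuple(samples),
        baseline_mean=baseline_mean,
        baseline_plus_sd=baseline_plus_sd,
        ssnr_threshold=threshold,
    )
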