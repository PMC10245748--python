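"""Steps 2-3 of the pipeline: colocalization counting and noise correction.

A synapse is operationalized as spatial coincidence of a presynaptic and a
postsynaptic punctum on the dendrite: the binary AND of the three masks,
counted as 8-connected components. Because spurious staining produces
random-chance coincidences, the raw count is corrected by subtracting a
noise estimate obtained under a spatial-randomness null, computed by either
of two independent procedures:

* randomization - relocate the puncta objects uniformly over the image and
  re-count (repeated; the mean is the noise estimate);
* spatial cross-correlation - shift the post mask relative to the pre mask
  and read the count profile's asymptote at shifts beyond any true
  pre/post pairing range.

Corrected counts are expressed per 100 um^2 of dendritic area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import count_components, disc_offsets, randomize_mask_objects, stamp_discs
from .puncta import DetectionParams, PunctaSet, detect_puncta, segment_dendrites

#: Shifts (px) at and beyond which true pre/post pairs (centroids < 5 px
#: apart, discs of radius 2) can no longer overlap: twice the punctum
#: diameter. Counts there are chance coincidences only.
MIN_ASYMPTOTE_SHIFT = 10


class DendriteAreaError(ValueError):
    """Raised when the dendrite mask is empty and density is undefined."""


@dataclass
class ColocResult:
    """Noise-corrected synapse count for one image."""

    total_count: int
    noise_estimate: float
    corrected_count: float
    dendritic_area_um2: float
    density_per_100um2: float
    noise_method: str = "randomization"
    replicates: int = 0
    seed: int = 0
    noise_se: float = float("nan")
    negative: bool = False  # corrected_count < 0 (reported, never clamped)
    source_id: str = ""
    crosscorr: "CrossCorrProfile | None" = field(default=None, repr=False)
    noise_estimate_crosscorr: float = float("nan")


@dataclass
class CrossCorrProfile:
    """Colocalization count versus relative mask displacement."""

    shifts_px: np.ndarray
    counts: np.ndarray
    asymptote: float
    asymptote_se: float = float("nan")
    min_asymptote_shift: int = MIN_ASYMPTOTE_SHIFT


def triple_and(pre: np.ndarray, post: np.ndarray, dendrite: np.ndarray) -> np.ndarray:
    """Binary AND of the pre, post and dendrite masks."""
    pre, post, dendrite = (np.asarray(m, dtype=bool) for m in (pre, post, dendrite))
    if not (pre.shape == post.shape == dendrite.shape):
        raise ValueError("mask shapes differ")
    return pre & post & dendrite


def count_colocalizations(coloc_mask: np.ndarray) -> int:
    """Number of 8-connected components in the colocalization mask."""
    return count_components(np.asarray(coloc_mask, dtype=bool))


def randomize_puncta(puncta: PunctaSet, seed: int | np.random.Generator = 0) -> PunctaSet:
    """Complete-spatial-randomness null: same puncta, i.i.d. uniform positions.

    Randomized puncta may overlap each other and may fall off-dendrite;
    the null is uniformity over the full image.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = puncta.image_shape
    n = len(puncta)
    pos = np.stack([rng.integers(0, h, n), rng.integers(0, w, n)], axis=1)
    return PunctaSet(pos, puncta.radius_px, puncta.image_shape)


def randomization_null_counts(
    pre: PunctaSet,
    post: PunctaSet,
    dendrite: np.ndarray,
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Colocalization counts over ``n_reps`` draws of the randomization null."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dendrite = np.asarray(dendrite, dtype=bool)
    counts = np.empty(n_reps, dtype=float)
    for i in range(n_reps):
        pre_mask = randomize_puncta(pre, rng).to_mask()
        post_mask = randomize_puncta(post, rng).to_mask()
        counts[i] = count_colocalizations(triple_and(pre_mask, post_mask, dendrite))
    return counts


def noise_by_randomization(
    pre: PunctaSet,
    post: PunctaSet,
    dendrite: np.ndarray,
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean chance-colocalization count after randomizing both puncta sets."""
    return float(randomization_null_counts(pre, post, dendrite, n_reps, seed).mean())


def mask_randomization_null_counts(
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    dendrite: np.ndarray,
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Randomization null that relocates whole mask objects (shape-preserving).

    Used when the input is already a binary mask and the individual discs
    that formed a merged object are not recoverable.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pre_mask = np.asarray(pre_mask, dtype=bool)
    post_mask = np.asarray(post_mask, dtype=bool)
    dendrite = np.asarray(dendrite, dtype=bool)
    counts = np.empty(n_reps, dtype=float)
    for i in range(n_reps):
        p = randomize_mask_objects(pre_mask, rng)
        q = randomize_mask_objects(post_mask, rng)
        counts[i] = count_colocalizations(triple_and(p, q, dendrite))
    return counts


def estimate_disc_count(mask: np.ndarray, radius_px: int = 2) -> int:
    """Number of discs underlying a binary mask, from its covered area.

    Overlapping discs merge, so the object count under-reports the number
    of puncta. For discs placed at spatially random positions the covered
    area fraction follows the Boolean-model relation
    ``p = 1 - exp(-n * a / N)`` (``a`` = disc area, ``N`` = image pixels),
    which is inverted here to recover ``n``.
    """
    mask = np.asarray(mask, dtype=bool)
    a = len(disc_offsets(radius_px))
    p = mask.mean()
    if p >= 1.0:
        raise ValueError("mask saturates the image; disc count unrecoverable")
    return int(np.rint(-mask.size * np.log1p(-p) / a))


def csr_disc_null_counts(
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    dendrite: np.ndarray,
    radius_px: int = 2,
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Punctum-level randomization null reconstructed from binary masks.

    Estimates the per-channel punctum count from mask area
    (:func:`estimate_disc_count`) and redraws that many discs uniformly at
    random, so the null reproduces the punctum process rather than the
    merged-object process. Used when the input is a binary mask and the
    individual puncta are not directly enumerable.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dendrite = np.asarray(dendrite, dtype=bool)
    h, w = dendrite.shape
    n_pre = estimate_disc_count(pre_mask, radius_px)
    n_post = estimate_disc_count(post_mask, radius_px)
    counts = np.empty(n_reps, dtype=float)
    for i in range(n_reps):
        pre = stamp_discs((h, w), np.stack([rng.integers(0, h, n_pre), rng.integers(0, w, n_pre)], 1), radius_px)
        post = stamp_discs((h, w), np.stack([rng.integers(0, h, n_post), rng.integers(0, w, n_post)], 1), radius_px)
        counts[i] = count_colocalizations(triple_and(pre, post, dendrite))
    return counts


def crosscorr_profile(
    pre: np.ndarray,
    post: np.ndarray,
    dendrite: np.ndarray,
    max_shift_px: int = 50,
    step_px: int = 1,
    min_asymptote_shift: int = MIN_ASYMPTOTE_SHIFT,
) -> CrossCorrProfile:
    """Spatial cross-correlation of the pre and post masks on the dendrite.

    The post mask is translated along rows by 0..max_shift_px (toroidal
    wrap, which conserves the puncta count at every displacement) and the
    AND-mask component count recorded. The asymptote is the mean count over
    shifts >= ``min_asymptote_shift``; its standard error is reported over
    those shifts.
    """
    pre = np.asarray(pre, dtype=bool)
    post = np.asarray(post, dtype=bool)
    dendrite = np.asarray(dendrite, dtype=bool)
    if max_shift_px < min_asymptote_shift:
        raise ValueError("max_shift_px must reach the asymptotic regime")
    if max_shift_px >= pre.shape[0]:
        raise ValueError("shift exceeds image size")
    shifts = np.arange(0, max_shift_px + 1, step_px)
    counts = np.empty(len(shifts), dtype=float)
    for i, d in enumerate(shifts):
        shifted = np.roll(post, int(d), axis=0) if d else post
        counts[i] = count_colocalizations(triple_and(pre, shifted, dendrite))
    tail = counts[shifts >= min_asymptote_shift]
    se = float(tail.std(ddof=1) / np.sqrt(len(tail))) if len(tail) > 1 else float("nan")
    return CrossCorrProfile(shifts, counts, float(tail.mean()), se, min_asymptote_shift)


def corrected_density(
    total: int,
    noise: float,
    dendrite: np.ndarray,
    pixel_size_nm: float,
    **extra,
) -> ColocResult:
    """Noise-corrected count and density per 100 um^2 dendritic area.

    ``corrected = total - noise`` may be negative (pure-noise images); it is
    reported as-is with a flag, never silently clamped, so that averages
    over images stay unbiased.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    dendrite = np.asarray(dendrite, dtype=bool)
    area_px = int(dendrite.sum())
    if area_px == 0:
        raise DendriteAreaError("empty dendrite mask: density undefined, image unusable")
    area_um2 = area_px * (pixel_size_nm / 1000.0) ** 2
    corrected = float(total) - float(noise)
    return ColocResult(
        total_count=int(total),
        noise_estimate=float(noise),
        corrected_count=corrected,
        dendritic_area_um2=area_um2,
        density_per_100um2=corrected / area_um2 * 100.0,
        negative=corrected < 0,
        **extra,
    )


def quantify_masks(
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    *,
    pre_puncta: PunctaSet | None = None,
    post_puncta: PunctaSet | None = None,
    pixel_size_nm: float = 50.0,
    noise_method: str = "randomization",
    n_reps: int = 10,
    seed: int = 0,
    max_shift_px: int = 50,
    source_id: str = "",
    punctum_radius_px: int = 2,
) -> ColocResult:
    """Count colocalizations on the dendrite and apply noise correction.

    When ``pre_puncta``/``post_puncta`` are provided (detection from
    intensity images) the randomization null redraws the detected discs at
    uniform positions; when absent (binary mask input) the punctum count is
    first recovered from mask area (:func:`estimate_disc_count`) and the
    null redraws that many discs. ``noise_method`` is one of
    ``randomization``, ``crosscorr`` or ``both`` (randomization is then the
    primary estimate).
    """
    if noise_method not in ("randomization", "crosscorr", "both"):
        raise ValueError(f"unknown noise_method {noise_method!r}")
    coloc = triple_and(pre_mask, post_mask, dendrite_mask)
    total = count_colocalizations(coloc)

    noise = float("nan")
    noise_se = float("nan")
    replicates = 0
    profile = None
    xc_noise = float("nan")
    if noise_method in ("randomization", "both"):
        if pre_puncta is not None and post_puncta is not None:
            counts = randomization_null_counts(pre_puncta, post_puncta, dendrite_mask, n_reps, seed)
        else:
            counts = csr_disc_null_counts(pre_mask, post_mask, dendrite_mask, punctum_radius_px, n_reps, seed)
        noise = float(counts.mean())
        noise_se = float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else float("nan")
        replicates = n_reps
    if noise_method in ("crosscorr", "both"):
        profile = crosscorr_profile(pre_mask, post_mask, dendrite_mask, max_shift_px)
        xc_noise = profile.asymptote
        if noise_method == "crosscorr":
            noise = xc_noise
            noise_se = profile.asymptote_se

    result = corrected_density(
        total,
        noise,
        dendrite_mask,
        pixel_size_nm,
        noise_method=noise_method,
        replicates=replicates,
        seed=seed,
        noise_se=noise_se,
        source_id=source_id,
    )
    result.crosscorr = profile
    result.noise_estimate_crosscorr = xc_noise
    return result


def _is_binary(image: np.ndarray) -> bool:
    vals = np.unique(np.asarray(image))
    return len(vals) <= 2 and vals.min() >= 0


def quantify_image_set(
    images,
    params: DetectionParams | None = None,
    *,
    noise_method: str = "randomization",
    n_reps: int = 10,
    seed: int = 0,
    max_shift_px: int = 50,
    binary: bool | None = None,
) -> ColocResult:
    """Run the full three-step quantification on an :class:`~synapcount.imgio.ImageSet`.

    Grayscale puncta channels go through the detection chain (background
    subtraction, median filter, percentile threshold, maxima, disc masks).
    Binary channels - e.g. the simulated validation images, which are
    rendered at mask level - are taken as puncta masks directly; set
    ``binary`` explicitly to override the auto-detection.
    """
    params = params or DetectionParams()
    images = images.project()
    pre_img = np.asarray(images.pre)
    post_img = np.asarray(images.post)
    if binary is None:
        binary = _is_binary(pre_img) and _is_binary(post_img)
    dendrite_mask = segment_dendrites(np.asarray(images.dendrite), params.dendrite_dilation_px)
    if binary:
        pre_mask = pre_img > 0
        post_mask = post_img > 0
        pre_puncta = post_puncta = None
    else:
        pre_det = detect_puncta(pre_img, params)
        post_det = detect_puncta(post_img, params)
        pre_mask, post_mask = pre_det.mask, post_det.mask
        pre_puncta, post_puncta = pre_det.puncta, post_det.puncta
    return quantify_masks(
        pre_mask,
        post_mask,
        dendrite_mask,
        pre_puncta=pre_puncta,
        post_puncta=post_puncta,
        pixel_size_nm=images.pixel_size_nm,
        noise_method=noise_method,
        n_reps=n_reps,
        seed=seed,
        max_shift_px=max_shift_px,
        source_id=images.source_id,
    )


__all__ = [
    "ColocResult",
    "CrossCorrProfile",
    "DendriteAreaError",
    "MIN_ASYMPTOTE_SHIFT",
    "triple_and",
    "count_colocalizations",
    "randomize_puncta",
    "randomization_null_counts",
    "noise_by_randomization",
    "mask_randomization_null_counts",
    "estimate_disc_count",
    "csr_disc_null_counts",
    "crosscorr_profile",
    "corrected_density",
    "quantify_masks",
    "quantify_image_set",
]
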