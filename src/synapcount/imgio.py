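"""Image loading, z-projection and quality screening.

Confocal stacks arrive as per-channel grayscale TIFFs (8/12/16-bit, single
or multi plane). The physical pixel size defaults to 50 nm/px, i.e. a
51.2 um x 51.2 um field of view at 1024 x 1024 px. Vendor formats (LIF) are
expected to be exported to TIFF upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

#: Default physical pixel size: 51200 nm field / 1024 px.
DEFAULT_PIXEL_SIZE_NM = 50.0

#: Quality screen: images whose signal-to-noise estimate falls below this
#: value are flagged as unusable (signal indistinguishable from background).
SNR_QUALITY_CUTOFF = 0.5


@dataclass
class ImageSet:
    """One acquisition site: aligned pre/post/dendrite (+ optional nuclei) channels.

    Channels may be 2-D planes or 3-D (plane, row, col) stacks awaiting
    projection; all channels must share the same in-plane geometry.
    """

    pre: np.ndarray
    post: np.ndarray
    dendrite: np.ndarray
    nuclei: np.ndarray | None = None
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        shapes = {np.asarray(ch).shape[-2:] for ch in self.channels().values()}
        if len(shapes) != 1:
            raise ValueError(f"channel dimensions differ: {sorted(shapes)}")

    def channels(self) -> dict[str, np.ndarray]:
        out = {"pre": self.pre, "post": self.post, "dendrite": self.dendrite}
        if self.nuclei is not None:
            out["nuclei"] = self.nuclei
        return out

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.pre).shape[-2:]

    def project(self) -> "ImageSet":
        """Collapse any z-stacks with a maximum-intensity projection."""

        def proj(ch: np.ndarray | None) -> np.ndarray | None:
            if ch is None:
                return None
            ch = np.asarray(ch)
            return max_project(list(ch)) if ch.ndim == 3 else ch

        return replace(
            self,
            pre=proj(self.pre),
            post=proj(self.post),
            dendrite=proj(self.dendrite),
            nuclei=proj(self.nuclei),
        )


@dataclass
class QualityReport:
    snr_estimate: float
    passed: bool
    reason: str = ""


def _read_gray_tiff(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[0]:
        raise ValueError(f"{path}: color (multi-sample) TIFF; grayscale required")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: expected 2-D plane or 3-D stack, got shape {arr.shape}")
    return arr


def load_image_set(
    paths: Mapping[str, str | Path] | Sequence[str | Path],
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    source_id: str | None = None,
) -> ImageSet:
    """Read per-channel TIFFs into an :class:`ImageSet`.

    Parameters
    ----------
    paths
        Mapping with keys ``pre``, ``post``, ``dendrite`` (``nuclei``
        optional), or a sequence in that order. Channel identity is taken
        from the keys/positions; nothing is reordered silently.
    pixel_size_nm
        Physical pixel pitch in nanometres (default 50).
    """
    if not isinstance(paths, Mapping):
        seq = list(paths)
        keys = ["pre", "post", "dendrite", "nuclei"][: len(seq)]
        paths = dict(zip(keys, seq))
    missing = {"pre", "post", "dendrite"} - set(paths)
    if missing:
        raise ValueError(f"missing required channels: {sorted(missing)}")
    arrays = {name: _read_gray_tiff(p) for name, p in paths.items()}
    if source_id is None:
        source_id = Path(paths["pre"]).stem
    return ImageSet(
        pre=arrays["pre"],
        post=arrays["post"],
        dendrite=arrays["dendrite"],
        nuclei=arrays.get("nuclei"),
        pixel_size_nm=pixel_size_nm,
        source_id=source_id,
    )


def max_project(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum over z-planes.

    The cultures are essentially a 2-D monolayer (< 1 um neuropil), so the
    three 0.33-um-stepped planes are collapsed by maximum projection before
    any analysis.
    """
    planes = [np.asarray(p) for p in stack]
    if not planes:
        raise ValueError("empty stack")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share the same shape")
    out = planes[0].copy()
    for p in planes[1:]:
        np.maximum(out, p, out=out)
    return out


def screen_quality(image: np.ndarray) -> QualityReport:
    """Estimate image SNR and flag poor-quality images (SNR < 0.5).

    The estimator splits pixels at the Otsu threshold and reports
    ``(mean(signal) - mean(background)) / std(background)``. It is a
    declared, parameter-free stand-in for an image-level signal/background
    screen: ratio-valued, deterministic, and invariant under positive
    intensity rescaling.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        return QualityReport(0.0, False, "no signal")
    t = threshold_otsu(img)
    above = img > t
    if not above.any() or above.all():
        return QualityReport(0.0, False, "no signal")
    below = ~above
    sd_bg = img[below].std()
    diff = img[above].mean() - img[below].mean()
    snr = float(diff / sd_bg) if sd_bg > 0 else float("inf")
    if snr >= SNR_QUALITY_CUTOFF:
        return QualityReport(snr, True, "")
    return QualityReport(snr, False, f"SNR {snr:.3g} < {SNR_QUALITY_CUTOFF}")
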