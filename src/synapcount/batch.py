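"""Batch orchestration over image grids and group-level statistics.

A batch manifest is a table with one row per acquisition site (the
experimental design samples an 81-location grid per coverslip, 162 images
per synapse type and age). Each entry is loaded, projected, screened
(images with SNR < 0.5 are dropped with a logged reason), quantified and
written as one result row carrying the full parameter set and seed, so a
rerun with the same manifest and seed reproduces the table exactly.
Group differences are assessed with the Wilcoxon rank-sum test with
Bonferroni correction across the requested pairs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import quantify_image_set
from .imgio import load_image_set, screen_quality
from .puncta import DetectionParams

log = logging.getLogger("synapcount.batch")

MANIFEST_REQUIRED = ("source_id", "pre_path", "post_path", "dendrite_path")


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int
    mean_a: float = float("nan")
    sem_a: float = float("nan")
    mean_b: float = float("nan")
    sem_b: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    return validate_manifest(manifest)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_REQUIRED) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.source_id.duplicated().any():
        dupes = manifest.source_id[manifest.source_id.duplicated()].tolist()
        raise ValueError(f"duplicate source_ids in manifest: {dupes}")
    return manifest


def _entry_seed(seed: int, source_id: str) -> int:
    """Per-image seed independent of manifest ordering."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(str(source_id).encode())]).generate_state(1)[0]
        % (2**31)
    )


def run_batch(
    manifest: pd.DataFrame,
    params: DetectionParams | None = None,
    *,
    noise_method: str = "randomization",
    n_reps: int = 10,
    seed: int = 0,
    pixel_size_nm: float = 50.0,
    max_shift_px: int = 50,
) -> pd.DataFrame:
    """Quantify every manifest entry; failures are logged and skipped.

    Returns a table with one row per analyzed image (density in counts per
    100 um^2 dendritic area) plus ``status`` rows for dropped entries.
    """
    params = params or DetectionParams()
    if len(manifest):
        validate_manifest(manifest)
    log.info("batch start: %d entries, params %s", len(manifest), params.to_dict())
    rows = []
    for entry in manifest.itertuples(index=False):
        sid = str(entry.source_id)
        entry_seed = _entry_seed(seed, sid)
        record = dict(
            source_id=sid,
            params_digest=params.digest(),
            seed=entry_seed,
            group=getattr(entry, "group", ""),
            synapse_type=getattr(entry, "synapse_type", ""),
        )
        try:
            paths = dict(pre=entry.pre_path, post=entry.post_path, dendrite=entry.dendrite_path)
            nuclei = getattr(entry, "nuclei_path", None)
            if isinstance(nuclei, str) and nuclei:
                paths["nuclei"] = nuclei
            images = load_image_set(paths, pixel_size_nm=pixel_size_nm, source_id=sid).project()
            quality = min(
                (screen_quality(np.asarray(ch)) for ch in (images.pre, images.post)),
                key=lambda q: q.snr_estimate,
            )
            if not quality.passed:
                log.info("drop %s: %s", sid, quality.reason or "failed quality screen")
                rows.append(dict(record, status="dropped", reason=quality.reason))
                continue
            res = quantify_image_set(
                images,
                params,
                noise_method=noise_method,
                n_reps=n_reps,
                seed=entry_seed,
                max_shift_px=max_shift_px,
            )
            rows.append(
                dict(
                    record,
                    status="ok",
                    reason="",
                    snr_estimate=quality.snr_estimate,
                    total_count=res.total_count,
                    noise_estimate=res.noise_estimate,
                    noise_estimate_crosscorr=res.noise_estimate_crosscorr,
                    corrected_count=res.corrected_count,
                    dendritic_area_um2=res.dendritic_area_um2,
                    density_per_100um2=res.density_per_100um2,
                    negative=res.negative,
                )
            )
            log.info("done %s: density %.2f /100um^2", sid, res.density_per_100um2)
        except Exception as exc:  # per-entry failures never abort the batch
            log.warning("skip %s: %s", sid, exc)
            rows.append(dict(record, status="error", reason=str(exc)))
    columns = [
        "source_id", "group", "synapse_type", "status", "reason", "params_digest", "seed",
        "snr_estimate", "total_count", "noise_estimate", "noise_estimate_crosscorr",
        "corrected_count", "dendritic_area_um2", "density_per_100um2", "negative",
    ]
    out = pd.DataFrame(rows)
    for col in columns:
        if col not in out.columns:
            out[col] = pd.Series(dtype=float)
    dropped = out[out.status != "ok"] if len(out) else out
    for grp, cnt in out[out.status == "ok"].groupby("group").size().items() if len(out) else []:
        log.info("group %s: %d images analyzed", grp, cnt)
    if len(dropped):
        log.info("dropped %d entries: %s", len(dropped), dropped.source_id.tolist())
    return out[columns]


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution for small samples (both n <= 20, no ties),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    exact = len(a) <= 20 and len(b) <= 20 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    results: pd.DataFrame,
    group_col: str,
    pairs: list[tuple[str, str]],
    value_col: str = "density_per_100um2",
) -> list[GroupComparison]:
    """Pairwise rank-sum comparisons with Bonferroni adjustment.

    ``p_adjusted = min(1, p_raw * n_comparisons)``; significance at
    adjusted p < 0.05. Group summaries are mean +/- SEM.
    """
    ok = results[results.status == "ok"] if "status" in results.columns else results
    out = []
    m = len(pairs)
    for ga, gb in pairs:
        a = ok.loc[ok[group_col] == ga, value_col].to_numpy(dtype=float)
        b = ok.loc[ok[group_col] == gb, value_col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group pair ({ga}, {gb}) needs n >= 2 per group")
        statistic, p_raw = rank_sum_test(a, b)
        out.append(
            GroupComparison(
                group_a=str(ga),
                group_b=str(gb),
                statistic=statistic,
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * m),
                n_a=len(a),
                n_b=len(b),
                mean_a=float(a.mean()),
                sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
                mean_b=float(b.mean()),
                sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
            )
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in comparisons])
    if len(df):
        df["significant"] = [c.significant for c in comparisons]
    return df


__all__ = [
    "GroupComparison",
    "read_manifest",
    "validate_manifest",
    "run_batch",
    "rank_sum_test",
    "compare_groups",
    "comparisons_frame",
]
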