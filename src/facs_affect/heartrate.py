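"""R-R artifact filtering, clip-anchored five-minute mean heart rate, and
paired testing.

The artifact filter is a protection-zone rule on instantaneous heart rate
(``HR_i = 60000 / rr_i`` bpm): beat *i* is rejected when it deviates from
the median over the five-beat window centered on it by more than
``max(protection_bpm, rel_threshold * median)``. The pass is repeated on the
surviving intervals until nothing more is rejected, so the filter is
idempotent on its own output. Defaults (6 bpm protection zone, 15% relative
component, 5-beat window) emulate a medium-strength commercial R-R filter;
all three are exposed.

Mean heart rate around a clip is taken over a five-minute window starting
2 min 15 s before the clip and ending 2 min 15 s after it, and is computed
time-weighted — beats per elapsed time in the window — not as a mean of
instantaneous rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events_io import ClipRecord, RRSeries
from .metrics import paired_pvalue
from statsmodels.stats.multitest import multipletests


class CoverageError(ValueError):
    """The recording covers too little of the requested window."""


def holm_adjust(pvals) -> list[float]:
    """Holm step-down adjusted p-values (monotone, order preserved)."""
    return [float(p) for p in multipletests(list(pvals), method="holm")[1]]


@dataclass
class HRWindow:
    """Mean heart rate over one clip-anchored window."""

    session_id: str
    horse_id: str
    condition: str
    window_start: float
    window_end: float
    mean_hr: float
    n_beats: int
    coverage: float


def _reject_pass(
    rr: np.ndarray, protection_bpm: float, rel_threshold: float, window_beats: int
) -> np.ndarray:
    """Boolean keep-mask for one application of the protection-zone rule."""
    hr = 60000.0 / rr
    med = (
        pd.Series(hr)
        .rolling(window_beats, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    zone = np.maximum(protection_bpm, rel_threshold * med)
    return np.abs(hr - med) <= zone


def filter_rr(
    series: RRSeries,
    protection_bpm: float = 6.0,
    rel_threshold: float = 0.15,
    window_beats: int = 5,
    warn_fraction: float = 0.25,
) -> tuple[RRSeries, float]:
    """Remove artifact beats; returns the filtered series and the fraction
    rejected.

    Requires at least five beats. A warning is issued when more than
    ``warn_fraction`` of beats are rejected (poor signal quality).
    """
    if len(series) < 5:
        raise ValueError(f"{series.session_id}: need >=5 beats to filter")
    rr = series.rr.copy()
    while len(rr) >= window_beats:
        keep = _reject_pass(rr, protection_bpm, rel_threshold, window_beats)
        if keep.all():
            break
        rr = rr[keep]
    fraction = 1.0 - len(rr) / len(series.rr)
    if fraction > warn_fraction:
        warnings.warn(
            f"{series.session_id}: {fraction:.0%} of beats rejected — "
            "poor signal quality"
        )
    filtered = RRSeries(
        series.session_id, series.horse_id, series.condition, series.t0, rr
    )
    return filtered, fraction


def window_mean(
    series: RRSeries,
    clip_start: float,
    clip_length: float = 30.0,
    pre_s: float = 135.0,
    post_s: float = 135.0,
    min_coverage: float = 0.5,
) -> HRWindow:
    """Time-weighted mean heart rate over the clip-anchored window.

    The window runs from ``clip_start - pre_s`` to
    ``clip_start + clip_length + post_s`` (300 s with the defaults). A beat
    belongs to the window when its time (end of its interval) falls inside
    it; the mean is ``60 * n_beats / total_interval_seconds``. Raises
    :class:`CoverageError` when the in-window intervals cover less than
    ``min_coverage`` of the window.
    """
    start = clip_start - pre_s
    end = clip_start + clip_length + post_s
    t = series.beat_times
    mask = (t > start) & (t <= end)
    rr_s = series.rr[mask] / 1000.0
    width = end - start
    coverage = rr_s.sum() / width
    if coverage < min_coverage:
        raise CoverageError(
            f"{series.session_id}: window [{start:g}, {end:g}] covered "
            f"{coverage:.0%} < {min_coverage:.0%}"
        )
    n = int(mask.sum())
    mean_hr = 60.0 * n / rr_s.sum()
    return HRWindow(
        series.session_id, series.horse_id, series.condition,
        start, end, mean_hr, n, coverage,
    )


def clip_windows(
    series_list: Sequence[RRSeries],
    clips: Sequence[ClipRecord],
    filter_first: bool = True,
    **filter_kwargs,
) -> pd.DataFrame:
    """Window means for every clip, matching recordings on (horse, condition).

    Clips without a matching recording, or whose window has insufficient
    coverage, are skipped with a warning. Returns one row per scored clip.
    """
    by_key: dict[tuple[str, str], RRSeries] = {}
    for s in series_list:
        by_key[(s.horse_id, s.condition)] = (
            filter_rr(s, **filter_kwargs)[0] if filter_first else s
        )
    rows = []
    for c in clips:
        s = by_key.get((c.horse_id, c.condition))
        if s is None:
            warnings.warn(
                f"no R-R recording for {c.horse_id}/{c.condition}; skipping "
                f"{c.video_id}"
            )
            continue
        try:
            w = window_mean(s, c.clip_start, c.clip_length)
        except CoverageError as exc:
            warnings.warn(str(exc))
            continue
        rows.append(
            {
                "video_id": c.video_id,
                "horse_id": c.horse_id,
                "group": c.group,
                "condition": c.condition,
                "mean_hr": w.mean_hr,
                "n_beats": w.n_beats,
                "coverage": w.coverage,
            }
        )
    return pd.DataFrame(rows)


def hr_tests(windows: pd.DataFrame, test: str = "wilcoxon") -> pd.DataFrame:
    """Paired heart-rate contrasts per study group.

    PRI horses contribute one contrast (transportation vs baseline, raw p);
    UNI horses contribute two (isolation and transportation vs baseline)
    whose p-values are Holm-adjusted as a family. Per-horse means over clips
    are paired within horse.
    """
    per_horse = (
        windows.groupby(["group", "horse_id", "condition"])["mean_hr"]
        .mean()
        .reset_index()
    )
    design = {"PRI": ["transportation"], "UNI": ["isolation", "transportation"]}
    rows = []
    for group, interventions in design.items():
        sub = per_horse[per_horse["group"] == group]
        if sub.empty:
            continue
        wide = sub.pivot(index="horse_id", columns="condition", values="mean_hr")
        raw = []
        for cond in interventions:
            if cond not in wide.columns or "baseline" not in wide.columns:
                continue
            paired = wide[[cond, "baseline"]].dropna()
            if len(paired) < 2:
                raise ValueError(
                    f"{group} {cond}: need >=2 horses with both conditions"
                )
            p = paired_pvalue(paired[cond], paired["baseline"], test)
            raw.append((cond, len(paired), p,
                        paired[cond].mean(), paired["baseline"].mean()))
        if not raw:
            continue
        adjusted = (
            holm_adjust([r[2] for r in raw]) if len(raw) > 1 else [raw[0][2]]
        )
        for (cond, n, p, mi, mb), p_adj in zip(raw, adjusted):
            rows.append(
                {
                    "group": group,
                    "contrast": f"{cond} vs baseline",
                    "n_horses": n,
                    "mean_intervention": mi,
                    "mean_baseline": mb,
                    "p_raw": p,
                    "p_adj": float(p_adj),
                }
            )
    return pd.DataFrame(rows)
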