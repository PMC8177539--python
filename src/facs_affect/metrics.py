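"""Per-clip frequency/duration summaries, paired tests, and inter-rater
agreement.

``summarize`` reduces an event stream to one row per clip and code with the
occurrence count and the maximum single-occurrence duration (the duration
statistic used throughout: maxima are more robust than totals to fragmented
coding of a sustained action). ``paired_tests`` compares per-horse means of
these measures between condition pools with a Wilcoxon signed-rank test.
``wexler_agreement`` is the event-level inter-coder agreement ratio
``2 * N_matched / (N1 + N2)``, matching events of the same code with
temporally overlapping intervals, each event used at most once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from typing import Sequence

import networkx as nx
from scipy import stats

from .events_io import AnnotationEvent, ClipRecord, INTERVENTIONS

MEASURES = ("frequency", "max_duration")


def summarize(
    events: Sequence[AnnotationEvent],
    clips: Sequence[ClipRecord],
    codes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-clip, per-code frequency and maximum duration.

    Every (clip, code) pair over the configured code set is reported; codes
    absent from a clip get frequency 0 and max_duration 0.
    """
    clip_ids = [c.video_id for c in clips]
    if codes is None:
        codes = sorted({e.code for e in events})
    else:
        codes = sorted(codes)
    idx = pd.MultiIndex.from_product([clip_ids, codes], names=["video_id", "code"])
    if events:
        df = pd.DataFrame(
            {
                "video_id": [e.video_id for e in events],
                "code": [e.code for e in events],
                "duration": [e.duration for e in events],
            }
        )
        df = df[df["video_id"].isin(set(clip_ids)) & df["code"].isin(set(codes))]
        grouped = df.groupby(["video_id", "code"])["duration"].agg(["size", "max"])
    else:
        grouped = pd.DataFrame(columns=["size", "max"])
    out = grouped.reindex(idx, fill_value=0).reset_index()
    out.columns = ["video_id", "code", "frequency", "max_duration"]
    out["frequency"] = out["frequency"].astype(int)
    out["max_duration"] = out["max_duration"].astype(float)
    return out


def paired_pvalue(x, y, test: str = "wilcoxon") -> float:
    """Two-sided paired p-value; 1.0 when every difference is zero.

    Wilcoxon drops zero differences and uses the exact null distribution for
    small samples (scipy's ``method='auto'``); ``test='ttest'`` gives the
    paired t alternative.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return 1.0
    if test == "ttest":
        if np.allclose(d, d[0]):
            return 0.0
        return float(stats.ttest_rel(x, y).pvalue)
    d = d[d != 0]
    return float(stats.wilcoxon(d, method="auto").pvalue)


def stars(p: float) -> str:
    """Significance band: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_tests(
    summary: pd.DataFrame,
    clips: Sequence[ClipRecord],
    intervention: Sequence[str] = INTERVENTIONS,
    control: Sequence[str] = ("baseline",),
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-code paired tests on per-horse mean frequency and max duration.

    Each horse contributes its mean over clips within each pool; horses
    lacking either pool are dropped. Returns one row per (code, measure)
    with the p-value and its significance band.
    """
    meta = pd.DataFrame(
        {
            "video_id": [c.video_id for c in clips],
            "horse_id": [c.horse_id for c in clips],
            "condition": [c.condition for c in clips],
        }
    )
    pools = {"intervention": set(intervention), "control": set(control)}
    meta["pool"] = meta["condition"].map(
        lambda c: next((n for n, s in pools.items() if c in s), None)
    )
    df = summary.merge(meta.dropna(subset=["pool"]), on="video_id")
    per_horse = (
        df.groupby(["code", "pool", "horse_id"])[list(MEASURES)].mean().reset_index()
    )
    rows = []
    for code, sub in per_horse.groupby("code"):
        wide = sub.pivot(index="horse_id", columns="pool", values=list(MEASURES))
        wide = wide.dropna()
        if len(wide) < 2:
            raise ValueError(
                f"need >=2 horses with both conditions for code {code}"
            )
        for measure in MEASURES:
            p = paired_pvalue(
                wide[(measure, "intervention")], wide[(measure, "control")], test
            )
            rows.append(
                {
                    "code": code,
                    "measure": measure,
                    "n_horses": len(wide),
                    "p": p,
                    "stars": stars(p),
                }
            )
    return pd.DataFrame(rows)


def wexler_agreement(
    events_a: Sequence[AnnotationEvent],
    events_b: Sequence[AnnotationEvent],
    min_overlap: float = 0.0,
) -> float:
    """Inter-coder agreement ratio ``2 * N_matched / (N1 + N2)`` in [0, 1].

    Two events match when they carry the same code and their intervals
    overlap by at least ``min_overlap`` seconds (with the default 0,
    touching intervals and coinciding point events match). Each event is
    matched at most once; the matched count is the per-code maximum
    bipartite matching, which makes the ratio symmetric in the two coders
    and equal to 1 exactly when a perfect matching of all events exists.

    With no events from either coder the ratio is vacuously 1.
    """
    n1, n2 = len(events_a), len(events_b)
    if n1 + n2 == 0:
        return 1.0
    by_code_a: dict[str, list[AnnotationEvent]] = {}
    by_code_b: dict[str, list[AnnotationEvent]] = {}
    for e in events_a:
        by_code_a.setdefault(e.code, []).append(e)
    for e in events_b:
        by_code_b.setdefault(e.code, []).append(e)
    matched = 0
    for code in set(by_code_a) & set(by_code_b):
        ea, eb = by_code_a[code], by_code_b[code]
        g = nx.Graph()
        left = [("a", i) for i in range(len(ea))]
        g.add_nodes_from(left, bipartite=0)
        g.add_nodes_from((("b", j) for j in range(len(eb))), bipartite=1)
        for i, x in enumerate(ea):
            for j, y in enumerate(eb):
                overlap = min(x.offset, y.offset) - max(x.onset, y.onset)
                if overlap >= min_overlap:
                    g.add_edge(("a", i), ("b", j))
        pairing = nx.bipartite.maximum_matching(g, top_nodes=left)
        matched += len(pairing) // 2
    return 2.0 * matched / (n1 + n2)
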