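"""Windowed co-occurrence graphs and the condition contrast built on them.

For one clip and one observation window size (OWS), a directed weighted
graph over codes records how often an occurrence of code B follows an
occurrence of code A within the window: ``w(A -> B)`` counts ordered
occurrence pairs with ``onset(B) - onset(A)`` in ``[0, ows]`` (simultaneous
onsets count in both directions; self-code pairs are excluded so repetition
of a single code does not masquerade as co-occurrence). Windows are anchored
at event onsets, not on a fixed grid, which avoids grid-phase dependence.

A code's profile in a clip is its degree rate: total in- plus out-weight per
minute of clip. The condition contrast averages profiles per horse and
condition, scores each code by the mean paired difference
(intervention minus control) across horses, and tests it with a paired
t-test; codes with a positive score are "selected", those with p < 0.05
additionally "significant".
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events_io import AnnotationEvent, ClipRecord, INTERVENTIONS

DEFAULT_OWS = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)


def build_graph(
    events: Sequence[AnnotationEvent],
    ows: float,
    clip_id: str | None = None,
    clip_length: float = 30.0,
) -> nx.DiGraph:
    """Build the directed co-occurrence graph of one clip.

    Nodes are the codes observed in the clip; edge weights count ordered
    occurrence pairs whose onset lag lies within the observation window.
    """
    if ows <= 0:
        raise ValueError(f"observation window size must be positive, got {ows}")
    g = nx.DiGraph(ows=float(ows), clip_id=clip_id, clip_length=float(clip_length))
    codes = [e.code for e in events]
    g.add_nodes_from(sorted(set(codes)))
    onsets = np.array([e.onset for e in events], dtype=float)
    n = len(events)
    if n:
        lag = onsets[None, :] - onsets[:, None]  # lag[i, j] = onset_j - onset_i
        ok = (lag >= 0.0) & (lag <= ows)
        np.fill_diagonal(ok, False)
        for i, j in zip(*np.nonzero(ok)):
            a, b = codes[i], codes[j]
            if a == b:
                continue
            w = g.get_edge_data(a, b, default={"weight": 0})["weight"]
            g.add_edge(a, b, weight=w + 1)
    return g


def code_profile(graph: nx.DiGraph) -> dict[str, float]:
    """Per-code co-occurrence degree rate (edge weight per minute of clip)."""
    minutes = graph.graph["clip_length"] / 60.0
    deg = {node: 0.0 for node in graph.nodes}
    for a, b, data in graph.edges(data=True):
        deg[a] += data["weight"]
        deg[b] += data["weight"]
    return {code: w / minutes for code, w in deg.items()}


def contrast(
    events: Sequence[AnnotationEvent],
    clips: Sequence[ClipRecord],
    ows: float,
    intervention: Sequence[str] = INTERVENTIONS,
    control: Sequence[str] = ("baseline",),
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Contrast co-occurrence profiles between two condition pools.

    Horses lacking clips in either pool are dropped with a warning; at least
    two horses with paired data are required. Returns one row per code with
    ``score`` (mean per-horse intervention-minus-control profile), ``p``
    (paired t-test across horses), ``selected`` (score > 0) and
    ``significant`` (selected and p below ``alpha``; Holm-adjusted across
    codes when ``holm`` is set).
    """
    by_video: dict[str, list[AnnotationEvent]] = {}
    for e in events:
        by_video.setdefault(e.video_id, []).append(e)

    pools = {"intervention": set(intervention), "control": set(control)}
    codes = sorted({e.code for e in events})
    # horse -> pool -> list of per-clip profile vectors
    per_horse: dict[str, dict[str, list[np.ndarray]]] = {}
    for c in clips:
        pool = next((n for n, conds in pools.items() if c.condition in conds), None)
        if pool is None:
            continue
        g = build_graph(
            by_video.get(c.video_id, []), ows, clip_id=c.video_id,
            clip_length=c.clip_length,
        )
        prof = code_profile(g)
        vec = np.array([prof.get(code, 0.0) for code in codes])
        per_horse.setdefault(c.horse_id, {"intervention": [], "control": []})[
            pool
        ].append(vec)

    paired = {
        h: d for h, d in per_horse.items() if d["intervention"] and d["control"]
    }
    dropped = sorted(set(per_horse) - set(paired))
    if dropped:
        warnings.warn(
            f"dropping horses without paired clips: {', '.join(dropped)}"
        )
    if len(paired) < 2:
        raise ValueError(
            f"paired t-test needs >=2 horses with both conditions, got {len(paired)}"
        )

    horses = sorted(paired)
    mat_int = np.vstack([np.mean(paired[h]["intervention"], axis=0) for h in horses])
    mat_ctl = np.vstack([np.mean(paired[h]["control"], axis=0) for h in horses])
    diffs = mat_int - mat_ctl
    scores = diffs.mean(axis=0)

    pvals = np.ones(len(codes))
    for k in range(len(codes)):
        d = diffs[:, k]
        if np.allclose(d, d[0]):
            pvals[k] = 1.0 if d[0] == 0 else 0.0
        else:
            pvals[k] = stats.ttest_rel(mat_int[:, k], mat_ctl[:, k]).pvalue
    p_eff = multipletests(pvals, method="holm")[1] if holm else pvals

    out = pd.DataFrame(
        {
            "code": codes,
            "score": scores,
            "p": p_eff,
            "selected": scores > 0,
        }
    )
    out["significant"] = out["selected"] & (out["p"] < alpha)
    out["n_horses"] = len(horses)
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def contrast_table(
    events: Sequence[AnnotationEvent],
    clips: Sequence[ClipRecord],
    ows_list: Sequence[float] = DEFAULT_OWS,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`contrast` for several observation window sizes."""
    frames = []
    for ows in ows_list:
        df = contrast(events, clips, ows, **kwargs)
        df.insert(0, "ows", ows)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
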