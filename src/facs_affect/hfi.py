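"""Frequency-based code selection (the "HFI" method) and occurrence tables.

The human-FACS-derived selection rule keeps the codes that (a) account for
at least 5% of all occurrences in the intervention pool and (b) occur at a
higher per-clip mean frequency during intervention than during control.
Occurrence shares are pooled over clips within each condition pool; the
reported frequency difference is the relative increase of the per-clip mean
frequency, so unbalanced clip numbers between pools do not bias it.

The occurrence denominator includes action descriptors, ear descriptors,
blinks and the composite ear-flicker index; the visibility code VC74 is
excluded upstream. Events are expected post ear-flicker merging
(:func:`facs_affect.fmi.apply_fmi`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events_io import AnnotationEvent, ClipRecord, INTERVENTIONS


@dataclass
class OccurrenceTable:
    """Pooled occurrence counts, shares and per-clip mean frequencies.

    ``table`` is indexed by code with columns ``count_intervention``,
    ``count_control``, ``share_intervention``, ``share_control`` (percent of
    the pool's total occurrences) and ``freq_intervention``,
    ``freq_control`` (occurrences per clip).
    """

    table: pd.DataFrame
    n_clips: dict[str, int]


def occurrence_table(
    events: Sequence[AnnotationEvent],
    clips: Sequence[ClipRecord],
    intervention: Sequence[str] = INTERVENTIONS,
    control: Sequence[str] = ("baseline",),
) -> OccurrenceTable:
    """Tabulate occurrences per code for an intervention and a control pool."""
    pools = {"intervention": set(intervention), "control": set(control)}
    pool_of: dict[str, str] = {}
    n_clips = {name: 0 for name in pools}
    for c in clips:
        for name, conds in pools.items():
            if c.condition in conds:
                pool_of[c.video_id] = name
                n_clips[name] += 1
    for name, n in n_clips.items():
        if n == 0:
            raise ValueError(f"{name} pool contains no clips")

    codes = sorted({e.code for e in events})
    counts = pd.DataFrame(0, index=codes, columns=["intervention", "control"], dtype=int)
    for e in events:
        pool = pool_of.get(e.video_id)
        if pool is not None:
            counts.loc[e.code, pool] += 1

    table = pd.DataFrame(index=counts.index)
    for name in ("intervention", "control"):
        total = counts[name].sum()
        table[f"count_{name}"] = counts[name]
        table[f"share_{name}"] = (
            100.0 * counts[name] / total if total else 0.0
        )
        table[f"freq_{name}"] = counts[name] / n_clips[name]
    return OccurrenceTable(table, n_clips)


def hfi_select(table: OccurrenceTable, threshold: float = 5.0) -> pd.DataFrame:
    """Apply the frequency-based selection rule to an occurrence table.

    Returns the selected codes (share descending) with their shares and the
    relative frequency difference ``100 * (f_int - f_ctl) / f_ctl`` in
    percent (``inf`` when the control frequency is zero).
    """
    t = table.table
    mask = (t["share_intervention"] >= threshold) & (
        t["freq_intervention"] > t["freq_control"]
    )
    sel = t.loc[mask].copy()
    with np.errstate(divide="ignore"):
        sel["freq_difference"] = np.where(
            sel["freq_control"] > 0,
            100.0 * (sel["freq_intervention"] - sel["freq_control"])
            / sel["freq_control"].replace(0, np.nan),
            np.inf,
        )
    sel = sel.sort_values("share_intervention", ascending=False)
    return sel[
        [
            "share_intervention",
            "share_control",
            "freq_intervention",
            "freq_control",
            "freq_difference",
        ]
    ]
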