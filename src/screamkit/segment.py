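"""Scream segmentation and bout/event grouping.

Temporal rules:

* voiced *units* separated by silences of at most 0.03 s belong to the same
  continuous vocal unit;
* gaps between 0.03 s and 0.3 s separate units of the *same* scream
  utterance (the scream spans first-unit onset to last-unit offset);
* silences of at least 0.3 s separate distinct screams;
* bouts are conflict stages with constant caller, social role and severity —
  any change starts a new bout;
* events are separated by at least 30 s without agonism or by a change of
  the interacting partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AudioClip

__all__ = [
    "ScreamSegment",
    "detect_screams",
    "group_bouts",
    "group_events",
    "bout_features",
    "UNIT_GAP",
    "SCREAM_GAP",
    "EVENT_GAP",
]

UNIT_GAP = 0.03  # s: max silence inside one vocal unit
SCREAM_GAP = 0.3  # s: min silence between distinct screams
EVENT_GAP = 30.0  # s: min quiet interval between events


@dataclass
class ScreamSegment:
    """A detected scream: overall extent plus its internal unit boundaries."""

    onset: float
    offset: float
    units: list[tuple[float, float]] = field(default_factory=list)
    caller_id: str | None = None
    bout_id: str | None = None
    event_id: str | None = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(edges[::2], edges[1::2]))


def detect_screams(
    clip: AudioClip,
    threshold_db: float = -25.0,
    min_dur: float = 0.05,
    smooth: float = 0.005,
    unit_gap: float = UNIT_GAP,
    scream_gap: float = SCREAM_GAP,
) -> list[ScreamSegment]:
    """Energy-gate segmentation of screams from a mono clip.

    The amplitude envelope (moving RMS over ``smooth`` seconds) is gated at
    ``threshold_db`` relative to the clip's peak envelope.  Active runs with
    gaps of at most ``unit_gap`` are merged into single units; units closer
    than ``scream_gap`` form one scream utterance; screams shorter than
    ``min_dur`` are dropped.  A silent clip yields an empty list.
    """
    x = clip.samples
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        return []
    rate = clip.rate
    win = max(1, int(round(smooth * rate)))
    kernel = np.ones(win) / win
    env = np.sqrt(np.convolve(x**2, kernel, mode="same"))
    gate = env >= env.max() * 10 ** (threshold_db / 20)

    # close gaps <= unit_gap inside a unit
    max_gap = int(round(unit_gap * rate))
    runs = _runs(gate)
    if not runs:
        return []
    units: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if a - units[-1][1] <= max_gap:
            units[-1][1] = b
        else:
            units.append([a, b])

    # group units into screams: gaps < scream_gap stay within one utterance
    scream_gap_n = int(round(scream_gap * rate))
    screams: list[list[list[int]]] = [[units[0]]]
    for u in units[1:]:
        if u[0] - screams[-1][-1][1] < scream_gap_n:
            screams[-1].append(u)
        else:
            screams.append([u])

    out = []
    for group in screams:
        onset = group[0][0] / rate
        offset = group[-1][1] / rate
        if offset - onset >= min_dur:
            out.append(
                ScreamSegment(onset, offset, units=[(a / rate, b / rate) for a, b in group])
            )
    return out


def group_bouts(table: pd.DataFrame) -> pd.Series:
    """Assign bout ids: a new bout whenever caller, role or severity changes.

    ``table`` needs columns ``event_id, caller_id, role, severity, onset``.
    Rows must be labelled; a missing label raises.  Returns a Series of bout
    ids aligned with ``table``.
    """
    for col in ("event_id", "caller_id", "role", "severity", "onset"):
        if col not in table.columns:
            raise ValueError(f"group_bouts: missing column {col!r}")
        bad = table.index[table[col].isna()]
        if len(bad):
            raise ValueError(f"group_bouts: unlabeled segment at row {bad[0]} (column {col!r})")
    ids = pd.Series(index=table.index, dtype=object)
    counter = 0
    for event_id, grp in table.groupby("event_id", sort=False):
        grp = grp.sort_values("onset")
        prev_key = None
        for idx, row in grp.iterrows():
            key = (row["caller_id"], row["role"], row["severity"])
            if key != prev_key:
                counter += 1
                prev_key = key
            ids.loc[idx] = f"bout{counter:03d}"
    return ids


def group_events(
    bouts: pd.DataFrame,
    gap: float = EVENT_GAP,
) -> pd.Series:
    """Assign event ids to time-ordered bouts.

    ``bouts`` needs ``onset, offset`` and optionally ``partners`` (a
    hashable identifier of the interacting pair).  A new event starts when
    the quiet interval since the previous bout reaches ``gap`` seconds or
    when the partners change.  Returns a Series of event ids.
    """
    for col in ("onset", "offset"):
        if col not in bouts.columns:
            raise ValueError(f"group_events: missing column {col!r}")
    order = bouts.sort_values("onset").index
    ids = pd.Series(index=bouts.index, dtype=object)
    counter = 0
    prev_offset = None
    prev_partners = None
    for idx in order:
        row = bouts.loc[idx]
        partners = row["partners"] if "partners" in bouts.columns else None
        new = (
            prev_offset is None
            or (row["onset"] - prev_offset) >= gap
            or (prev_partners is not None and partners != prev_partners)
        )
        if new:
            counter += 1
        ids.loc[idx] = f"ev{counter:03d}"
        prev_offset = max(prev_offset or -np.inf, row["offset"])
        prev_partners = partners
    return ids


def bout_features(
    segments: list[tuple[float, float]],
    nlp_flags: list[bool] | None = None,
) -> dict:
    """The six bout-level parameters from a bout's scream intervals.

    ``segments`` are (onset, offset) pairs of the bout's screams, one caller.
    Bout duration runs from the first onset to the last offset; the scream
    rate is screams per second of bout duration; ``scream_intervals`` is the
    mean inter-scream silence (NaN for single-scream bouts); ``pct_nlp`` is
    the percentage of screams with at least one non-linear phenomenon.
    """
    if not segments:
        raise ValueError("bout_features: empty bout")
    segs = sorted(segments)
    onsets = np.array([s[0] for s in segs])
    offsets = np.array([s[1] for s in segs])
    if (offsets <= onsets).any():
        raise ValueError("bout_features: segment with offset <= onset")
    n = len(segs)
    bout_duration = offsets[-1] - onsets[0]
    intervals = onsets[1:] - offsets[:-1]
    if nlp_flags is not None and len(nlp_flags) != n:
        raise ValueError("bout_features: nlp_flags length mismatch")
    pct = 100.0 * np.mean(nlp_flags) if nlp_flags is not None else float("nan")
    return {
        "bout_duration": float(bout_duration),
        "n_screams": n,
        "avg_scream_duration": float(np.mean(offsets - onsets)),
        "scream_intervals": float(np.mean(intervals)) if n > 1 else float("nan"),
        "scream_rate": n / bout_duration if bout_duration > 0 else float("nan"),
        "pct_nlp": float(pct),
    }
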