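"""Audio and annotation I/O.

WAV files are read and written through :mod:`scipy.io.wavfile` (PCM 16/24/32
bit and float formats); Praat TextGrids (long format, interval tiers) have a
small dedicated reader/writer.  Annotation tables are plain UTF-8 CSV with a
documented header (see :data:`ANNOTATION_COLUMNS`).

Conventions: times are seconds from clip start, intervals are half-open
``[onset, offset)``; frequencies are Hz; samples are floats in ``[-1, 1]``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioClip",
    "FormatError",
    "ValidationError",
    "ANNOTATION_COLUMNS",
    "read_wav",
    "write_wav",
    "read_annotations",
    "validate_annotations",
    "filter_quality",
    "read_textgrid",
    "write_textgrid",
]

DEFAULT_RATE = 44100

#: Required columns of the annotation CSV dialect.  ``onset``/``offset`` may
#: be empty when segmentation is to be run from audio.
ANNOTATION_COLUMNS = [
    "event_id",
    "bout_id",
    "caller_id",
    "role",
    "severity",
    "context",
    "support",
    "onset",
    "offset",
    "quality",
]

ROLES = ("aggressor", "victim")
SEVERITIES = ("mild", "severe")


class FormatError(ValueError):
    """An input file is not in the expected format."""


class ValidationError(ValueError):
    """An annotation table violates a structural invariant."""


@dataclass
class AudioClip:
    """Mono PCM audio: float samples in ``[-1, 1]`` plus a sample rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise FormatError("AudioClip requires mono (1-D) samples")
        if self.rate <= 0:
            raise FormatError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def time_slice(self, onset: float, offset: float) -> "AudioClip":
        i0 = max(0, int(round(onset * self.rate)))
        i1 = min(len(self.samples), int(round(offset * self.rate)))
        return AudioClip(self.samples[i0:i1], self.rate)


_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): None}


def read_wav(path, target_rate: int | None = None) -> AudioClip:
    """Read a mono WAV file into an :class:`AudioClip`.

    Integer PCM (16/24/32 bit) is normalized to ``[-1, 1]``; 24-bit data
    arrives from scipy as int32 with the payload in the top three bytes, so
    dividing by 2**31 is correct for both depths.  If ``target_rate`` is
    given and differs from the file's rate, the clip is resampled with a
    warning.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on junk input
        raise FormatError(f"{path}: not a readable WAV file ({exc})") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype.kind == "f":
        samples = data.astype(np.float64)
    elif data.dtype == np.dtype("uint8"):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        raise FormatError(f"{path}: unsupported sample format {data.dtype}")
    clip = AudioClip(samples, int(rate))
    if target_rate is not None and clip.rate != target_rate:
        warnings.warn(
            f"{path}: resampling from {clip.rate} Hz to {target_rate} Hz",
            stacklevel=2,
        )
        g = np.gcd(clip.rate, target_rate)
        samples = resample_poly(clip.samples, target_rate // g, clip.rate // g)
        clip = AudioClip(np.clip(samples, -1.0, 1.0), target_rate)
    return clip


def write_wav(clip: AudioClip, path) -> None:
    """Write a clip as 16-bit PCM WAV."""
    if np.max(np.abs(clip.samples), initial=0.0) > 1.0:
        raise FormatError("samples exceed [-1, 1]; rescale before writing")
    pcm = np.round(clip.samples * (2**15 - 1)).astype(np.int16)
    wavfile.write(str(path), clip.rate, pcm)


# ---------------------------------------------------------------------------
# Annotation tables


def read_annotations(path, validate: bool = True) -> pd.DataFrame:
    """Read and (by default) validate an annotation CSV."""
    table = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if validate:
        validate_annotations(table)
    return table


def validate_annotations(table: pd.DataFrame) -> None:
    """Check annotation invariants, reporting offending rows/bouts.

    Raises :class:`ValidationError` when an offset precedes its onset, when a
    label is outside its vocabulary, when a bout spans several events, or when
    social role or conflict severity changes within a bout (a bout is by
    definition a conflict stage with constant role and severity).
    """
    problems: list[str] = []
    has_times = table["onset"].notna() & table["offset"].notna()
    bad = table.index[has_times & (table["offset"].astype(float) <= table["onset"].astype(float))]
    problems += [f"row {i}: offset <= onset" for i in bad]
    bad_role = table.index[~table["role"].isin(ROLES)]
    problems += [f"row {i}: role must be one of {ROLES}" for i in bad_role]
    bad_sev = table.index[~table["severity"].isin(SEVERITIES)]
    problems += [f"row {i}: severity must be one of {SEVERITIES}" for i in bad_sev]
    for bout_id, grp in table.groupby("bout_id"):
        if grp["event_id"].nunique() > 1:
            problems.append(f"bout {bout_id}: spans multiple events")
        for col in ("role", "severity", "caller_id"):
            if grp[col].nunique() > 1:
                problems.append(
                    f"bout {bout_id}: {col} changes within the bout "
                    "(a bout has constant caller, role and severity)"
                )
    if problems:
        raise ValidationError("; ".join(problems))


def filter_quality(table: pd.DataFrame, keep: str = "good") -> pd.DataFrame:
    """Retain only rows whose ``quality`` equals ``keep``.

    The number of excluded rows is reported via :mod:`warnings` when the
    result is empty and always recorded in ``result.attrs['n_excluded']``.
    """
    if "quality" not in table.columns:
        raise ValidationError("annotation table has no 'quality' column")
    kept = table[table["quality"] == keep].copy()
    n_excluded = len(table) - len(kept)
    kept.attrs["n_excluded"] = n_excluded
    if len(kept) == 0 and len(table) > 0:
        warnings.warn("all rows excluded by quality filter", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# Praat TextGrid (long format, interval tiers only)

_TG_NUM = re.compile(r"=\s*([-0-9.eE+]+)")
_TG_STR = re.compile(r'=\s*"(.*)"\s*$')


def read_textgrid(path) -> list[dict]:
    """Parse a long-format Praat TextGrid into labelled intervals.

    Returns one dict per *labelled* interval: ``{"tier", "onset", "offset",
    "label"}``.  Empty-label intervals (silence padding) are skipped.  Point
    tiers are ignored.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text or "TextGrid" not in text:
        raise FormatError(f"{path}: not a Praat TextGrid")
    intervals: list[dict] = []
    tier_name = None
    is_interval_tier = False
    cur: dict = {}
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("class"):
            m = _TG_STR.search(s)
            is_interval_tier = bool(m) and m.group(1) == "IntervalTier"
        elif s.startswith("name"):
            m = _TG_STR.search(s)
            tier_name = m.group(1) if m else None
        elif is_interval_tier and s.startswith("intervals ["):
            cur = {}
        elif is_interval_tier and s.startswith("xmin") and cur is not None:
            cur["onset"] = float(_TG_NUM.search(s).group(1))
        elif is_interval_tier and s.startswith("xmax") and "onset" in cur:
            cur["offset"] = float(_TG_NUM.search(s).group(1))
        elif is_interval_tier and s.startswith("text"):
            m = _TG_STR.search(s)
            label = m.group(1) if m else ""
            if label and "onset" in cur and "offset" in cur:
                intervals.append(
                    {"tier": tier_name, "onset": cur["onset"], "offset": cur["offset"], "label": label}
                )
            cur = {}
    return intervals


def write_textgrid(intervals: list[dict], path, tier: str = "screams", xmax: float | None = None) -> None:
    """Write labelled intervals as a one-tier long-format TextGrid.

    Gaps between labelled intervals are filled with empty-text intervals so
    the tier tiles ``[0, xmax]`` as Praat requires.  Boundaries are written
    with millisecond precision.
    """
    ivs = sorted(intervals, key=lambda d: d["onset"])
    if xmax is None:
        xmax = max((d["offset"] for d in ivs), default=1.0)
    tiled: list[tuple[float, float, str]] = []
    t = 0.0
    for d in ivs:
        if d["onset"] > t:
            tiled.append((t, d["onset"], ""))
        tiled.append((d["onset"], d["offset"], d["label"]))
        t = d["offset"]
    if t < xmax:
        tiled.append((t, xmax, ""))
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.3f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier}"',
        "        xmin = 0",
        f"        xmax = {xmax:.3f}",
        f"        intervals: size = {len(tiled)}",
    ]
    for i, (a, b, label) in enumerate(tiled, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a:.3f}",
            f"            xmax = {b:.3f}",
            f'            text = "{label}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
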