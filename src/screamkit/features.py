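"""Spectro-temporal feature extraction.

The call-level parameter set (nine features per scream) is computed from a
short-time Fourier spectrogram: duration, peak frequency, coefficients of
frequency variation and modulation (sd/mean and mean|Δ|/mean of the
dominant-frequency track), signed frequency transitions at onset and offset,
the 50% energy quartile (Q50), the inter-quartile range (Q75 − Q25) and
normalized Shannon spectral entropy (white noise → 1, pure tone → 0).  Four
non-linear phenomena (frequency jump, sub-harmonics, bi-phonation,
deterministic chaos) are flagged per scream by rule-based detectors.

Default spectral settings: 512-sample FFT, Hann window, 90% overlap at
44.1 kHz (bin spacing ≈ 86.13 Hz, hop 51 samples ≈ 1.16 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import AudioClip

__all__ = [
    "SpectrogramSettings",
    "Spectrogram",
    "NLPSettings",
    "CALL_FEATURES",
    "BOUT_FEATURES",
    "compute_spectrogram",
    "spectral_slice",
    "peak_frequency",
    "frequency_track",
    "modulation_track",
    "coef_variation",
    "coef_modulation",
    "transitions",
    "spectral_quartiles",
    "shannon_entropy",
    "detect_nlp",
    "call_features",
    "extract_all",
]

#: Call-level feature columns (nine parameters).
CALL_FEATURES = [
    "duration",
    "peak_freq",
    "coef_var",
    "coef_mod",
    "trans_onset",
    "trans_offset",
    "q50",
    "iqr",
    "entropy",
]

#: Bout-level feature columns (six parameters).
BOUT_FEATURES = [
    "bout_duration",
    "n_screams",
    "avg_scream_duration",
    "scream_intervals",
    "scream_rate",
    "pct_nlp",
]

#: Dominant-frequency tracking band: DC excluded, 100 Hz .. Nyquist.
TRACK_FMIN = 100.0


@dataclass(frozen=True)
class SpectrogramSettings:
    fft_size: int = 512
    window: str = "hann"
    overlap: float = 0.9
    dynamic_range: float = 40.0  # dB, used for display-style flooring only

    def __post_init__(self) -> None:
        if not (self.fft_size > 0 and (self.fft_size & (self.fft_size - 1)) == 0):
            raise ValueError("fft_size must be a power of two")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be within [0, 1)")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.fft_size * (1.0 - self.overlap))))


@dataclass
class Spectrogram:
    """Linear power spectrogram: ``power[bin, frame]`` plus axes."""

    power: np.ndarray  # (n_bins, n_frames), linear power, >= 0
    times: np.ndarray  # frame centres, s
    freqs: np.ndarray  # bin frequencies, Hz
    settings: SpectrogramSettings

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]

    def crop(self, onset: float, offset: float) -> "Spectrogram":
        """Frames whose centres fall within ``[onset, offset)``."""
        keep = (self.times >= onset) & (self.times < offset)
        if not keep.any():
            raise ValueError(f"no frames within [{onset}, {offset})")
        return Spectrogram(self.power[:, keep], self.times[keep], self.freqs, self.settings)


def compute_spectrogram(clip: AudioClip, settings: SpectrogramSettings | None = None) -> Spectrogram:
    settings = settings or SpectrogramSettings()
    if len(clip.samples) < settings.fft_size:
        raise ValueError(
            f"clip too short for fft_size={settings.fft_size} "
            f"({len(clip.samples)} samples); zero-pad the clip first"
        )
    freqs, times, power = sps.spectrogram(
        clip.samples,
        fs=clip.rate,
        window=settings.window,
        nperseg=settings.fft_size,
        noverlap=settings.fft_size - settings.hop,
        mode="psd",
    )
    return Spectrogram(power, times, freqs, settings)


def spectral_slice(spec: Spectrogram) -> np.ndarray:
    """Per-bin mean power over the frames, normalized to sum to one."""
    m = spec.power.mean(axis=1)
    total = m.sum()
    if total <= 0:
        return m  # all-zero: degenerate, handled by the callers
    return m / total


def peak_frequency(slice_: np.ndarray, freqs: np.ndarray) -> float:
    """Frequency (Hz) of the maximum-power bin; ties go to the lowest bin.

    Returns NaN on an all-zero slice.
    """
    if slice_.sum() <= 0:
        return float("nan")
    return float(freqs[int(np.argmax(slice_))])  # argmax returns the first (lowest) tie


def frequency_track(spec: Spectrogram, fmin: float = TRACK_FMIN, fold_octaves: bool = True) -> np.ndarray:
    """Dominant (argmax) frequency per frame within the analysis band.

    Frames with no energy in the band are interpolated from neighbours.
    With ``fold_octaves`` (default) frames whose argmax lands on the second
    or third harmonic of the call's median dominant frequency are folded
    back down: under heavy broadband noise the per-frame argmax
    occasionally flips to a harmonic, which would otherwise masquerade as
    frequency modulation.
    """
    band = spec.freqs >= fmin
    sub = spec.power[band]
    freqs = spec.freqs[band]
    track = freqs[np.argmax(sub, axis=0)].astype(float)
    empty = sub.sum(axis=0) <= 0
    if empty.all():
        return np.full(spec.n_frames, np.nan)
    if empty.any():
        idx = np.arange(len(track))
        track[empty] = np.interp(idx[empty], idx[~empty], track[~empty])
    if fold_octaves:
        med = np.median(track)
        if med > 0:
            for k in (2.0, 3.0):
                flip = np.abs(track / med - k) < 0.25 * k
                track[flip] /= k
    return track


def modulation_track(spec: Spectrogram, n_steps: int = 20, fmin: float = TRACK_FMIN) -> np.ndarray:
    """Coarse dominant-frequency contour for the modulation coefficients.

    The call is divided into a fixed number of equal time steps (Praat-style
    fixed-count sampling); frames within each step are averaged before the
    argmax, the peak is refined by parabolic interpolation, octave flips are
    folded and the result is median-smoothed.  Two properties matter: at the
    native 90%-overlap frame rate the per-frame argmax jitters with broadband
    noise, which would turn the modulation coefficients into noise meters,
    and a fixed *duration* step would make mean|Δf| scale inversely with call
    length, turning the modulation coefficient into a duration proxy.
    """
    if spec.n_frames < 2:
        return np.full(spec.n_frames, np.nan)
    block = max(1, spec.n_frames // n_steps)
    n = spec.n_frames - (spec.n_frames % block)
    P = spec.power[:, :n].reshape(spec.power.shape[0], n // block, block).mean(axis=2)
    band = spec.freqs >= fmin
    fb = spec.freqs[band]
    Pb = P[band]
    if Pb.sum() <= 0:
        return np.full(Pb.shape[1], np.nan)
    idx = np.argmax(Pb, axis=0)
    track = np.array([_interp_peak(Pb[:, j], int(idx[j]), fb) for j in range(Pb.shape[1])])
    med = np.median(track)
    if med > 0:
        for k in (2.0, 3.0):
            flip = np.abs(track / med - k) < 0.25 * k
            track[flip] /= k
    return _median_smooth(track, 3)


def coef_variation(track: np.ndarray) -> float:
    """sd/mean of the dominant-frequency track (scale-invariant)."""
    track = np.asarray(track, dtype=float)
    if len(track) < 2 or np.isnan(track).any():
        return float("nan")
    return float(np.std(track) / np.mean(track))


def coef_modulation(track: np.ndarray) -> float:
    """mean|Δ|/mean of the dominant-frequency track (scale-invariant)."""
    track = np.asarray(track, dtype=float)
    if len(track) < 2 or np.isnan(track).any():
        return float("nan")
    return float(np.mean(np.abs(np.diff(track))) / np.mean(track))


def transitions(spec: Spectrogram, window_frac: float = 0.2) -> tuple[float, float]:
    """Signed frequency transitions (onset, offset).

    Onset = peak frequency of the central window minus that of the first
    window; offset = last window minus central window.  Windows are the
    first, central and last ``window_frac`` of frames.
    """
    n = spec.n_frames
    if n < 3:
        return float("nan"), float("nan")
    w = max(1, int(round(window_frac * n)))
    mid0 = max(0, (n - w) // 2)

    def peak_of(frames: np.ndarray) -> float:
        return peak_frequency(frames.mean(axis=1), spec.freqs)

    f_begin = peak_of(spec.power[:, :w])
    f_mid = peak_of(spec.power[:, mid0 : mid0 + w])
    f_end = peak_of(spec.power[:, n - w :])
    return f_mid - f_begin, f_end - f_mid


def spectral_quartiles(slice_: np.ndarray, freqs: np.ndarray) -> tuple[float, float, float, float]:
    """Energy quartile frequencies ``(q25, q50, q75, iqr)``.

    Each quartile is the frequency of the first bin at which cumulative
    energy reaches the requested fraction of the total.  Returns NaNs on a
    zero-energy slice.
    """
    total = slice_.sum()
    if total <= 0:
        return (float("nan"),) * 4
    cum = np.cumsum(slice_) / total
    idx = np.searchsorted(cum, [0.25, 0.50, 0.75], side="left")
    q25, q50, q75 = (float(freqs[min(i, len(freqs) - 1)]) for i in idx)
    return q25, q50, q75, q75 - q25


def shannon_entropy(slice_: np.ndarray) -> float:
    """Normalized Shannon entropy of a power spectrum: −Σ p·log p / log N.

    1 for a flat (white-noise) spectrum, 0 for all energy in one bin.
    Returns NaN on a zero-energy slice.
    """
    total = slice_.sum()
    if total <= 0 or len(slice_) < 2:
        return float("nan")
    p = slice_ / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(len(slice_)))


# ---------------------------------------------------------------------------
# Non-linear phenomena detectors


@dataclass(frozen=True)
class NLPSettings:
    """Rule thresholds for the four non-linear-phenomena detectors.

    ``chaos_thresh=None`` selects an adaptive per-call rule (frames whose
    entropy exceeds the call's 25th-percentile frame entropy by
    ``chaos_delta``); a float selects a fixed absolute threshold.
    """

    jump_frac: float = 0.22  # min sustained |Δf|, as fraction of the median track
    jump_sustain: int = 10  # frames of stable level required on each side
    sub_rel_db: float = -10.0  # min level at f/2 relative to the dominant peak
    sub_min_frac: float = 0.4  # fraction of blocks that must show the sub-harmonic
    biph_rel_db: float = -9.0
    biph_min_frac: float = 0.30  # fraction of blocks voting a consistent extra ratio
    harmonic_tol: float = 0.04  # relative tolerance for "harmonically related"
    chaos_thresh: float | None = None
    chaos_delta: float = 0.10
    chaos_min_frac: float = 0.22


def _frame_entropies(power: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of every frame (vectorized)."""
    totals = power.sum(axis=0)
    out = np.full(power.shape[1], np.nan)
    ok = totals > 0
    if ok.any():
        p = power[:, ok] / totals[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        out[ok] = -plogp.sum(axis=0) / np.log(power.shape[0])
    return out


def _median_smooth(x: np.ndarray, k: int = 3) -> np.ndarray:
    if len(x) < k:
        return x
    return sps.medfilt(x, kernel_size=k)


# ratios explainable by a shared fundamental with sub-harmonics up to order 3;
# the half-integer comb of the dominant frequency is excluded separately
_HARMONIC_RATIOS = sorted(
    {Fraction(p, q) for p in range(1, 10) for q in range(1, 4)}, key=float
)


def _harmonically_related(ratio: float, tol: float) -> bool:
    return any(abs(ratio - float(r)) / float(r) <= tol for r in _HARMONIC_RATIOS)


def _interp_peak(col: np.ndarray, idx: int, freqs: np.ndarray) -> float:
    """Parabolic (log-power) refinement of a spectral peak frequency."""
    if idx <= 0 or idx >= len(col) - 1:
        return float(freqs[idx])
    a, b, c = (math.log(max(col[idx + d], 1e-300)) for d in (-1, 0, 1))
    denom = a - 2 * b + c
    if denom >= 0:
        return float(freqs[idx])
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(freqs[idx] + delta * (freqs[1] - freqs[0]))


_ORDER_GRID = np.arange(0.35, 6.0, 0.01)


def _order_spectra(
    spec: Spectrogram, track: np.ndarray, block: int = 5
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """f0-aligned (order) spectra per frame block, plus their mean.

    Each block of ``block`` frames is averaged, then resampled onto the
    ratio axis ``f / f_dom`` of the block.  Returns (per-block spectra
    normalized to unit max, overall mean spectrum, ratio grid).
    """
    n = spec.n_frames
    out = []
    for j0 in range(0, n - block + 1, block):
        p = spec.power[:, j0 : j0 + block].mean(axis=1)
        f_dom = float(np.median(track[j0 : j0 + block]))
        if f_dom <= 0 or p.max() <= 0:
            continue
        # refine the alignment frequency beyond bin resolution
        f_dom = _interp_peak(p, int(np.argmin(np.abs(spec.freqs - f_dom))), spec.freqs)
        o = np.interp(_ORDER_GRID * f_dom, spec.freqs, p, right=0.0)
        m = o.max()
        if m > 0:
            out.append(o / m)
    if not out:
        return [], np.zeros_like(_ORDER_GRID), _ORDER_GRID
    return out, np.mean(out, axis=0), _ORDER_GRID



def detect_nlp(spec: Spectrogram, settings: NLPSettings | None = None) -> dict[str, bool]:
    """Flag the four non-linear phenomena on a per-scream spectrogram.

    All-false on degenerate input (fewer than 3 frames or silent).
    """
    st = settings or NLPSettings()
    flags = {"jump": False, "subharmonic": False, "biphonation": False, "chaos": False}
    if spec.n_frames < 3 or spec.power.sum() <= 0:
        return flags

    track = _median_smooth(frequency_track(spec), 5)
    med = float(np.nanmedian(track))
    if not np.isfinite(med) or med <= 0:
        return flags

    # frequency jump: a sustained step of the dominant frequency, detected on
    # the robust 20-step contour (block averaging suppresses the brief
    # argmax flips heavy noise causes on the frame-rate track).  The
    # threshold has an absolute floor of 2.5 bins so that bin quantization
    # on low-frequency calls cannot register as a jump.
    df = float(spec.freqs[1] - spec.freqs[0])
    coarse = modulation_track(spec)
    k = 3  # contour steps of stable level on each side
    if len(coarse) >= 2 * k and not np.isnan(coarse).any():
        wins = np.median(np.lib.stride_tricks.sliding_window_view(coarse, k), axis=1)
        step = np.abs(wins[k:] - wins[:-k])
        if np.any(step > max(st.jump_frac * med, 2.5 * df)):
            flags["jump"] = True

    # sub-harmonics and bi-phonation are detected on the f0-aligned "order
    # spectrum": every frame block's spectrum is resampled onto a ratio axis
    # f / f_dom(t) before averaging, so frequency drift and jumps leave the
    # harmonic comb at integer ratios and additional voices at their true
    # frequency ratio; simultaneity is inherent in the per-frame alignment.
    blocks, orders, rgrid = _order_spectra(spec, track)
    if len(blocks):
        dom = np.array([b[np.argmin(np.abs(rgrid - 1.0))] for b in blocks])
        subwin = (rgrid > 0.47) & (rgrid < 0.53)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_db = 10.0 * np.log10(
                np.array([b[subwin].max() for b in blocks]) / np.where(dom > 0, dom, np.inf)
            )
        if np.mean(rel_db > st.sub_rel_db) >= st.sub_min_frac:
            flags["subharmonic"] = True

        # a real second voice keeps the same frequency ratio to f0 wherever it
        # is phonating, while noise bumps wander: vote candidate ratios
        # across blocks and require a consistent ratio in enough of them
        votes = np.zeros(len(rgrid))
        # the comb exclusion widens with bin width / f0: a peak closer to a
        # harmonic than the spectrogram can resolve must not count as a
        # second voice
        comb_tol = max(0.06, 1.25 * (spec.freqs[1] - spec.freqs[0]) / med)
        for b in blocks:
            floor = b.max() * 10 ** (st.biph_rel_db / 10)
            peaks, _ = sps.find_peaks(b, height=floor, prominence=0.5 * floor)
            seen = np.zeros(len(rgrid), dtype=bool)
            for pk in peaks:
                r = float(rgrid[pk])
                if min(abs(r - 0.5 * m) for m in range(1, 13)) < comb_tol:
                    continue  # harmonic / sub-harmonic comb
                ratio = r if r >= 1 else 1.0 / r
                if _harmonically_related(ratio, st.harmonic_tol):
                    continue
                lo = max(0, pk - 3)
                seen[lo : pk + 4] = True  # +-0.03 ratio tolerance
            votes += seen
        if votes.max() >= st.biph_min_frac * len(blocks):
            flags["biphonation"] = True

    # chaos: a sustained run of high-entropy frames
    frame_entropy = _frame_entropies(spec.power)
    valid = np.isfinite(frame_entropy)
    if valid.sum() >= 3:
        if st.chaos_thresh is not None:
            high = frame_entropy > st.chaos_thresh
        else:
            base = np.percentile(frame_entropy[valid], 25)
            high = frame_entropy > base + st.chaos_delta
        high &= valid
        frac = high.mean()
        # require a contiguous run of at least 3 high frames
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, high.view(np.int8), 0]) != 0)).max(
            initial=0
        ) if high.any() else 0
        if frac >= st.chaos_min_frac and runs >= 3:
            flags["chaos"] = True

    return flags


# ---------------------------------------------------------------------------
# Whole-dataset extraction


def call_features(
    clip: AudioClip,
    settings: SpectrogramSettings | None = None,
    nlp_settings: NLPSettings | None = None,
    compute_nlp: bool = True,
) -> dict:
    """All nine call-level parameters plus NLP flags for one scream clip.

    ``compute_nlp=False`` skips the non-linear-phenomena detectors (flags
    come back False) for analyses that only need the numeric parameters.
    """
    settings = settings or SpectrogramSettings()
    samples = clip.samples
    if len(samples) < settings.fft_size:
        samples = np.pad(samples, (0, settings.fft_size - len(samples)))
    spec = compute_spectrogram(AudioClip(samples, clip.rate), settings)
    sl = spectral_slice(spec)
    track = modulation_track(spec)
    t_on, t_off = transitions(spec)
    q25, q50, q75, iqr = spectral_quartiles(sl, spec.freqs)
    if compute_nlp:
        flags = detect_nlp(spec, nlp_settings)
    else:
        flags = {"jump": False, "subharmonic": False, "biphonation": False, "chaos": False}
    pf = peak_frequency(sl, spec.freqs)
    return {
        "duration": clip.duration,
        "peak_freq": pf / 1000.0 if np.isfinite(pf) else float("nan"),  # kHz
        "coef_var": coef_variation(track),
        "coef_mod": coef_modulation(track),
        "trans_onset": t_on,
        "trans_offset": t_off,
        "q50": q50,
        "iqr": iqr,
        "entropy": shannon_entropy(sl),
        "nlp_jump": flags["jump"],
        "nlp_subharmonic": flags["subharmonic"],
        "nlp_biphonation": flags["biphonation"],
        "nlp_chaos": flags["chaos"],
        "nlp_any": any(flags.values()),
    }


_META_COLS = [
    "scream_id",
    "event_id",
    "bout_id",
    "caller_id",
    "role",
    "severity",
    "context",
    "context4",
    "support",
    "onset",
    "offset",
]


def extract_all(
    clips: dict[str, AudioClip],
    annotations: pd.DataFrame,
    settings: SpectrogramSettings | None = None,
    nlp_settings: NLPSettings | None = None,
    compute_nlp: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract call- and bout-level feature tables for an annotated dataset.

    ``clips`` maps event ids to event audio; scream intervals come from the
    annotation rows (annotation-trusting mode).  Feature failures yield NaN
    for the affected columns, never dropped rows.  Returns
    ``(call_table, bout_table)``; both carry the annotation labels.
    """
    from .segment import bout_features  # local import to avoid a cycle

    rows = []
    for _, ann in annotations.iterrows():
        meta = {c: ann[c] for c in _META_COLS if c in annotations.columns}
        clip = clips.get(ann["event_id"])
        if clip is None:
            feats = {c: float("nan") for c in CALL_FEATURES}
            feats.update({f"nlp_{k}": False for k in ("jump", "subharmonic", "biphonation", "chaos")})
            feats["nlp_any"] = False
        else:
            scream = clip.time_slice(float(ann["onset"]), float(ann["offset"]))
            feats = call_features(scream, settings, nlp_settings, compute_nlp=compute_nlp)
        rows.append({**meta, **feats})
    call_table = pd.DataFrame(rows)
    if call_table.empty:
        call_table = pd.DataFrame(columns=_META_COLS + CALL_FEATURES + ["nlp_any"])

    bout_rows = []
    if not call_table.empty:
        for bout_id, grp in call_table.groupby("bout_id", sort=True):
            segs = list(zip(grp["onset"].astype(float), grp["offset"].astype(float)))
            bf = bout_features(segs, grp["nlp_any"].astype(bool).tolist())
            meta = {
                c: grp.iloc[0][c]
                for c in ("event_id", "caller_id", "role", "severity", "context", "context4", "support")
                if c in grp.columns
            }
            bout_rows.append({"bout_id": bout_id, **meta, **bf})
    bout_table = pd.DataFrame(bout_rows)
    if bout_table.empty:
        bout_table = pd.DataFrame(columns=["bout_id"] + BOUT_FEATURES)
    return call_table, bout_table
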