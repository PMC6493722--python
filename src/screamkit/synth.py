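"""Synthetic agonistic-scream generator.

The generator is the testing substrate for the whole pipeline: it produces
scream waveforms with known ground truth (caller signature, social role,
conflict severity, injected non-linear phenomena) and whole synthetic studies
whose group contrasts are configured, not estimated.

Synthesis model
---------------
A scream is a harmonic stack (per-harmonic ``1/k`` amplitude roll-off) on a
pseudo-fundamental trajectory ``f0(t) = base_freq + freq_slope * t``, mixed
with broadband noise whose energy share is ``noise_mix``.  By default the
noise is spectrally *matched* to the harmonic-stack envelope (turbulence
passing the same vocal tract as the voiced source), so raising ``noise_mix``
raises spectral entropy without dragging the frequency quartiles; pass
``noise_shape="white"`` for flat noise.  Four non-linear phenomena can be
injected on a mid-call segment: a frequency jump (f0 step), a sub-harmonic
component at f0/2, bi-phonation (an independent second voice), and a
deterministic-chaos stand-in (the segment's tonal part replaced by
full-depth noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AudioClip, DEFAULT_RATE

__all__ = ["ScreamSpec", "StudyConfig", "StudyData", "synth_scream", "simulate_study"]

#: Call-fraction window on which NLP components are active.
NLP_WINDOW = (0.30, 0.80)


@dataclass(frozen=True)
class ScreamSpec:
    """Generative parameters of a single scream."""

    duration: float = 0.3
    base_freq: float = 1500.0
    freq_slope: float = 0.0  # Hz/s
    n_harmonics: int = 5
    noise_mix: float = 0.25  # broadband energy share, 0..1
    noise_shape: str = "matched"  # or "white"
    jump_frac: float | None = None  # f0 step as fraction of base_freq
    subharmonic_db: float | None = None  # level of f0/2 component re fundamental
    biphonation_freq: float | None = None  # Hz, independent second voice
    biphonation_db: float = -6.0
    chaos_frac: float | None = None  # fraction of call replaced by noise
    attack: float = 0.02  # s
    decay: float = 0.05  # s
    amplitude: float = 0.9

    def validate(self, rate: int = DEFAULT_RATE) -> None:
        if self.duration <= 0:
            raise ValueError("invalid ScreamSpec: duration must be > 0")
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("invalid ScreamSpec: noise_mix must be within [0, 1]")
        if not 0.0 < self.base_freq < rate / 2:
            raise ValueError("invalid ScreamSpec: base_freq must lie below Nyquist")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("invalid ScreamSpec: amplitude must be within [0, 1] (no clipping)")
        if self.n_harmonics < 1:
            raise ValueError("invalid ScreamSpec: n_harmonics must be >= 1")
        if self.noise_shape not in ("matched", "white"):
            raise ValueError("invalid ScreamSpec: noise_shape must be 'matched' or 'white'")
        if self.chaos_frac is not None and not 0.0 < self.chaos_frac <= 1.0:
            raise ValueError("invalid ScreamSpec: chaos_frac must be within (0, 1]")
        if self.biphonation_freq is not None and not 0.0 < self.biphonation_freq < rate / 2:
            raise ValueError("invalid ScreamSpec: biphonation_freq must lie below Nyquist")

    @property
    def nlp_flags(self) -> dict[str, bool]:
        return {
            "jump": self.jump_frac is not None,
            "subharmonic": self.subharmonic_db is not None,
            "biphonation": self.biphonation_freq is not None,
            "chaos": self.chaos_frac is not None,
        }

    @property
    def has_nlp(self) -> bool:
        return any(self.nlp_flags.values())


def _harmonic_stack(phase: np.ndarray, f0: np.ndarray, n_harmonics: int, rate: int) -> np.ndarray:
    """Sum of harmonics with 1/k roll-off; harmonics above Nyquist are dropped."""
    out = np.zeros_like(phase)
    for k in range(1, n_harmonics + 1):
        keep = k * f0 < rate / 2
        out += np.where(keep, np.sin(k * phase) / k, 0.0)
    return out


def _matched_noise(n: int, rate: int, base_freq: float, n_harmonics: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to the harmonic-stack envelope.

    The shaping envelope is a sum of Gaussians (sd = 0.35*f0) centred on the
    harmonics with 1/k amplitude weights, so the noise has approximately the
    same frequency-quartile structure as the tonal part while filling the
    space between harmonics.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    env = np.zeros_like(freqs)
    sd = 0.35 * base_freq
    for k in range(1, n_harmonics + 1):
        fk = k * base_freq
        if fk < rate / 2:
            env += np.exp(-0.5 * ((freqs - fk) / sd) ** 2) / k
    shaped = np.fft.irfft(spec * env, n)
    return shaped


def synth_scream(spec: ScreamSpec, rate: int = DEFAULT_RATE, seed: int | np.random.Generator = 0) -> AudioClip:
    """Synthesize one scream.

    The clip has exactly ``round(duration * rate)`` samples; tonal and noise
    components are normalized to unit power before mixing so the broadband
    energy share equals ``noise_mix``; the peak amplitude equals
    ``spec.amplitude``.
    """
    spec.validate(rate)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate

    f0 = spec.base_freq + spec.freq_slope * t
    w0, w1 = (int(NLP_WINDOW[0] * n), int(NLP_WINDOW[1] * n))
    if spec.jump_frac is not None:
        f0 = f0.copy()
        f0[w0:w1] *= 1.0 + spec.jump_frac
    phase = 2 * np.pi * np.cumsum(f0) / rate
    tonal = _harmonic_stack(phase, f0, spec.n_harmonics, rate)

    if spec.subharmonic_db is not None:
        sub = np.sin(phase / 2.0) * 10 ** (spec.subharmonic_db / 20)
        tonal[w0:w1] += sub[w0:w1]
    if spec.biphonation_freq is not None:
        # the second voice keeps a fixed ratio to the (possibly drifting)
        # pseudo-fundamental, as an independent source filtered by the same
        # tract would
        ratio = spec.biphonation_freq / spec.base_freq
        second = np.sin(ratio * phase) * 10 ** (spec.biphonation_db / 20)
        tonal[w0:w1] += second[w0:w1]
    if spec.chaos_frac is not None:
        c0 = int(n * (0.5 - spec.chaos_frac / 2))
        c1 = int(n * (0.5 + spec.chaos_frac / 2))
        burst = rng.standard_normal(c1 - c0)
        rms = np.sqrt(np.mean(tonal**2)) or 1.0
        tonal = tonal.copy()
        tonal[c0:c1] = burst / np.sqrt(np.mean(burst**2)) * rms

    if spec.noise_shape == "white":
        noise = rng.standard_normal(n)
    else:
        noise = _matched_noise(n, rate, spec.base_freq, spec.n_harmonics, rng)

    def _unit_power(x: np.ndarray) -> np.ndarray:
        p = np.sqrt(np.mean(x**2))
        return x / p if p > 0 else x

    y = np.sqrt(1.0 - spec.noise_mix) * _unit_power(tonal) + np.sqrt(spec.noise_mix) * _unit_power(noise)

    # raised-cosine attack/decay envelope
    env = np.ones(n)
    na = min(n, max(1, int(spec.attack * rate)))
    nd = min(n, max(1, int(spec.decay * rate)))
    env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    env[n - nd:] = np.minimum(env[n - nd:], 0.5 * (1 + np.cos(np.pi * np.arange(nd) / nd)))
    y *= env

    peak = np.max(np.abs(y))
    if peak > 0:
        y *= spec.amplitude / peak
    return AudioClip(y, rate)


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a synthetic scream study.

    Defaults reproduce the structure of the field dataset the pipeline is
    designed for: 26 callers, 374 analysable screams in 119 bouts and 95
    events, one recording per event, victim screams longer (factor 1.5) and
    higher-frequency (+200 Hz) than aggressor screams, severe-conflict
    screams noisier (noise_mix +0.2) and given at lower rates (factor 0.6),
    and support probabilities 0.396 (aggressor) vs 0.048 (victim) with a
    severe-conflict odds multiplier of 2.
    """

    n_individuals: int = 26
    n_events: int = 95
    n_bouts: int = 119
    n_screams: int = 374
    rate: int = DEFAULT_RATE
    # caller signatures
    mean_base_freq: float = 1500.0
    between_sd: float = 300.0  # caller-signature spread (Hz)
    within_sd: float = 100.0  # within-caller spread (Hz)
    # durations (log-normal)
    aggressor_duration: float = 0.25  # s, median for aggressors in mild conflicts
    duration_log_sd: float = 0.25
    freq_drift_sd: float = 500.0  # sd of the total per-call frequency drift (Hz)
    victim_duration_factor: float = 1.5
    victim_q50_shift: float = 200.0  # Hz added to victim base_freq
    # severity effects
    noise_mix_mild: float = 0.25
    severe_entropy_shift: float = 0.20  # noise_mix increment for severe conflicts
    noise_mix_jitter: float = 0.03
    mild_nlp_prob: float = 0.15
    severe_nlp_prob: float = 0.45
    severe_rate_factor: float = 0.6  # scream-rate ratio severe/mild
    # NLP injection strengths
    jump_frac: float = 0.35
    subharmonic_db: float = -6.0
    biphonation_ratio: float = 1.78  # second voice at ratio * base_freq
    chaos_frac: float = 0.30
    # temporal structure
    mean_interval: float = 0.5  # s between screams in a bout
    interval_sd: float = 0.15
    min_interval: float = 0.3
    bout_gap: float = 2.0  # s between bouts of the same event
    # support
    support_prob_aggressor: float = 0.396
    support_prob_victim: float = 0.048
    support_prob_severe_multiplier: float = 2.0  # odds multiplier
    support_caller_sd: float = 0.3  # caller random effect on the support logit
    # misc
    p_severe: float = 0.4
    p_victim: float = 0.5
    caller_activity_sd: float = 1.0  # lognormal spread of per-caller event counts
    context_labels: tuple[str, ...] = (
        "observation_feeding",
        "observation_other",
        "experiment_food",
        "experiment_other",
    )
    context_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    poor_quality_fraction: float = 0.0
    n_harmonics: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "support_prob_aggressor",
            "support_prob_victim",
            "p_severe",
            "p_victim",
            "mild_nlp_prob",
            "severe_nlp_prob",
            "poor_quality_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid StudyConfig: {name} must be within [0, 1]")
        if min(self.n_individuals, self.n_events, self.n_bouts) < 1:
            raise ValueError("invalid StudyConfig: counts must be >= 1")
        if self.n_bouts < self.n_events:
            raise ValueError("invalid StudyConfig: need at least one bout per event")
        if self.n_screams != 0 and self.n_screams < self.n_bouts:
            raise ValueError("invalid StudyConfig: need at least one scream per bout")
        if not 0.0 <= self.noise_mix_mild + self.severe_entropy_shift <= 1.0:
            raise ValueError("invalid StudyConfig: severe noise_mix exceeds [0, 1]")


@dataclass
class StudyData:
    """A simulated study: per-event audio, annotations and ground truth."""

    clips: dict[str, AudioClip]  # event_id -> audio (empty if not rendered)
    annotations: pd.DataFrame
    ground_truth: pd.DataFrame
    config: StudyConfig


def _allocate(total: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly allocate ``total`` items over ``n_groups``, each >= 1."""
    extra = rng.multinomial(total - n_groups, np.full(n_groups, 1.0 / n_groups))
    return extra + 1


def simulate_study(config: StudyConfig | None = None, render_audio: bool = True) -> StudyData:
    """Generate a full annotated synthetic study.

    The realized dataset has exactly the configured number of screams, bouts,
    events and callers.  Within an event, consecutive bouts change either the
    social role of the (same) signaller or the conflict severity, so the
    bout-definition rule is genuinely exercised.  With ``render_audio=False``
    only the annotation and ground-truth tables are produced (timing fields
    are still populated), which is enough for the bout-level support model.
    """
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_screams == 0:
        import warnings

        warnings.warn("zero screams requested: returning empty dataset")
        empty = pd.DataFrame()
        return StudyData({}, empty, empty, config)

    callers = [f"ind{i:02d}" for i in range(config.n_individuals)]
    signatures = {
        c: config.mean_base_freq + config.between_sd * rng.standard_normal() for c in callers
    }
    support_re = {c: config.support_caller_sd * rng.standard_normal() for c in callers}

    bouts_per_event = _allocate(config.n_bouts, config.n_events, rng)
    screams_per_bout = _allocate(config.n_screams, config.n_bouts, rng)

    # focal caller per event: every caller appears at least once (when there
    # are enough events); remaining events go to callers with lognormal
    # activity weights, mirroring the strongly unequal per-individual call
    # counts of field recordings
    order = list(callers)
    rng.shuffle(order)
    focal = order[: config.n_events]
    if config.n_events > len(order):
        w = np.exp(config.caller_activity_sd * rng.standard_normal(len(callers)))
        w /= w.sum()
        extra = rng.choice(callers, size=config.n_events - len(order), p=w)
        focal = focal + list(extra)
    rng.shuffle(focal)

    ann_rows: list[dict] = []
    gt_rows: list[dict] = []
    clips: dict[str, AudioClip] = {}
    bout_counter = 0
    scream_counter = 0

    for e in range(config.n_events):
        event_id = f"ev{e:03d}"
        caller = focal[e]
        opponent = callers[rng.integers(len(callers) - 1)]
        if opponent == caller:
            opponent = callers[-1] if caller != callers[-1] else callers[0]
        context4 = config.context_labels[
            rng.choice(len(config.context_labels), p=np.asarray(config.context_probs))
        ]
        context = "observation" if context4.startswith("observation") else "experiment"
        role = "victim" if rng.random() < config.p_victim else "aggressor"
        severity = "severe" if rng.random() < config.p_severe else "mild"

        pieces: list[np.ndarray] = []
        t_cursor = 0.2  # lead-in silence
        n_bouts_here = bouts_per_event[e]
        for b in range(n_bouts_here):
            bout_id = f"bout{bout_counter:03d}"
            n_here = screams_per_bout[bout_counter]
            bout_counter += 1
            if b > 0:
                # a new bout within an event requires a role or severity change
                if rng.random() < 0.6:
                    role = "victim" if role == "aggressor" else "aggressor"
                else:
                    severity = "severe" if severity == "mild" else "mild"
                t_cursor += config.bout_gap + rng.random() * 0.5

            noise_mix = config.noise_mix_mild + (
                config.severe_entropy_shift if severity == "severe" else 0.0
            )
            nlp_prob = config.severe_nlp_prob if severity == "severe" else config.mild_nlp_prob
            rate_factor = config.severe_rate_factor if severity == "severe" else 1.0

            # support drawn once per bout on the logit scale
            base_p = (
                config.support_prob_aggressor if role == "aggressor" else config.support_prob_victim
            )
            logit = math.log(base_p / (1 - base_p)) + support_re[caller]
            if severity == "severe":
                logit += math.log(config.support_prob_severe_multiplier)
            support = "yes" if rng.random() < 1.0 / (1.0 + math.exp(-logit)) else "no"

            for _ in range(n_here):
                base = signatures[caller] + config.within_sd * rng.standard_normal()
                if role == "victim":
                    base += config.victim_q50_shift
                base = float(np.clip(base, 400.0, 3500.0))
                dur = config.aggressor_duration * math.exp(
                    config.duration_log_sd * rng.standard_normal()
                )
                if role == "victim":
                    dur *= config.victim_duration_factor
                nm = float(np.clip(noise_mix + config.noise_mix_jitter * rng.standard_normal(), 0.02, 0.95))
                # drift is drawn as a total per-call excursion so that scream
                # length does not mechanically change the spectral smear
                drift = rng.normal(0.0, config.freq_drift_sd)
                spec = ScreamSpec(
                    duration=dur,
                    base_freq=base,
                    freq_slope=float(drift / dur),
                    n_harmonics=config.n_harmonics,
                    noise_mix=nm,
                )
                if rng.random() < nlp_prob:
                    kind = ("jump", "subharmonic", "biphonation", "chaos")[rng.integers(4)]
                    if kind == "jump":
                        spec = replace(spec, jump_frac=config.jump_frac)
                    elif kind == "subharmonic":
                        spec = replace(spec, subharmonic_db=config.subharmonic_db)
                    elif kind == "biphonation":
                        spec = replace(spec, biphonation_freq=config.biphonation_ratio * base)
                    else:
                        spec = replace(spec, chaos_frac=config.chaos_frac)

                onset = t_cursor
                offset = onset + spec.duration
                scream_id = f"scr{scream_counter:04d}"
                scream_counter += 1
                quality = "poor" if rng.random() < config.poor_quality_fraction else "good"
                ann_rows.append(
                    {
                        "scream_id": scream_id,
                        "event_id": event_id,
                        "bout_id": bout_id,
                        "caller_id": caller,
                        "opponent_id": opponent,
                        "role": role,
                        "severity": severity,
                        "context": context,
                        "context4": context4,
                        "support": support,
                        "onset": round(onset, 6),
                        "offset": round(offset, 6),
                        "quality": quality,
                    }
                )
                gt_rows.append(
                    {
                        "scream_id": scream_id,
                        "event_id": event_id,
                        "bout_id": bout_id,
                        "caller_id": caller,
                        "role": role,
                        "severity": severity,
                        "support": support,
                        "duration": spec.duration,
                        "base_freq": spec.base_freq,
                        "freq_slope": spec.freq_slope,
                        "noise_mix": spec.noise_mix,
                        "nlp_jump": spec.nlp_flags["jump"],
                        "nlp_subharmonic": spec.nlp_flags["subharmonic"],
                        "nlp_biphonation": spec.nlp_flags["biphonation"],
                        "nlp_chaos": spec.nlp_flags["chaos"],
                        "nlp_any": spec.has_nlp,
                    }
                )
                if render_audio:
                    clip = synth_scream(spec, config.rate, rng)
                    pieces.append((onset, clip.samples))
                gap = max(
                    config.min_interval,
                    rng.normal(config.mean_interval / rate_factor, config.interval_sd),
                )
                t_cursor = offset + gap

        if render_audio:
            total = int(round((t_cursor + 0.2) * config.rate))
            buf = np.zeros(total)
            for onset, samples in pieces:
                i0 = int(round(onset * config.rate))
                buf[i0 : i0 + len(samples)] += samples
            peak = np.max(np.abs(buf))
            if peak > 1.0:
                buf /= peak * 1.01
            clips[event_id] = AudioClip(buf, config.rate)

    annotations = pd.DataFrame(ann_rows)
    ground_truth = pd.DataFrame(gt_rows)
    return StudyData(clips, annotations, ground_truth, config)
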