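"""Synthetic multi-subject, multi-rate, multi-montage EEG generation.

Emulates the heterogeneity the harmonization stage must absorb — sampling
rates from 100 to 2048 Hz, montages ranging from two electrodes to 10/20
supersets with auxiliary channels, per-subject amplitude scales — together
with temporal structure the contrastive task can learn: band-limited
oscillations whose amplitudes are modulated by smooth random envelopes on a
1-5 s timescale (slow enough to be predictive at the ~2.67 Hz BENDR rate),
on top of 1/f background noise synthesized in the frequency domain.

For downstream tests, labeled trials embed a class effect — by default a
lateralized band-power difference (e.g., 10 Hz stronger over C3 than C4 in
one class and reversed in the other), the synthetic stand-in for
sensorimotor-rhythm structure.  An oracle band-power-ratio classifier
bounds what any pipeline can recover; a null effect (size 1) must score at
chance, guarding against label leakage.

No physiological forward-model realism is attempted: topographies are plain
spatial gain vectors over the 19 canonical electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .harmonization import (CANONICAL_19, RawRecording, write_text_recording)

__all__ = [
    "Oscillation",
    "SynthConfig",
    "ClassEffect",
    "generate_recording",
    "generate_labeled_trials",
    "generate_corpus",
    "bandpower_ratio_classify",
]

_RATE_POOL = (100.0, 160.0, 250.0, 256.0, 2048.0)

#: Montage variants drawn per subject: the full canonical set, a
#: two-electrode sleep-style pair, and a superset with auxiliary channels.
_MONTAGES = {
    "full19": list(CANONICAL_19),
    "pair": ["Fpz-Cz", "Pz-Oz"],
    "superset": list(CANONICAL_19) + ["A1", "A2", "EOG1", "EOG2", "ECG"],
}


@dataclass(frozen=True)
class Oscillation:
    center_hz: float
    bandwidth_hz: float
    amplitude: float = 1.0
    #: per-canonical-electrode gain (length 19); None = uniform
    topography: tuple[float, ...] | None = None
    #: AM envelope timescale bounds in seconds
    envelope_s: tuple[float, float] = (1.0, 5.0)


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 4
    duration_s: float = 120.0
    sfreq_pool: tuple[float, ...] = _RATE_POOL
    montage_pool: tuple[str, ...] = ("full19", "pair", "superset")
    oscillations: tuple[Oscillation, ...] = (
        Oscillation(10.0, 2.0, amplitude=3.0),
        Oscillation(4.0, 1.0, amplitude=2.0),
        Oscillation(20.0, 4.0, amplitude=1.0),
    )
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    amplitude_scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0


@dataclass(frozen=True)
class ClassEffect:
    """A detectable class-conditional signal difference."""

    label: str = "lateralized"
    kind: str = "lateralized-band-power"  # | 'spectral-shift' | 'evoked'
    center_hz: float = 10.0
    #: band-power ratio between the favored and suppressed electrode
    effect_size: float = 3.0
    electrodes: tuple[str, str] = ("C3", "C4")


def _pink_noise(n_ch: int, n_samp: int, sfreq: float, exponent: float,
                scale: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, random phases in the frequency domain."""
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sfreq)
    mag = np.zeros_like(freqs)
    mag[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, freqs.size))
    spec = mag * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return scale * x / np.maximum(rms, 1e-30)


def _smooth_envelope(n_samp: int, sfreq: float, timescale_s: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Positive slowly varying AM envelope (low-passed noise, unit mean)."""
    t_env = rng.uniform(*timescale_s)
    cutoff = 1.0 / t_env
    raw = rng.normal(size=n_samp)
    sos = signal.butter(2, min(cutoff, 0.45 * sfreq), fs=sfreq, output="sos")
    env = signal.sosfiltfilt(sos, raw)
    env = env - env.min()
    mean = env.mean()
    return env / mean if mean > 0 else np.ones(n_samp)


def _band_osc(n_samp: int, sfreq: float, center: float, bw: float,
              rng: np.random.Generator) -> np.ndarray:
    """Narrow-band oscillation: band-pass-filtered white noise, unit RMS."""
    lo = max(center - bw / 2.0, 0.1)
    hi = min(center + bw / 2.0, 0.49 * sfreq)
    x = rng.normal(size=n_samp)
    sos = signal.butter(4, [lo, hi], btype="band", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-30)


def _subject_draws(cfg: SynthConfig, subject: int):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject]))
    sfreq = cfg.sfreq_pool[rng.integers(len(cfg.sfreq_pool))]
    montage = cfg.montage_pool[subject % len(cfg.montage_pool)]
    amp = rng.uniform(*cfg.amplitude_scale_range)
    return rng, sfreq, montage, amp


def _electrode_gains(ch_names: list[str],
                     topography: tuple[float, ...] | None,
                     rng: np.random.Generator) -> np.ndarray:
    canon = {name.upper(): i for i, name in enumerate(CANONICAL_19)}
    gains = np.empty(len(ch_names))
    base = (np.asarray(topography, dtype=float) if topography is not None
            else np.ones(len(CANONICAL_19)))
    for j, name in enumerate(ch_names):
        key = name.split("-", 1)[0].strip().upper()
        idx = canon.get({"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8",
                         "FPZ": "FP1", "OZ": "O1"}.get(key, key))
        gains[j] = base[idx] if idx is not None else 0.2 * rng.random()
    return gains


def generate_recording(cfg: SynthConfig, subject: int = 0,
                       amplitude_scale: float | None = None) -> RawRecording:
    """One subject's recording: modulated oscillations + 1/f noise.

    Deterministic under (cfg.seed, subject); sampling rate, montage and
    per-subject amplitude scale are drawn from the configured pools.
    """
    rng, sfreq, montage, amp = _subject_draws(cfg, subject)
    if amplitude_scale is not None:
        amp = amplitude_scale
    ch_names = list(_MONTAGES[montage])
    n_samp = int(round(cfg.duration_s * sfreq))
    data = _pink_noise(len(ch_names), n_samp, sfreq, cfg.noise_exponent,
                       cfg.noise_scale, rng)
    for osc in cfg.oscillations:
        if osc.center_hz >= 0.5 * sfreq:
            continue
        carrier = _band_osc(n_samp, sfreq, osc.center_hz, osc.bandwidth_hz, rng)
        env = _smooth_envelope(n_samp, sfreq, osc.envelope_s, rng)
        gains = _electrode_gains(ch_names, osc.topography, rng)
        data += osc.amplitude * gains[:, None] * (carrier * env)[None, :]
    data *= amp
    return RawRecording(data=data, sfreq=sfreq, ch_names=ch_names,
                        subject_id=f"S{subject:03d}", dataset_id="synthetic")


def _lateralized_topography(effect: ClassEffect, side: int) -> np.ndarray:
    """Gain vector boosting one electrode and suppressing the other."""
    gains = np.full(len(CANONICAL_19), 0.3)
    i_a = CANONICAL_19.index(effect.electrodes[0])
    i_b = CANONICAL_19.index(effect.electrodes[1])
    hi, lo = (i_a, i_b) if side == 0 else (i_b, i_a)
    gains[hi] = effect.effect_size
    gains[lo] = 1.0
    return gains


def generate_labeled_trials(cfg: SynthConfig, effect: ClassEffect,
                            n_per_class: dict[str, int] | int,
                            trial_s: float = 3.0, seed: int = 0,
                            sfreq: float = 256.0,
                            n_subjects: int | None = None
                            ) -> list[tuple[RawRecording, str, str]]:
    """Balanced (or explicitly imbalanced) labeled trials embedding the effect.

    Returns (recording, label, subject_id) triples; the null effect
    (effect_size == 1) embeds no class information.
    """
    if isinstance(n_per_class, int):
        n_per_class = {"left": n_per_class, "right": n_per_class}
    labels = sorted(n_per_class)
    n_subj = n_subjects or cfg.n_subjects
    rng = np.random.default_rng(seed)
    ch_names = list(CANONICAL_19)
    n_samp = int(round(trial_s * sfreq))
    out = []
    for side, label in enumerate(labels):
        gains = _lateralized_topography(effect, side)
        for k in range(n_per_class[label]):
            subj = (len(out)) % n_subj
            data = _pink_noise(len(ch_names), n_samp, sfreq,
                               cfg.noise_exponent, cfg.noise_scale, rng)
            carrier = _band_osc(n_samp, sfreq, effect.center_hz, 2.0, rng)
            env = _smooth_envelope(n_samp, sfreq, (0.5, 2.0), rng)
            data += 1.5 * gains[:, None] * (carrier * env)[None, :]
            # task-independent background rhythm on all channels
            theta = _band_osc(n_samp, sfreq, 4.0, 1.0, rng)
            data += 0.8 * theta[None, :]
            rec = RawRecording(data=data, sfreq=sfreq, ch_names=ch_names,
                               subject_id=f"S{subj:03d}",
                               dataset_id="synthetic-trials")
            out.append((rec, label, rec.subject_id))
    return out


def bandpower_ratio_classify(trials, effect: ClassEffect) -> np.ndarray:
    """Oracle classifier: sign of log band-power ratio at the two electrodes.

    Returns predicted labels (sorted label order) for (rec, label, subj)
    triples; used as an independent detectability bound for the class effect.
    """
    labels = sorted({lab for _, lab, _ in trials})
    preds = []
    for rec, _, _ in trials:
        i_a = rec.ch_names.index(effect.electrodes[0])
        i_b = rec.ch_names.index(effect.electrodes[1])
        f, pa = signal.periodogram(rec.data[i_a], fs=rec.sfreq)
        _, pb = signal.periodogram(rec.data[i_b], fs=rec.sfreq)
        band = (f >= effect.center_hz - 2) & (f <= effect.center_hz + 2)
        ratio = pa[band].sum() / max(pb[band].sum(), 1e-30)
        preds.append(labels[0] if ratio > 1 else labels[1])
    return np.asarray(preds)


def long_context_config(cfg: SynthConfig) -> SynthConfig:
    """Variant whose envelopes vary on 10-60 s timescales, so signal content
    at lags beyond 20 s is informative for the contrastive task."""
    return replace(cfg, oscillations=(
        Oscillation(10.0, 2.0, amplitude=3.0, envelope_s=(20.0, 60.0)),
        Oscillation(4.0, 1.0, amplitude=2.0, envelope_s=(10.0, 30.0)),
        Oscillation(20.0, 4.0, amplitude=1.0, envelope_s=(2.0, 8.0)),
    ))


def generate_corpus(cfg: SynthConfig, out_dir,
                    n_trials_per_class: int = 4,
                    trial_s: float = 3.0) -> Path:
    """Write the full fixture set with a JSON manifest.

    Three sections, all in the delimited-text format readable by the
    harmonization stage: the mixed-rate mixed-montage pre-training corpus
    (``recordings``), a long-context corpus with slow envelope structure
    (``long_context``), and labeled downstream trials (``trials``).
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def write_subjects(config: SynthConfig, subdir: str) -> list[dict]:
        (out_dir / subdir).mkdir(exist_ok=True) if subdir else None
        entries = []
        for subject in range(config.n_subjects):
            rec = generate_recording(config, subject)
            fname = f"{subdir}{'/' if subdir else ''}subject_{subject:03d}.txt"
            write_text_recording(out_dir / fname, rec)
            entries.append({"file": fname, "subject_id": rec.subject_id,
                            "sfreq": rec.sfreq, "channels": rec.ch_names,
                            "duration_s": rec.duration_s})
        return entries

    recordings = write_subjects(cfg, "")
    long_ctx = write_subjects(
        replace(long_context_config(cfg), seed=cfg.seed + 1), "long_context")

    (out_dir / "trials").mkdir(exist_ok=True)
    trial_entries = []
    trials = generate_labeled_trials(cfg, ClassEffect(), n_trials_per_class,
                                     trial_s=trial_s, seed=cfg.seed + 2)
    for i, (rec, label, subject) in enumerate(trials):
        fname = f"trials/trial_{i:03d}.txt"
        write_text_recording(out_dir / fname, rec)
        trial_entries.append({"file": fname, "label": label,
                              "subject_id": subject, "sfreq": rec.sfreq})

    manifest = {"seed": cfg.seed, "n_subjects": cfg.n_subjects,
                "recordings": recordings, "long_context": long_ctx,
                "trials": trial_entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
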