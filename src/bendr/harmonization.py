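"""Harmonize heterogeneous raw EEG into a canonical 20 x T, 256 Hz representation.

Raw recordings arrive with arbitrary sampling rates (100-2048 Hz), arbitrary
channel montages and arbitrary amplitude scales.  Every recording is mapped to
a fixed representation:

* 19 rows for the electrodes of the reduced 10/20 set, in a fixed order;
  channels absent from the source montage are zero, surplus channels dropped;
* each sequence linearly rescaled (one weight and offset across all channels)
  so its extremes are exactly -1 and +1;
* a 20th constant row carrying the sequence's amplitude range relative to the
  full dataset range, restoring the scale information lost to normalization;
* resampled to 256 Hz by an integer up/down step to the whole multiple (or
  divisor) of the source rate nearest the target, then nearest-neighbor
  interpolation to the exact rate, with an anti-alias low-pass below 120 Hz
  applied first when source content exceeds the target Nyquist.

Pre-training consumes non-overlapping 60 s windows (15,360 samples); labeled
downstream tasks consume per-event trials cropped at a fixed offset/length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

TARGET_SFREQ = 256.0
ANTIALIAS_CUTOFF_HZ = 120.0
PRETRAIN_WINDOW_S = 60.0

#: The 19 electrodes of the reduced 10/20 montage, fixed canonical order
#: (modern T7/T8/P7/P8 naming); row 19 is the relative-amplitude constant.
CANONICAL_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)
N_CHANNELS = 20  # 19 electrodes + amplitude row

#: Legacy/synonym electrode names (upper-cased keys), including the older
#: temporal-chain labels and midline fallbacks used by two-electrode
#: sleep montages (Fpz has no dedicated row; it lands on the nearest
#: canonical frontal-pole electrode).
CHANNEL_SYNONYMS = {
    "T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8",
    "FPZ": "Fp1", "OZ": "O1",
}


class DegenerateDatasetError(ValueError):
    """Dataset (or sequence) amplitude range is zero."""


class UnmappableRecordingError(ValueError):
    """No channel of a recording matches the canonical montage."""


# =============================================================================
# Domain types
# =============================================================================


@dataclass
class RawRecording:
    """A channels x samples EEG matrix with its sampling rate and names."""

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = ""
    dataset_id: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel-name count must match row count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class ChannelMap:
    """Mapping from source channel names onto canonical row indices 0-18."""

    canonical_order: tuple[str, ...]
    source_to_canonical: dict[str, int]
    unmatched: list[str]

    @classmethod
    def build(cls, ch_names: list[str]) -> "ChannelMap":
        canonical_upper = {name.upper(): i for i, name in enumerate(CANONICAL_19)}
        mapping: dict[str, int] = {}
        unmatched: list[str] = []
        taken: set[int] = set()
        for name in ch_names:
            key = name.strip().upper()
            # bipolar channels map by their first electrode (FPz-Cz -> FPz)
            if "-" in key:
                key = key.split("-", 1)[0].strip()
            key = CHANNEL_SYNONYMS.get(key, key).upper()
            idx = canonical_upper.get(key)
            if idx is None or idx in taken:
                unmatched.append(name)
            else:
                mapping[name] = idx
                taken.add(idx)
        order = CANONICAL_19 + ("amplitude",)
        return cls(canonical_order=order, source_to_canonical=mapping,
                   unmatched=unmatched)


@dataclass
class DatasetStats:
    """Global amplitude extremes over every sample of a dataset."""

    global_min: float
    global_max: float

    def __post_init__(self):
        if not self.global_max > self.global_min:
            raise DegenerateDatasetError(
                "dataset amplitude range is zero (max == min)")

    @property
    def range(self) -> float:
        return self.global_max - self.global_min


@dataclass
class HarmonizedSequence:
    """Canonical 20 x T matrix at 256 Hz; row 19 is the amplitude constant."""

    data: np.ndarray
    sfreq: float = TARGET_SFREQ
    amplitude: float = 1.0
    subject_id: str = ""
    dataset_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape[0] != N_CHANNELS:
            raise ValueError(f"harmonized data must have {N_CHANNELS} rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# =============================================================================
# Operations
# =============================================================================


def compute_dataset_stats(recordings) -> DatasetStats:
    """Minimum and maximum over all samples of all recordings."""
    gmin = np.inf
    gmax = -np.inf
    n = 0
    for rec in recordings:
        if rec.data.size == 0:
            continue
        gmin = min(gmin, float(rec.data.min()))
        gmax = max(gmax, float(rec.data.max()))
        n += 1
    if n == 0:
        raise DegenerateDatasetError("no recordings with samples provided")
    return DatasetStats(global_min=gmin, global_max=gmax)


def scale_sequence(x: np.ndarray) -> tuple[np.ndarray, float, float, bool]:
    """One linear weight+offset over the whole sequence mapping extremes to ±1.

    Applies jointly across all channels, preserving inter-channel amplitude
    ratios.  Returns ``(scaled, trial_min, trial_max, degenerate)``; constant
    input maps to all zeros with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence contains non-finite samples")
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        return np.zeros_like(x), lo, hi, True
    scaled = (x - lo) * (2.0 / (hi - lo)) - 1.0
    return scaled, lo, hi, False


def amplitude_value(trial_min: float, trial_max: float,
                    stats: DatasetStats) -> float:
    """Relative amplitude (trial range / dataset range), clamped to 1."""
    value = (trial_max - trial_min) / stats.range
    if value > 1.0:
        warnings.warn("trial amplitude range exceeds dataset range; "
                      "clamping amplitude channel to 1", stacklevel=2)
        value = 1.0
    return value


def _best_integer_rate(sfreq: float, target_hz: float) -> tuple[float, int, str]:
    """Whole multiple (or divisor) of sfreq nearest the target.

    Returns (rate, factor, mode) with mode 'up' (repeat each sample ``factor``
    times) or 'down' (keep every ``factor``-th sample).  Ties break toward the
    higher rate.
    """
    if sfreq <= target_hz:
        m_lo = max(1, int(np.floor(target_hz / sfreq)))
        candidates = [(sfreq * m, m, "up") for m in (m_lo, m_lo + 1)]
    else:
        d_lo = max(1, int(np.floor(sfreq / target_hz)))
        candidates = [(sfreq / d, d, "down") for d in (d_lo + 1, d_lo)]
    # sort by |rate-target| then by -rate so ties pick the higher rate
    candidates.sort(key=lambda c: (abs(c[0] - target_hz), -c[0]))
    return candidates[0]


def resample_to_target(rec: RawRecording,
                       target_hz: float = TARGET_SFREQ) -> RawRecording:
    """Integer up/down step to the nearest whole-multiple rate, then
    nearest-neighbor index mapping to the exact target rate."""
    if rec.sfreq == target_hz:
        return rec
    rate, factor, mode = _best_integer_rate(rec.sfreq, target_hz)
    if not (target_hz / 2 <= rate <= target_hz * 2):
        warnings.warn(
            f"no whole multiple of {rec.sfreq} Hz lands within a factor 2 of "
            f"{target_hz} Hz (best {rate} Hz); proceeding", stacklevel=2)
    if mode == "up":
        x = np.repeat(rec.data, factor, axis=1)
    else:
        x = rec.data[:, ::factor]
    n_int = x.shape[1]
    # number of output samples preserving duration at the exact target rate
    n_out = int(np.floor(n_int * target_hz / rate + 0.5))
    n_out = max(n_out, 1)
    # nearest-neighbor: output index j reads input round(j * f_in/f_out),
    # half-up rounding
    src = np.floor(np.arange(n_out) * (rate / target_hz) + 0.5).astype(np.intp)
    src = np.minimum(src, n_int - 1)
    return RawRecording(data=x[:, src], sfreq=target_hz,
                        ch_names=list(rec.ch_names),
                        annotations=list(rec.annotations),
                        subject_id=rec.subject_id, dataset_id=rec.dataset_id)


def apply_antialias(rec: RawRecording,
                    cutoff_hz: float = ANTIALIAS_CUTOFF_HZ) -> RawRecording:
    """Zero-phase FIR low-pass (transition band 10% of cutoff)."""
    nyq = rec.sfreq / 2.0
    if cutoff_hz >= nyq:
        warnings.warn(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz; "
                      "anti-alias filter skipped", stacklevel=2)
        return rec
    transition = 0.1 * cutoff_hz
    numtaps = int(np.ceil(3.3 * rec.sfreq / transition))
    numtaps += 1 - numtaps % 2  # odd length, linear phase
    numtaps = min(numtaps, max(3, rec.n_samples // 3 * 2 - 1))
    taps = signal.firwin(numtaps, cutoff_hz, fs=rec.sfreq)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return RawRecording(data=filtered, sfreq=rec.sfreq,
                        ch_names=list(rec.ch_names),
                        annotations=list(rec.annotations),
                        subject_id=rec.subject_id, dataset_id=rec.dataset_id)


def harmonize_recording(rec: RawRecording, cmap: ChannelMap,
                        stats: DatasetStats) -> HarmonizedSequence:
    """Place matched channels at canonical rows, scale to ±1, add amplitude row.

    Expects ``rec`` already resampled to 256 Hz (see :func:`harmonize`).
    """
    if not cmap.source_to_canonical:
        raise UnmappableRecordingError(
            f"no channel of {rec.ch_names} matches the canonical montage")
    rows = [rec.ch_names.index(name) for name in cmap.source_to_canonical]
    matched = rec.data[rows, :]
    scaled, lo, hi, degenerate = scale_sequence(matched)
    out = np.zeros((N_CHANNELS, rec.n_samples), dtype=np.float64)
    for (name, canon_idx), scaled_row in zip(cmap.source_to_canonical.items(),
                                             scaled):
        out[canon_idx] = scaled_row
    amp = 0.0 if degenerate else amplitude_value(lo, hi, stats)
    out[N_CHANNELS - 1] = amp
    return HarmonizedSequence(data=out, sfreq=rec.sfreq, amplitude=amp,
                              subject_id=rec.subject_id,
                              dataset_id=rec.dataset_id)


def harmonize(rec: RawRecording, stats: DatasetStats,
              cmap: ChannelMap | None = None,
              target_hz: float = TARGET_SFREQ) -> HarmonizedSequence:
    """Full pipeline: anti-alias (if needed), resample, map, scale."""
    if cmap is None:
        cmap = ChannelMap.build(rec.ch_names)
    if rec.sfreq / 2.0 > target_hz / 2.0:
        rec = apply_antialias(rec, min(ANTIALIAS_CUTOFF_HZ, target_hz / 2.0))
    rec = resample_to_target(rec, target_hz)
    return harmonize_recording(rec, cmap, stats)


def window_pretrain(seq: HarmonizedSequence,
                    win_s: float = PRETRAIN_WINDOW_S) -> list[HarmonizedSequence]:
    """Non-overlapping consecutive windows; trailing remainder dropped."""
    win = int(round(win_s * seq.sfreq))
    n_windows = seq.n_samples // win
    out = []
    for k in range(n_windows):
        out.append(HarmonizedSequence(
            data=seq.data[:, k * win:(k + 1) * win].copy(), sfreq=seq.sfreq,
            amplitude=seq.amplitude, subject_id=seq.subject_id,
            dataset_id=seq.dataset_id))
    return out


def extract_trials(seq: HarmonizedSequence,
                   events: list[tuple[float, str]],
                   start_s: float, length_s: float
                   ) -> list[tuple[np.ndarray, str]]:
    """Crop one trial per event at onset+start (floor to samples).

    Trials extending beyond the recording are dropped (count logged).
    """
    n_len = int(round(length_s * seq.sfreq))
    trials = []
    dropped = 0
    for onset, label in events:
        i0 = int(np.floor((onset + start_s) * seq.sfreq))
        if i0 < 0 or i0 + n_len > seq.n_samples:
            dropped += 1
            continue
        trials.append((seq.data[:, i0:i0 + n_len].copy(), label))
    if dropped:
        logger.info("extract_trials: dropped %d/%d trials outside recording",
                    dropped, len(events))
    return trials


# =============================================================================
# I/O
# =============================================================================


def read_edf(path, subject_id: str = "", dataset_id: str = "") -> RawRecording:
    """Read an EDF/EDF+ file (annotations included) into a RawRecording."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ann = [(float(a["onset"]), float(a["duration"]), str(a["description"]))
           for a in raw.annotations]
    return RawRecording(data=raw.get_data(), sfreq=float(raw.info["sfreq"]),
                        ch_names=list(raw.ch_names), annotations=ann,
                        subject_id=subject_id, dataset_id=dataset_id)


def write_text_recording(path, rec: RawRecording) -> None:
    """Delimited-text recording: '# sfreq=<Hz>' header, then named columns."""
    with open(path, "w") as f:
        f.write(f"# sfreq={rec.sfreq}\n")
        if rec.annotations:
            for onset, dur, label in rec.annotations:
                f.write(f"# annotation={onset}\t{dur}\t{label}\n")
        f.write("\t".join(rec.ch_names) + "\n")
        np.savetxt(f, rec.data.T, fmt="%.8g", delimiter="\t")


def read_text_recording(path, subject_id: str = "",
                        dataset_id: str = "") -> RawRecording:
    sfreq = None
    annotations: list[tuple[float, float, str]] = []
    with open(path) as f:
        while True:
            pos = f.tell()
            line = f.readline()
            if line.startswith("# sfreq="):
                sfreq = float(line.split("=", 1)[1])
            elif line.startswith("# annotation="):
                onset, dur, label = line.split("=", 1)[1].rstrip("\n").split("\t")
                annotations.append((float(onset), float(dur), label))
            else:
                break
        f.seek(pos)
        names = f.readline().rstrip("\n").split("\t")
        data = np.loadtxt(f, delimiter="\t", ndmin=2)
    if sfreq is None:
        raise ValueError(f"{path}: missing '# sfreq=' header")
    return RawRecording(data=data.T, sfreq=sfreq, ch_names=names,
                        annotations=annotations, subject_id=subject_id,
                        dataset_id=dataset_id)


def read_recording(path, **kw) -> RawRecording:
    path = str(path)
    if path.lower().endswith(".edf"):
        return read_edf(path, **kw)
    return read_text_recording(path, **kw)


def save_harmonized(path, seqs: list[HarmonizedSequence]) -> None:
    """Write harmonized sequences to a chunked HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["channel_order"] = [*CANONICAL_19, "amplitude"]
        for i, seq in enumerate(seqs):
            d = f.create_dataset(f"seq_{i:05d}", data=seq.data,
                                 chunks=(N_CHANNELS, min(seq.n_samples, 4096)))
            d.attrs["sfreq"] = seq.sfreq
            d.attrs["amplitude"] = seq.amplitude
            d.attrs["subject_id"] = seq.subject_id
            d.attrs["dataset_id"] = seq.dataset_id


def load_harmonized(path) -> list[HarmonizedSequence]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            d = f[key]
            out.append(HarmonizedSequence(
                data=d[()], sfreq=float(d.attrs["sfreq"]),
                amplitude=float(d.attrs["amplitude"]),
                subject_id=str(d.attrs["subject_id"]),
                dataset_id=str(d.attrs["dataset_id"])))
    return out
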