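"""Turn raw paired thalamic/cortical recordings into analysis-ready trials.

Recordings are split into non-overlapping 10 s trials, demeaned, detrended,
band-stop filtered at the line frequency and all its harmonics, and
resampled to the working rates (416 Hz for the information-transfer
analyses, 500 Hz for the chaos test).  Welch spectra provide descriptive
power estimates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "Trial",
    "segment_trials",
    "clean",
    "resample",
    "resample_series",
    "welch_psd",
    "read_delimited",
    "read_edf",
    "write_trials",
]


@dataclass
class Recording:
    """A labeled multichannel recording (channels x samples)."""

    data: np.ndarray
    channel_names: list[str]
    channel_regions: list[str]          # "cortex" or "thalamus" per channel
    fs: float
    line_freq: float = 60.0
    state: str = "waking"
    subject: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names does not match data rows")
        if len(self.channel_regions) != len(self.channel_names):
            raise ValueError("channel_regions does not match channels")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class Trial:
    """One fixed-length segment of a recording."""

    data: np.ndarray
    channel_names: list[str]
    channel_regions: list[str]
    fs: float
    line_freq: float
    state: str
    subject: str
    index: int
    artifact_flag: bool = False

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def segment_trials(rec: Recording, length: float = 10.0) -> list[Trial]:
    """Split a recording into consecutive non-overlapping trials.

    The trailing remainder shorter than ``length`` is dropped; a recording
    shorter than one trial yields an empty list with a warning.
    """
    n = int(round(length * rec.fs))
    total = rec.data.shape[1]
    if total < n:
        warnings.warn(
            f"recording of {rec.duration:.1f} s shorter than one "
            f"{length:.0f} s trial: no trials produced", stacklevel=2)
        return []
    trials = []
    for i in range(total // n):
        trials.append(Trial(
            data=rec.data[:, i * n:(i + 1) * n].copy(),
            channel_names=list(rec.channel_names),
            channel_regions=list(rec.channel_regions),
            fs=rec.fs, line_freq=rec.line_freq, state=rec.state,
            subject=rec.subject, index=i,
        ))
    return trials


def clean(trial: Trial, line_freq: float | None = None,
          notch_halfwidth: float = 2.0) -> Trial:
    """Demean, detrend, and band-stop the line frequency and its harmonics.

    Every harmonic below Nyquist is removed by zeroing the DFT bins within
    +/- ``notch_halfwidth`` Hz -- a zero-phase spectral projection, so the
    whole operation (detrend + notch + demean) is idempotent to numerical
    tolerance, unlike a cascade of recursive notches.
    """
    lf = trial.line_freq if line_freq is None else line_freq
    if trial.fs <= 2 * lf:
        raise ValueError("sample rate must exceed twice the line frequency")
    x = trial.data
    n = x.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / trial.fs)
    kill = np.zeros(freqs.size, dtype=bool)
    nyq = trial.fs / 2
    f = lf
    while f < nyq:
        kill |= np.abs(freqs - f) <= notch_halfwidth
        f += lf
    # detrending and bin-zeroing are individually idempotent projections but
    # do not commute exactly; two alternations drive the cross-talk below
    # numerical tolerance
    for _ in range(2):
        x = signal.detrend(x, axis=1, type="linear")
        X = np.fft.rfft(x, axis=1)
        X[:, kill] = 0.0
        x = np.fft.irfft(X, n=n, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    return replace(trial, data=x)


def resample_series(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase anti-aliased resampling of a 1-D or 2-D (channels last) array."""
    if target_fs > fs:
        raise ValueError("upsampling is not supported")
    if target_fs == fs:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                frac.denominator, axis=-1)


def resample(trial: Trial, target_fs: float) -> Trial:
    """Resample a trial to the working rate; duration is preserved."""
    data = resample_series(trial.data, trial.fs, target_fs)
    return replace(trial, data=data, fs=target_fs)


def welch_psd(trial: Trial | np.ndarray, fs: float | None = None,
              seg_seconds: float = 2.0, overlap: float = 0.5,
              window: str = "hann"):
    """Welch power spectral density (2 s segments, 50% overlap, Hann taper)."""
    if isinstance(trial, Trial):
        data, fs = trial.data, trial.fs
    else:
        data = np.asarray(trial, dtype=float)
        if fs is None:
            raise ValueError("fs required for a bare array")
    nper = int(round(seg_seconds * fs))
    nper = min(nper, data.shape[-1])
    return signal.welch(data, fs=fs, window=window, nperseg=nper,
                        noverlap=int(round(overlap * nper)), axis=-1)


def flag_artifacts(trials: list[Trial], threshold_sd: float = 8.0) -> list[Trial]:
    """Optional automatic amplitude flagger (off by default in the pipeline).

    Flags a trial if any channel exceeds ``threshold_sd`` standard
    deviations of that channel's across-trial amplitude; a stand-in for the
    manual visual inspection used on real recordings.
    """
    if not trials:
        return trials
    stacked = np.concatenate([t.data for t in trials], axis=1)
    sd = stacked.std(axis=1, keepdims=True)
    out = []
    for t in trials:
        bad = bool(np.any(np.abs(t.data) > threshold_sd * sd))
        out.append(replace(t, artifact_flag=bad))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_delimited(path, fs: float | None = None, line_freq: float = 60.0,
                   state: str = "waking", subject: str = "",
                   regions: dict[str, str] | None = None,
                   sep: str = "\t") -> Recording:
    """Read a delimited-text recording (columns = channels, header = labels).

    A header cell of the form ``name:region`` assigns the channel region;
    otherwise ``regions`` maps names to regions (default "cortex" for names
    containing "ctx"/"cortex", "thalamus" for "thal").
    """
    df = pd.read_csv(path, sep=sep)
    if fs is None:
        if "t" in df.columns or "time" in df.columns:
            tcol = df["t"] if "t" in df.columns else df["time"]
            fs = 1.0 / float(np.median(np.diff(tcol.to_numpy())))
            df = df.drop(columns=[tcol.name])
        else:
            raise ValueError("fs not given and no time column present")
    names, regs = [], []
    for col in df.columns:
        if ":" in col:
            name, reg = col.split(":", 1)
        else:
            name = col
            if regions and col in regions:
                reg = regions[col]
            elif "thal" in col.lower():
                reg = "thalamus"
            else:
                reg = "cortex"
        names.append(name)
        regs.append(reg)
    return Recording(data=df.to_numpy().T, channel_names=names,
                     channel_regions=regs, fs=float(fs), line_freq=line_freq,
                     state=state, subject=subject)


def read_edf(path, line_freq: float = 60.0, state: str = "waking",
             subject: str = "", regions: dict[str, str] | None = None) -> Recording:
    """Read an EDF recording via MNE (lazy import)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    regs = []
    for nm in names:
        if regions and nm in regions:
            regs.append(regions[nm])
        elif "thal" in nm.lower():
            regs.append("thalamus")
        else:
            regs.append("cortex")
    return Recording(data=raw.get_data(), channel_names=names,
                     channel_regions=regs, fs=float(raw.info["sfreq"]),
                     line_freq=line_freq, state=state, subject=subject)


def write_trials(trials: list[Trial], out_dir) -> list[Path]:
    """Write per-trial delimited files plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in trials:
        stem = f"{t.subject or 'subject'}_{t.state}_trial{t.index:03d}"
        cols = {f"{n}:{r}": t.data[i]
                for i, (n, r) in enumerate(zip(t.channel_names,
                                               t.channel_regions))}
        fpath = out_dir / f"{stem}.tsv"
        pd.DataFrame(cols).to_csv(fpath, sep="\t", index=False)
        meta = {"fs": t.fs, "line_freq": t.line_freq, "state": t.state,
                "subject": t.subject, "index": t.index,
                "artifact_flag": t.artifact_flag}
        (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        written.append(fpath)
    return written
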