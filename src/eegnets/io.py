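"""Reading, writing, epoching and preprocessing of multichannel EEG-like data.

The raw container is a :class:`Recording` — a labelled channels × samples
matrix in microvolts with its sampling rate.  Epoching cuts a recording into
a :class:`TrialSet` of equal-length condition-labelled trials, the unit every
downstream stage (connectivity, networks, statistics) consumes.

Preprocessing follows standard evoked-potential practice: a zero-phase
band-pass (0.5–50 Hz by default) and threshold-based artifact rejection.
A per-frequency power-spectrum comparison between conditions is provided as
the usual pre-check before collapsing the analysis onto the broadband signal.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger("eegnets")

__all__ = [
    "Recording",
    "TrialSet",
    "PreprocessConfig",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "epoch",
    "bandpass",
    "reject_artifacts",
    "spectrum_compare",
    "save_trialset",
    "load_trialset",
]


class FormatError(ValueError):
    """Malformed on-disk recording or annotation file."""


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding used for all ms→samples conversions."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A labelled channels × samples matrix with its sampling rate.

    Parameters
    ----------
    labels
        Ordered electrode names (10–20 system for scalp EEG); unique.
    data
        Real matrix of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    """

    labels: list[str]
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = [str(l) for l in self.labels]
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples matrix")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate channel label(s): {', '.join(dupes)}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Epoched trials with condition labels; the unit of statistical comparison.

    ``data`` has shape ``(n_trials, n_channels, n_samples_per_trial)``; all
    trials share the channel order of ``labels`` and a common length.
    """

    labels: list[str]
    data: np.ndarray
    fs: float
    conditions: list[str]
    onsets: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_length_s: float = 1.3

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("channel count does not match labels")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        self.conditions = [str(c) for c in self.conditions]
        if self.onsets is None:
            self.onsets = np.zeros(self.data.shape[0], dtype=int)
        self.onsets = np.asarray(self.onsets, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def select(self, mask: np.ndarray) -> "TrialSet":
        mask = np.asarray(mask, dtype=bool)
        return TrialSet(
            labels=list(self.labels),
            data=self.data[mask],
            fs=self.fs,
            conditions=[c for c, m in zip(self.conditions, mask) if m],
            onsets=self.onsets[mask],
            epoch_length_s=self.epoch_length_s,
        )

    def condition(self, name: str) -> "TrialSet":
        return self.select(np.array([c == name for c in self.conditions]))


@dataclass
class PreprocessConfig:
    """Band-pass edges (Hz) and artifact-rejection threshold (µV)."""

    band_lo_hz: float = 0.5
    band_hi_hz: float = 50.0
    artifact_threshold_uv: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ValueError("require 0 < band_lo_hz < band_hi_hz")
        if not self.artifact_threshold_uv > 0:
            raise ValueError("artifact threshold must be positive")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DELIMS = {"csv": ",", "tsv": "\t"}


def read_recording(path, format: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from CSV/TSV (one channel per row) or EDF.

    The text layout is: an optional ``# fs=<Hz>`` comment line, a header row
    whose first cell is ``channel``, then one row per channel starting with
    its label.  ``fs`` must be given explicitly when the file carries no
    ``# fs=`` line.  EDF files (requires :mod:`mne`) supply both labels and
    sampling rate from their header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        return _read_edf(path)
    if format not in _DELIMS:
        raise FormatError(f"unknown recording format {format!r}")
    delim = _DELIMS[format]

    file_fs = None
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            stripped = ln.lstrip("#").strip()
            if stripped.startswith("fs="):
                file_fs = float(stripped[3:])
        else:
            body.append(ln)
    if not body:
        raise FormatError(f"{path}: empty recording file")
    header = body[0].split(delim)
    data_lines = body[1:]
    if header and header[0].strip().lower() == "channel":
        pass  # standard header
    else:
        # headerless: treat the first line as data
        data_lines = body
    for r, ln in enumerate(data_lines):
        cells = ln.split(delim)
        label = cells[0].strip()
        if not label:
            raise FormatError(f"{path}: missing channel label on data row {r}")
        labels.append(label)
        try:
            rows.append(np.array([float(c) for c in cells[1:]], dtype=float))
        except ValueError:
            for c_idx, c in enumerate(cells[1:], start=1):
                try:
                    float(c)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {c!r} at row {r}, column {c_idx}"
                    ) from None
            raise
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"{path}: duplicate channel label(s): {', '.join(dupes)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: unequal row lengths {sorted(lengths)}")
    use_fs = fs if fs is not None else file_fs
    if use_fs is None:
        raise FormatError(
            f"{path}: sampling rate not in file header; pass fs= explicitly"
        )
    return Recording(labels=labels, data=np.vstack(rows), fs=float(use_fs))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional 'mne' dependency") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        labels=list(raw.ch_names),
        data=raw.get_data() * 1e6,  # volts → microvolts
        fs=float(raw.info["sfreq"]),
    )


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a recording as CSV/TSV with a ``# fs=`` line and channel rows."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in _DELIMS:
        raise FormatError(f"unknown recording format {format!r}")
    delim = _DELIMS[format]
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:.10g}\n")
        fh.write(delim.join(["channel"] + [f"s{i}" for i in range(rec.n_samples)]))
        fh.write("\n")
        for label, row in zip(rec.labels, rec.data):
            fh.write(label + delim + delim.join(repr(float(v)) for v in row) + "\n")


def read_annotations(path) -> pd.DataFrame:
    """Read a 3-column TSV of (onset_sample, condition, block)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "condition", "block"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation file must have columns {sorted(required)}")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def save_trialset(ts: TrialSet, outdir, rejection_log: dict | None = None) -> None:
    """Serialize a trial set as per-trial TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in range(ts.n_trials):
        rec = Recording(labels=list(ts.labels), data=ts.data[t], fs=ts.fs)
        write_recording(rec, outdir / f"trial_{t:04d}.tsv", "tsv")
    manifest = {
        "fs": ts.fs,
        "labels": list(ts.labels),
        "epoch_length_s": ts.epoch_length_s,
        "conditions": list(ts.conditions),
        "onsets": [int(o) for o in ts.onsets],
        "rejection_log": rejection_log or {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_trialset(outdir) -> TrialSet:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    data = []
    for t in range(len(manifest["conditions"])):
        rec = read_recording(outdir / f"trial_{t:04d}.tsv", "tsv")
        data.append(rec.data)
    return TrialSet(
        labels=manifest["labels"],
        data=np.stack(data) if data else np.empty((0, len(manifest["labels"]), 0)),
        fs=manifest["fs"],
        conditions=manifest["conditions"],
        onsets=np.asarray(manifest["onsets"], dtype=int),
        epoch_length_s=manifest["epoch_length_s"],
    )


# ---------------------------------------------------------------------------
# epoching & preprocessing
# ---------------------------------------------------------------------------


def epoch(
    rec: Recording,
    onsets: Sequence[int],
    labels: Sequence[str],
    epoch_length_s: float = 1.3,
) -> TrialSet:
    """Cut a recording into fixed-length trials starting at ``onsets``.

    Trial *t* holds the half-open sample range
    ``[onset_t, onset_t + round(epoch_length_s * fs))`` (0-based, half-up
    rounding), so adjacent non-overlapping onsets partition the recording
    exactly.
    """
    if len(onsets) != len(labels):
        raise ValueError("one condition label per onset required")
    n = round_half_up(epoch_length_s * rec.fs)
    trials = []
    for t, onset in enumerate(onsets):
        onset = int(onset)
        if onset < 0 or onset + n > rec.n_samples:
            raise IndexError(
                f"trial {t} (onset {onset}, length {n}) overruns the recording "
                f"of {rec.n_samples} samples"
            )
        trials.append(rec.data[:, onset : onset + n])
    return TrialSet(
        labels=list(rec.labels),
        data=np.stack(trials) if trials else np.empty((0, rec.n_channels, n)),
        fs=rec.fs,
        conditions=list(labels),
        onsets=np.asarray(onsets, dtype=int),
        epoch_length_s=epoch_length_s,
    )


def _bandpass_sos(cfg: PreprocessConfig, fs: float):
    if cfg.band_hi_hz >= fs / 2:
        raise ValueError(
            f"band edge {cfg.band_hi_hz} Hz is not below Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(
        4, [cfg.band_lo_hz, cfg.band_hi_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase (forward–backward) 4th-order Butterworth band-pass.

    Zero-phase filtering preserves the relative timing of the channels, so
    the zero-lag correlations computed downstream are not distorted.  The
    pass-band excludes DC, removing any offset.
    """
    cfg = cfg or PreprocessConfig()
    sos = _bandpass_sos(cfg, rec.fs)
    return Recording(
        labels=list(rec.labels),
        data=signal.sosfiltfilt(sos, rec.data, axis=-1),
        fs=rec.fs,
    )


def bandpass_trials(ts: TrialSet, cfg: PreprocessConfig | None = None) -> TrialSet:
    """Apply :func:`bandpass` trial by trial."""
    cfg = cfg or PreprocessConfig()
    sos = _bandpass_sos(cfg, ts.fs)
    return replace(ts, data=signal.sosfiltfilt(sos, ts.data, axis=-1))


def reject_artifacts(ts: TrialSet, cfg: PreprocessConfig | None = None) -> TrialSet:
    """Drop trials where any channel exceeds the amplitude threshold.

    The criterion is per-sample absolute amplitude against
    ``cfg.artifact_threshold_uv``; the number of rejected trials is logged.
    Idempotent: surviving trials pass the criterion by construction.
    """
    cfg = cfg or PreprocessConfig()
    if ts.n_trials == 0:
        return ts
    peak = np.max(np.abs(ts.data), axis=(1, 2))
    keep = peak <= cfg.artifact_threshold_uv
    n_dropped = int((~keep).sum())
    logger.info(
        "artifact rejection: dropped %d of %d trials (threshold %.3g µV)",
        n_dropped,
        ts.n_trials,
        cfg.artifact_threshold_uv,
    )
    if not keep.any():
        warnings.warn(
            "artifact rejection removed every trial "
            f"(threshold {cfg.artifact_threshold_uv} µV)",
            stacklevel=2,
        )
    return ts.select(keep)


# ---------------------------------------------------------------------------
# spectrum pre-check
# ---------------------------------------------------------------------------


def spectrum_compare(
    ts: TrialSet,
    f_lo: float = 0.0,
    f_hi: float = 50.0,
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-frequency two-condition power comparison (rank-sum test).

    For every trial a Hann-tapered periodogram is computed per channel and
    averaged over channels; at each frequency bin in ``[f_lo, f_hi]`` the two
    conditions' per-trial powers are compared with the same two-sided
    rank-sum test used for the network statistics.  A flat p-value profile
    (no bin below the significance level beyond chance) is the usual
    justification for analysing the broadband signal as a whole.

    Returns a DataFrame with columns ``frequency`` (Hz) and ``p_value``.
    """
    from .groupstats import rank_sum_p  # local import to avoid cycle

    if conditions is None:
        names = ts.condition_names()
        if len(names) != 2:
            raise ValueError(
                f"need exactly two conditions, found {names}; pass conditions="
            )
        conditions = (names[0], names[1])
    cond = np.asarray(ts.conditions)
    a_idx = cond == conditions[0]
    b_idx = cond == conditions[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError(
            "need at least 2 trials per condition "
            f"({conditions[0]}: {a_idx.sum()}, {conditions[1]}: {b_idx.sum()})"
        )
    freqs, power = signal.periodogram(ts.data, fs=ts.fs, window="hann", axis=-1)
    trial_power = power.mean(axis=1)  # average over channels → (trials, freqs)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    a = trial_power[a_idx][:, sel]
    b = trial_power[b_idx][:, sel]
    p = rank_sum_p(a.T, b.T)
    return pd.DataFrame({"frequency": freqs[sel], "p_value": p})
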