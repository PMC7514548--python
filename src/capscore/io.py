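"""File formats: signals, annotations, labels, scoring files, EDF, configs.

Canonical text dialects (all plain text, one record per line):

* **signal**: ``# key=value`` header lines (``fs`` required), then one
  sample per line;
* **annotations**: whitespace-separated ``onset_s  duration_s  label``
  event records, expanded to a per-second A/B track (B is the background);
* **labels**: one ``A``/``B`` letter per line, optional leading timestamp
  column;
* **scoring file**: one line per epoch with ISO timestamp, phase letter,
  CAP flag and error flag, preceded by ``#`` header lines carrying the
  config hash and seed.

EDF support: reading goes through ``mne`` (optional dependency) with a
channel-label fallback list for the two monopolar derivations; writing is
a minimal single-channel 16-bit EDF encoder sufficient for fixtures and
round trips.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import yaml

from .cap_cycles import CAP, ERRONEOUS, CAPCyclesVector
from .errors import AnnotationParseError
from .signal_prep import ErrorFlags, RawRecording

logger = logging.getLogger(__name__)

#: Channel labels tried, in order, when reading an EDF without an explicit pick.
EDF_CHANNEL_FALLBACKS = ("C4-A1", "C3-A2", "C4A1", "C3A2")

PHASE_CHARS = {0: "B", 1: "A"}
PHASE_CODES = {"B": 0, "A": 1}


# ----------------------------------------------------------------------------
# Plain-text signal


def write_signal_txt(recording: RawRecording, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={recording.fs:g}\n")
        fh.write(f"# derivation={recording.derivation}\n")
        fh.write(f"# subject_id={recording.subject_id}\n")
        if recording.start_time is not None:
            fh.write(f"# start_time={recording.start_time.isoformat()}\n")
        np.savetxt(fh, recording.samples, fmt="%.9g")


def read_signal_txt(path) -> RawRecording:
    path = Path(path)
    header: dict[str, str] = {}
    data_start = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            data_start += 1
            key, _, value = line.lstrip("#").strip().partition("=")
            header[key.strip()] = value.strip()
    if "fs" not in header:
        raise AnnotationParseError(f"{path}: signal header must declare fs")
    samples = np.loadtxt(path, skiprows=data_start, ndmin=1)
    start = (datetime.fromisoformat(header["start_time"])
             if "start_time" in header else None)
    rec = RawRecording(samples=samples, fs=float(header["fs"]),
                       derivation=header.get("derivation", "C4-A1"),
                       subject_id=header.get("subject_id", path.stem),
                       start_time=start)
    logger.info("read %s: %d samples at %g Hz (%s)", path, samples.size,
                rec.fs, rec.derivation)
    return rec


# ----------------------------------------------------------------------------
# EDF


def read_edf(path, channel: str | None = None) -> RawRecording:
    """Read one EEG channel from a 16-bit EDF file (requires ``mne``).

    If ``channel`` is not given, the monopolar-derivation fallback list is
    tried in order; the chosen channel, native rate and scaling are logged.
    Values are returned in physical units (microvolt).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    names = raw.ch_names
    if channel is None:
        normalized = {n.strip().upper(): n for n in names}
        for cand in EDF_CHANNEL_FALLBACKS:
            if cand.upper() in normalized:
                channel = normalized[cand.upper()]
                break
        else:
            raise ValueError(
                f"no monopolar derivation found in {names}; pass channel="
            )
    raw = raw.pick([channel]).load_data()
    samples = raw.get_data()[0] * 1e6  # volt -> microvolt
    fs = float(raw.info["sfreq"])
    logger.info("read %s: channel %s at %g Hz", path, channel, fs)
    start = raw.info.get("meas_date")
    return RawRecording(samples=samples, fs=fs, derivation=channel,
                        subject_id=Path(path).stem,
                        start_time=(start.replace(tzinfo=None)
                                    if start is not None else None))


def write_edf(recording: RawRecording, path) -> None:
    """Write a single-channel 16-bit EDF file.

    Minimal encoder: one data record per second, amplitudes scaled to the
    signal's physical range.  Sufficient for fixtures and round-tripping
    through :func:`read_edf`.
    """
    path = Path(path)
    fs = int(round(recording.fs))
    n_records = recording.samples.size // fs
    x = recording.samples[: n_records * fs]
    phys_max = float(max(np.abs(x).max(), 1e-6))
    digital = np.clip(np.rint(x / phys_max * 32767), -32768, 32767).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    start = recording.start_time or datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8),
        pad(recording.subject_id, 80),
        pad("capscore synthetic", 80),
        pad(start.strftime("%d.%m.%y"), 8),
        pad(start.strftime("%H.%M.%S"), 8),
        pad(str(256 + 256), 8),          # header bytes: fixed + 1 channel
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),                      # record duration (s)
        pad("1", 4),                      # number of signals
        # per-signal fields
        pad(recording.derivation, 16),
        pad("AgAgCl electrode", 80),
        pad("uV", 8),
        pad(f"{-phys_max:.6g}", 8),
        pad(f"{phys_max:.6g}", 8),
        pad("-32768", 8),
        pad("32767", 8),
        pad("", 80),
        pad(str(fs), 8),
        pad("", 32),
    ])
    with path.open("wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


# ----------------------------------------------------------------------------
# Annotations and labels


def read_annotations(path, record_duration: int) -> np.ndarray:
    """Expand onset/duration A-phase events into a per-second label track.

    The background is B (0); any event labelled ``A`` (case-insensitive,
    also matching subtype labels such as ``A1``) marks its seconds as A.
    Overlapping A events are merged (union) with a warning; events beyond
    the record duration are truncated with a warning.

    Raises
    ------
    AnnotationParseError
        On a malformed line, carrying its line number.
    """
    labels = np.zeros(int(record_duration), dtype=np.int8)
    prev_onset = -np.inf
    covered_until = 0.0
    with Path(path).open() as fh:
        for ln, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise AnnotationParseError(
                    f"expected 'onset duration label', got {line!r}", ln)
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError:
                raise AnnotationParseError(
                    f"non-numeric onset/duration in {line!r}", ln) from None
            label = parts[2].upper()
            if onset < prev_onset:
                raise AnnotationParseError("onsets must be non-decreasing", ln)
            if duration <= 0:
                raise AnnotationParseError("durations must be positive", ln)
            prev_onset = onset
            if not label.startswith("A"):
                continue
            if onset < covered_until:
                logger.warning("%s line %d: overlapping A events merged",
                               path, ln)
            if onset + duration > record_duration:
                logger.warning("%s line %d: event beyond record end truncated",
                               path, ln)
            lo = int(np.floor(onset))
            hi = int(np.ceil(min(onset + duration, record_duration)))
            labels[lo:hi] = 1
            covered_until = max(covered_until, onset + duration)
    return labels


def write_annotations(labels: np.ndarray, path) -> None:
    """Write a per-second label track as onset/duration A-phase events."""
    from .cap_cycles import runs_from_labels

    with Path(path).open("w") as fh:
        fh.write("# onset_s duration_s label\n")
        for run in runs_from_labels(np.asarray(labels)):
            if run.label == 1:
                fh.write(f"{run.start_epoch} {run.duration_s} A\n")


def write_labels(labels: np.ndarray, path,
                 start_time: datetime | None = None) -> None:
    """One phase letter per line, with an optional leading timestamp column."""
    with Path(path).open("w") as fh:
        for i, lab in enumerate(np.asarray(labels).astype(int)):
            if start_time is not None:
                ts = (start_time + timedelta(seconds=i)).isoformat()
                fh.write(f"{ts}\t{PHASE_CHARS[lab]}\n")
            else:
                fh.write(f"{PHASE_CHARS[lab]}\n")


def read_labels(path) -> np.ndarray:
    out = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[-1].upper()
            if token not in PHASE_CODES:
                raise AnnotationParseError(f"unknown phase label {token!r}", ln)
            out.append(PHASE_CODES[token])
    return np.array(out, dtype=np.int8)


# ----------------------------------------------------------------------------
# Scoring file


def write_scoring_file(labels: np.ndarray, cycles: CAPCyclesVector,
                       flags: ErrorFlags, start_time: datetime | None,
                       path, config_hash: str = "", seed: int | None = None
                       ) -> None:
    """Per-epoch scoring record: timestamp, phase, CAP flag, error flag."""
    labels = np.asarray(labels).astype(int).ravel()
    if not (labels.size == cycles.flags.size == flags.flags.size):
        raise ValueError("labels, cycles and flags must align")
    start = start_time or datetime(2000, 1, 1)
    with Path(path).open("w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        fh.write(f"# seed={'' if seed is None else seed}\n")
        fh.write("# timestamp\tphase\tcap\terror\n")
        for i in range(labels.size):
            ts = (start + timedelta(seconds=i)).isoformat()
            cap = ("ERRONEOUS" if cycles.flags[i] == ERRONEOUS
                   else "CAP" if cycles.flags[i] == CAP else "non-CAP")
            err = "ERR" if flags.flags[i] else "OK"
            fh.write(f"{ts}\t{PHASE_CHARS[labels[i]]}\t{cap}\t{err}\n")


def read_scoring_file(path):
    """Read back a scoring file; returns (timestamps, labels, cycle flags, errors)."""
    ts, labels, caps, errs = [], [], [], []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            t, phase, cap, err = line.rstrip("\n").split("\t")
            ts.append(datetime.fromisoformat(t))
            labels.append(PHASE_CODES[phase])
            caps.append(ERRONEOUS if cap == "ERRONEOUS"
                        else CAP if cap == "CAP" else 0)
            errs.append(err == "ERR")
    return (ts, np.array(labels, dtype=np.int8),
            CAPCyclesVector(np.array(caps, dtype=np.int8)),
            ErrorFlags(np.array(errs, dtype=bool)))


# ----------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    preset: str = "lstm_table1"
    seed: int = 0
    output_dir: str = "capscore_out"
    signal_path: str | None = None
    annotation_path: str | None = None
    # training
    cells: int | None = None
    context_length: int = 60
    n_passes: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    class_weighting: bool = False
    sequence_mode: str = "epochs"
    candidate: str = "tanh"
    threshold: float = 0.5
    # FSM / post-processing
    min_cycles_per_sequence: int = 2
    exactly_two: bool = False
    flatline_eps: float = 1e-3
    # evaluation / simulation
    n_repeats: int = 50
    n_subjects: int = 19
    duration_s: int = 600
    snr: float = 4.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
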