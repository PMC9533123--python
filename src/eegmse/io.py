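"""Multichannel EEG containers and file IO (EDF and delimited text).

The in-memory container is :class:`EEGRecording`: a channels-by-samples
float array in microvolts plus sampling rate and canonical 10-20 labels.
Two on-disk forms are supported:

* EDF (European Data Format), the standard clinical container.  Reading
  goes through :mod:`mne`; writing uses a small EDF writer (16-bit,
  one-second data records).
* A plain delimited matrix: ``#``-prefixed header lines ``fs=<Hz>`` and
  ``labels=<comma list>``, then one comma-separated row per channel.

Readers remap channels into canonical montage order and fail loudly when
montage channels are missing, so every downstream grid is comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .montage import MONTAGE_1020, montage_indices

__all__ = [
    "EEGRecording",
    "FormatError",
    "MontageError",
    "read_delimited_matrix",
    "write_delimited_matrix",
    "read_edf",
    "write_edf",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class MontageError(FormatError):
    """Channels required by the canonical montage are absent."""


@dataclass
class EEGRecording:
    """A multichannel EEG signal in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel labels, a subset of the canonical montage, in montage order.
    subject_id : str
        Identifier carried through the pipeline.
    meta : dict
        Free-text acquisition metadata (reference scheme, notes).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


def _reorder_to_montage(
    data: np.ndarray, labels: list[str], source: str
) -> tuple[np.ndarray, list[str]]:
    """Remap rows into canonical montage order; error on missing channels."""
    idx = montage_indices(labels)
    missing = [lab for lab in MONTAGE_1020 if lab not in idx]
    if missing:
        raise MontageError(
            f"{source}: missing montage channel(s): {', '.join(missing)}"
        )
    known = set(idx.values())
    unknown = [labels[i] for i in range(len(labels)) if i not in known]
    if unknown:
        warnings.warn(
            f"{source}: dropping non-montage channel(s): {', '.join(unknown)}"
        )
    rows = [idx[lab] for lab in MONTAGE_1020]
    return data[rows], list(MONTAGE_1020)


# ---------------------------------------------------------------------------
# delimited matrix
# ---------------------------------------------------------------------------

def read_delimited_matrix(path) -> EEGRecording:
    """Read a ``#fs=``/``#labels=`` headed channel-by-sample CSV matrix."""
    fs = None
    labels: list[str] | None = None
    subject_id = ""
    rows: list[np.ndarray] = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs="):
                    try:
                        fs = float(body[3:])
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric fs {body[3:]!r}"
                        ) from None
                    if not fs > 0:
                        raise FormatError(f"{path}:{lineno}: fs must be > 0, got {fs}")
                elif body.startswith("labels="):
                    labels = [s.strip() for s in body[len("labels="):].split(",")]
                elif body.startswith("subject="):
                    subject_id = body[len("subject="):].strip()
                continue
            try:
                row = np.array([float(v) for v in line.split(",")])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from None
            if n_cols is None:
                n_cols = row.size
            elif row.size != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: row has {row.size} values, expected {n_cols}"
                )
            rows.append(row)
    if fs is None:
        raise FormatError(f"{path}: missing '#fs=' header line")
    if labels is None:
        raise FormatError(f"{path}: missing '#labels=' header line")
    if len(rows) != len(labels):
        raise FormatError(
            f"{path}: {len(rows)} data rows but {len(labels)} labels"
        )
    data, labels = _reorder_to_montage(np.vstack(rows), labels, str(path))
    return EEGRecording(data=data, fs=fs, labels=labels, subject_id=subject_id)


def write_delimited_matrix(rec: EEGRecording, path) -> None:
    """Write a recording as a headed channel-by-sample CSV matrix."""
    with open(path, "w") as fh:
        fh.write(f"#fs={rec.fs:.10g}\n")
        fh.write(f"#labels={','.join(rec.labels)}\n")
        if rec.subject_id:
            fh.write(f"#subject={rec.subject_id}\n")
        np.savetxt(fh, rec.data, fmt="%.10g", delimiter=",")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path) -> EEGRecording:
    """Read an EDF file into canonical montage order (signal in µV).

    The physical dimension is assumed to be µV; any other unit string is
    passed through with a warning.  Reference montage and similar
    acquisition facts are retained only as free-text metadata.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on corrupt headers
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    labels = list(raw.ch_names)
    orig_units = getattr(raw, "_orig_units", {}) or {}
    for ch, unit in orig_units.items():
        if unit not in ("µV", "uV", "n/a"):
            warnings.warn(f"{path}: channel {ch} has unit {unit!r}; assuming µV")
    # mne scales EEG channels to volts internally
    data_uv = raw.get_data() * 1e6
    data, labels = _reorder_to_montage(data_uv, labels, str(path))
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=labels,
        subject_id=str(raw.info.get("subject_info") or ""),
        meta={"source": str(path)},
    )


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as a 16-bit EDF file with one-second data records.

    The sampling rate must be integer-valued (EDF stores samples per
    record); a trailing partial second is dropped.  Quantisation to the
    16-bit digital range limits round-trip fidelity to ~1/65536 of each
    channel's peak amplitude.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels
    data = rec.data[:, : n_records * spr]

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    def phys(v: float) -> str:
        # must fit the 8-char EDF field; 16-bit quantisation dominates anyway
        s = f"{v:.6g}"
        return s if len(s) <= 8 else f"{v:.1e}"

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    # quantise against the values actually written into the header fields
    phys_max = np.array([abs(float(phys(pm))) for pm in phys_max])
    phys_max = np.maximum(phys_max, 1e-6)
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad(rec.subject_id or "X", 80))
        fh.write(pad("Startdate 01-JAN-2000", 80))
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (1 + ns)), 8))
        fh.write(pad("EDF", 44))
        fh.write(pad(str(n_records), 8))
        fh.write(pad("1", 8))  # record duration, seconds
        fh.write(pad(str(ns), 4))
        for lab in rec.labels:
            fh.write(pad(f"EEG {lab}", 16))
        for _ in range(ns):
            fh.write(pad("AgAgCl electrode", 80))
        for _ in range(ns):
            fh.write(pad("uV", 8))
        for pm in phys_max:
            fh.write(pad(phys(-pm), 8))
        for pm in phys_max:
            fh.write(pad(phys(pm), 8))
        for _ in range(ns):
            fh.write(pad(str(dig_min), 8))
        for _ in range(ns):
            fh.write(pad(str(dig_max), 8))
        for _ in range(ns):
            fh.write(pad("BP 1-60Hz", 80))
        for _ in range(ns):
            fh.write(pad(str(spr), 8))
        for _ in range(ns):
            fh.write(pad("", 32))
        for rec_i in range(n_records):
            sl = slice(rec_i * spr, (rec_i + 1) * spr)
            for ch in range(ns):
                dig = np.clip(
                    np.round(data[ch, sl] * scale[ch]), dig_min, dig_max
                ).astype("<i2")
                fh.write(dig.tobytes())
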