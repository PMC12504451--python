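"""Record I/O and the in-memory signal model.

ECG records arrive in three shapes: WFDB header+signal pairs (PTB-XL
style), single-matrix MAT files (CinC-2017 / CPSC-2018 style), and plain
delimited text with one column per lead.  All are mapped onto
:class:`ECGRecord`, a list of equal-length :class:`Signal` leads in
millivolts.

The WFDB reader/writer here is intentionally minimal: format-16 signal
files (interleaved little-endian int16) with per-lead gain/baseline, which
covers PTB-XL-style exports.  Amplitudes are converted to mV on load using
the header gain; delimited and MAT inputs are assumed to already be in mV
unless an explicit ``gain`` is given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

#: Conventional 12-lead order, used for positional lead naming.
LEAD_ORDER = ["I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6"]


@dataclass
class Signal:
    """One lead's samples in mV at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    lead: str = "SL"
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D sample array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in lead {self.lead!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, *, fs: float | None = None) -> "Signal":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs)


@dataclass
class ECGRecord:
    """A multi-lead record whose leads share fs and length."""

    signals: list[Signal]
    label: str = "unlabeled"
    record_id: str = ""

    def __post_init__(self) -> None:
        if not self.signals:
            raise ValueError("record must contain at least one signal")
        fs0, n0 = self.signals[0].fs, self.signals[0].n_samples
        for s in self.signals:
            if s.fs != fs0 or s.n_samples != n0:
                raise ValueError("all leads must share sampling rate and length")
        names = [s.lead.lower() for s in self.signals]
        if len(set(names)) != len(names):
            raise ValueError("lead names must be unique within a record")
        if self.label not in ("norm", "afib", "unlabeled"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def fs(self) -> float:
        return self.signals[0].fs

    @property
    def n_samples(self) -> int:
        return self.signals[0].n_samples

    @property
    def lead_names(self) -> list[str]:
        return [s.lead for s in self.signals]


def select_lead(record: ECGRecord, lead: str) -> Signal:
    """Return the named lead (case-insensitive); pure projection."""
    for s in record.signals:
        if s.lead.lower() == lead.lower():
            return s
    raise LookupError(
        f"lead {lead!r} not in record; available: {record.lead_names}")


def _positional_names(n: int) -> list[str]:
    if n == 1:
        return ["SL"]
    if n <= len(LEAD_ORDER):
        return LEAD_ORDER[:n]
    return LEAD_ORDER + [f"CH{i}" for i in range(len(LEAD_ORDER), n)]


def _check_finite(matrix: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        if not np.all(np.isfinite(matrix[:, j])):
            raise DataError(f"non-finite samples in lead {name!r}")


# ---------------------------------------------------------------------------
# WFDB (minimal, format 16)

def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line in {hea_path}")
    name, nsig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3])
    specs = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        if re.sub(r"[x:+].*", "", fmt) != "16":
            raise FormatError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        gain, baseline = 200.0, 0.0
        if len(tok) > 2:
            m = re.match(r"([-\d.eE+]+)(?:\(([-\d.]+)\))?(?:/(\S+))?", tok[2])
            if m:
                gain = float(m.group(1)) or 200.0
                baseline = float(m.group(2)) if m.group(2) else 0.0
        desc = " ".join(tok[8:]) if len(tok) > 8 else ""
        specs.append((fname, gain, baseline, desc))
    return name, nsig, fs, nsamp, specs


def _load_wfdb(path: Path) -> ECGRecord:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing WFDB header {hea}")
    name, nsig, fs, nsamp, specs = _parse_header(hea)
    dat = hea.with_name(specs[0][0])
    try:
        raw = np.fromfile(dat, dtype="<i2")
    except OSError as exc:
        raise FormatError(f"cannot read WFDB signal file {dat}: {exc}") from None
    if raw.size < nsamp * nsig:
        raise FormatError(f"WFDB signal file {dat} truncated")
    mat = raw[: nsamp * nsig].reshape(nsamp, nsig).astype(float)
    names = []
    for j, (_, gain, baseline, desc) in enumerate(specs):
        mat[:, j] = (mat[:, j] - baseline) / gain
        names.append(desc or _positional_names(nsig)[j])
    _check_finite(mat, names)
    signals = [Signal(mat[:, j], fs, lead=names[j], source=str(path))
               for j in range(nsig)]
    return ECGRecord(signals, record_id=name)


def write_wfdb(record: ECGRecord, path: str | Path, gain: float = 1000.0) -> None:
    """Write a format-16 WFDB pair (``<path>.hea`` + ``<path>.dat``)."""
    path = Path(path)
    nsig, nsamp = len(record.signals), record.n_samples
    rid = record.record_id or path.stem
    lines = [f"{path.stem} {nsig} {record.fs:g} {nsamp}"]
    cols = []
    for s in record.signals:
        adc = np.rint(s.samples * gain)
        if np.any(np.abs(adc) > 32767):
            raise ValueError(f"lead {s.lead!r} overflows int16 at gain {gain}")
        cols.append(adc.astype("<i2"))
        lines.append(f"{path.stem}.dat 16 {gain:g}(0)/mV 16 0 "
                     f"{int(adc[0])} 0 0 {s.lead}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    np.stack(cols, axis=1).reshape(-1).tofile(path.with_suffix(".dat"))
    del rid


# ---------------------------------------------------------------------------
# MAT (single 2-D numeric matrix)

def _load_mat(path: Path, fs_hint: float | None, gain: float) -> ECGRecord:
    from scipy.io import loadmat

    if fs_hint is None:
        raise ConfigurationError(
            "MAT files carry no sampling rate; pass fs_hint")
    try:
        contents = loadmat(path)
    except Exception as exc:  # noqa: BLE001 - scipy raises various types
        raise FormatError(f"cannot parse MAT file {path}: {exc}") from None
    arrays = [v for k, v in contents.items()
              if not k.startswith("__") and isinstance(v, np.ndarray)
              and v.ndim == 2 and np.issubdtype(v.dtype, np.number)]
    if not arrays:
        raise FormatError(f"no 2-D numeric matrix found in {path}")
    mat = np.asarray(arrays[0], dtype=float)
    if mat.shape[0] < mat.shape[1]:  # longer axis is time
        mat = mat.T
    mat = mat / gain
    names = _positional_names(mat.shape[1])
    _check_finite(mat, names)
    signals = [Signal(mat[:, j], fs_hint, lead=names[j], source=str(path))
               for j in range(mat.shape[1])]
    return ECGRecord(signals, record_id=path.stem)


# ---------------------------------------------------------------------------
# Delimited text

def _load_delimited(path: Path, fs_hint: float | None) -> ECGRecord:
    if fs_hint is None:
        raise ConfigurationError(
            "delimited files carry no sampling rate; pass fs_hint")
    with open(path) as fh:
        first_line = fh.readline().strip()
    if not first_line:
        raise FormatError(f"empty delimited file {path}")
    sep = next((s for s in ("\t", ",", ";") if s in first_line), ",")
    has_header = not all(_is_number(tok) for tok in first_line.split(sep))
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse delimited file {path}: {exc}") from None
    names = ([str(c) for c in df.columns] if has_header
             else _positional_names(df.shape[1]))
    mat = df.to_numpy(dtype=float)
    _check_finite(mat, names)
    signals = [Signal(mat[:, j], fs_hint, lead=names[j], source=str(path))
               for j in range(mat.shape[1])]
    return ECGRecord(signals, record_id=path.stem)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_delimited(record: ECGRecord, path: str | Path, header: bool = True) -> None:
    """Write one column per lead as CSV; values round-trip to <1e-6 mV."""
    df = pd.DataFrame({s.lead: s.samples for s in record.signals})
    df.to_csv(path, index=False, header=header, float_format="%.8f")


# ---------------------------------------------------------------------------

def load_record(path: str | Path, format: str | None = None,
                fs_hint: float | None = None, gain: float = 1.0) -> ECGRecord:
    """Load an ECG record.

    Parameters
    ----------
    path
        Record path.  For WFDB, either the ``.hea`` file or the path stem.
    format
        ``"wfdb"``, ``"mat"`` or ``"delimited"``; inferred from the file
        extension when omitted.
    fs_hint
        Sampling rate in Hz, required for MAT and delimited inputs.
    gain
        ADU-per-mV divisor for MAT inputs whose matrices are stored as
        integer ADC counts (e.g. 1000 for CinC-2017 exports).
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".hea": "wfdb", ".dat": "wfdb", ".mat": "mat"}.get(ext, "delimited")
    if format == "wfdb":
        return _load_wfdb(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "mat":
        return _load_mat(path, fs_hint, gain)
    if format == "delimited":
        return _load_delimited(path, fs_hint)
    raise ConfigurationError(f"unknown format {format!r}")
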