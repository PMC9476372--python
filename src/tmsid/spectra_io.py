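"""Reading, writing and range-clamping of MSP-style EI mass-spectral records.

The unit of all spectral computation is :class:`Spectrum`: an ordered peak
list (m/z, abundance) plus identity metadata (name, InChIKey, molecular
formula, nominal molecular weight, exact mass, CAS number, library id).
The reader accepts NIST-style .msp dialects: header keys are matched
case-insensitively, peak lines may be space- or tab-separated and may carry
a trailing ``;``. Duplicate m/z values inside one record are merged by
summing their intensities (abundances are ion counts, so summing is the
physically meaningful merge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Peak",
    "Spectrum",
    "MSPFormatError",
    "read_msp",
    "write_msp",
    "clamp_mz_range",
]


@dataclass(frozen=True)
class Peak:
    """A single (m/z, abundance) pair at nominal EI resolution."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


# Header keys with first-class fields; everything else is kept opaque.
_KNOWN_KEYS = {
    "name": "name",
    "inchikey": "inchikey",
    "formula": "formula",
    "mw": "mw",
    "exactmass": "exact_mass",
    "exact mass": "exact_mass",
    "cas#": "cas",
    "cas": "cas",
    "db#": "library_id",
    "nist#": "library_id",
    "id": "library_id",
}

_FLOAT_FIELDS = {"mw", "exact_mass"}


@dataclass
class Spectrum:
    """An EI mass spectrum: strictly ascending peak list plus metadata.

    Metadata fields are ``None`` when absent from the source record; they
    are never invented. Unknown header keys survive round trips through
    ``extra`` (original key casing preserved).
    """

    peaks: list[Peak]
    name: str = ""
    inchikey: str | None = None
    formula: str | None = None
    mw: float | None = None
    exact_mass: float | None = None
    cas: str | None = None
    library_id: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"peaks of '{self.name}' not strictly ascending in m/z")

    @property
    def mz(self):
        return [p.mz for p in self.peaks]

    @property
    def intensities(self):
        return [p.intensity for p in self.peaks]

    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def __len__(self) -> int:
        return len(self.peaks)


class MSPFormatError(ValueError):
    """A malformed MSP record, annotated with file/line context."""

    def __init__(self, message: str, path=None, line: int | None = None, record: str = ""):
        ctx = []
        if path is not None:
            ctx.append(str(path))
        if line is not None:
            ctx.append(f"line {line}")
        if record:
            ctx.append(f"record '{record}'")
        super().__init__(f"{message} ({', '.join(ctx)})" if ctx else message)
        self.path, self.line, self.record = path, line, record


def _merge_duplicate_mz(pairs: list[tuple[float, float]]) -> list[Peak]:
    """Sort ascending and merge equal m/z by intensity sum."""
    merged: dict[float, float] = {}
    for mz, inten in pairs:
        merged[mz] = merged.get(mz, 0.0) + inten
    return [Peak(mz, merged[mz]) for mz in sorted(merged)]


def _meta_name(meta: dict) -> str:
    for key, value in meta.items():
        if key.lower() == "name":
            return value
    return ""


def _finish_record(meta, pairs, declared, path, start_line, errors, on_error, spectra):
    name = _meta_name(meta)
    if declared is not None and declared != len(pairs):
        err = MSPFormatError(
            f"'Num Peaks: {declared}' disagrees with {len(pairs)} peak lines",
            path=path, line=start_line, record=name,
        )
        if on_error == "raise":
            raise err
        errors.append(err)
        return
    kwargs = {"extra": {}}
    for key, raw in meta.items():
        target = _KNOWN_KEYS.get(key.lower())
        if target is None:
            kwargs["extra"][key] = raw
        elif target in _FLOAT_FIELDS:
            try:
                kwargs[target] = float(raw)
            except ValueError:
                kwargs["extra"][key] = raw  # malformed numeric: keep opaque, never invent
        else:
            kwargs[target] = raw
    try:
        spectra.append(Spectrum(peaks=_merge_duplicate_mz(pairs), **kwargs))
    except ValueError as exc:
        err = MSPFormatError(str(exc), path=path, line=start_line, record=name)
        if on_error == "raise":
            raise err
        errors.append(err)


def read_msp(path, on_error: str = "raise", errors: list | None = None) -> list[Spectrum]:
    """Read an MSP-style library file into a list of :class:`Spectrum`.

    Parameters
    ----------
    path : path-like
        MSP file; records separated per the NIST convention
        (``Name:`` ... ``Num Peaks:`` ... peak lines, blank-line separated).
    on_error : {"raise", "skip"}
        ``"raise"`` aborts at the first malformed record; ``"skip"`` drops
        the offending record and appends the error to *errors*.
    errors : list, optional
        Receives :class:`MSPFormatError` objects in ``"skip"`` mode.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    if errors is None:
        errors = []
    spectra: list[Spectrum] = []
    meta: dict[str, str] = {}
    pairs: list[tuple[float, float]] = []
    declared: int | None = None
    start_line = 1
    in_record = False

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if in_record:
                    _finish_record(meta, pairs, declared, path, start_line,
                                   errors, on_error, spectra)
                    meta, pairs, declared, in_record = {}, [], None, False
                continue
            if not in_record:
                in_record, start_line = True, lineno
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key, value = key.strip(), value.strip()
                if key.lower() == "num peaks":
                    try:
                        declared = int(value)
                    except ValueError:
                        err = MSPFormatError(f"unparsable 'Num Peaks: {value}'",
                                             path=path, line=lineno,
                                             record=_meta_name(meta))
                        if on_error == "raise":
                            raise err
                        errors.append(err)
                        declared = None
                else:
                    meta[key] = value
                continue
            # peak line: "mz intensity" / "mz<tab>intensity;" / several pairs per line
            tokens = line.replace(";", " ").replace(",", " ").split()
            if len(tokens) % 2 != 0:
                err = MSPFormatError(f"unparsable peak line '{line}'", path=path,
                                     line=lineno, record=_meta_name(meta))
                if on_error == "raise":
                    raise err
                errors.append(err)
                continue
            try:
                for i in range(0, len(tokens), 2):
                    pairs.append((float(tokens[i]), float(tokens[i + 1])))
            except ValueError:
                err = MSPFormatError(f"unparsable peak line '{line}'", path=path,
                                     line=lineno, record=_meta_name(meta))
                if on_error == "raise":
                    raise err
                errors.append(err)
    if in_record:
        _finish_record(meta, pairs, declared, path, start_line, errors, on_error, spectra)
    return spectra


# Canonical header order on output; extras follow in insertion order.
_WRITE_ORDER = [
    ("name", "Name"),
    ("inchikey", "InChIKey"),
    ("formula", "Formula"),
    ("mw", "MW"),
    ("exact_mass", "ExactMass"),
    ("cas", "CAS#"),
    ("library_id", "DB#"),
]


def _fmt_number(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".") if not math.isnan(x) else "nan"


def write_msp(spectra: list[Spectrum], path) -> None:
    """Write spectra as NIST-style MSP with a deterministic field order.

    Peak lines are ``mz intensity`` with up to four decimals; the output
    round-trips bit-stably through :func:`read_msp` at that precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            for attr, label in _WRITE_ORDER:
                value = getattr(s, attr)
                if value is None or value == "":
                    continue
                fh.write(f"{label}: {_fmt_number(value) if isinstance(value, float) else value}\n")
            for key, value in s.extra.items():
                fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for p in s.peaks:
                fh.write(f"{_fmt_number(p.mz)} {_fmt_number(p.intensity)}\n")
            fh.write("\n")


def clamp_mz_range(s: Spectrum, low: float = 50.0, high: float | None = None) -> Spectrum:
    """Restrict a spectrum to the closed m/z interval [low, high].

    ``high`` defaults to ``s.mw + 10`` — the final modification applied to
    the curated training library (scan window m/z 50 up to M_w + 10 Da).
    Metadata is unchanged; the operation is idempotent.
    """
    if high is None:
        if s.mw is None:
            raise ValueError(
                f"spectrum '{s.name}': mw unknown and no explicit upper bound given")
        high = s.mw + 10.0
    kept = [p for p in s.peaks if low <= p.mz <= high]
    return replace(s, peaks=kept, extra=dict(s.extra))
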