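"""Sweep-set data model, voltage-protocol model, and text readers/writers.

The exchange format ("CSV-S") is a plain-text CSV with ``# key=value``
header lines, a column-header row ``time_ms,sweep_000,...`` and numeric
rows.  Serialization is deterministic (fixed key order, fixed float
formatting) so that write -> read -> write is byte-identical and the
numeric matrix round-trips to full double precision.

Conventions used throughout the package:

* inward current is negative pA,
* time is milliseconds on a strictly uniform grid,
* sample windows are half-open ``[start, end)`` in 0-based sample indices,
* ms -> sample conversions round to nearest with ties toward the earlier
  sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VoltageProtocol",
    "SweepSet",
    "SweepSegment",
    "SweepFormatError",
    "GridError",
    "read_sweepset",
    "write_sweepset",
    "read_protocol",
    "write_protocol",
    "segment",
    "ms_to_sample",
]

#: sentinel level meaning "use the per-sweep test potential"
VARIABLE = None

_FLOAT_FMT = "%.17e"  # lossless for float64; see DESIGN notes in docs


class SweepFormatError(ValueError):
    """Malformed sweep or protocol file."""


class GridError(ValueError):
    """Non-uniform time grid."""


def ms_to_sample(t_ms: float, sample_rate_khz: float) -> int:
    """Convert a time in ms to a 0-based sample index.

    Rounds to nearest sample; exact half-sample ties go to the earlier
    sample so that windowing is deterministic.
    """
    x = t_ms * sample_rate_khz
    lo = math.floor(x)
    frac = x - lo
    if frac > 0.5 + 1e-12:
        return lo + 1
    return lo


@dataclass(frozen=True)
class VoltageProtocol:
    """Epoch description of a voltage-clamp stimulus.

    ``epochs`` is an ordered list of ``(level_mv, duration_ms)`` tuples;
    a level of ``None`` marks the variable epoch whose level is taken
    from ``sweep_levels[sweep_index]``.
    """

    name: str
    holding_mv: float
    epochs: tuple  # of (level_mv | None, duration_ms)
    sweep_levels: tuple  # test potential per sweep, mV
    sample_rate_khz: float
    inter_sweep_interval_ms: float = 0.0

    def __post_init__(self):
        if self.sample_rate_khz <= 0:
            raise ValueError("sample_rate_khz must be > 0")
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        object.__setattr__(self, "epochs", tuple((lv, float(d)) for lv, d in self.epochs))
        object.__setattr__(self, "sweep_levels", tuple(float(v) for v in self.sweep_levels))
        for i, (_, dur) in enumerate(self.epochs):
            if dur <= 0:
                raise ValueError(f"epoch {i} has non-positive duration {dur}")
            n = dur * self.sample_rate_khz
            if abs(n - round(n)) > 1e-6:
                raise ValueError(
                    f"epoch {i}: duration {dur} ms is not an integer number of "
                    f"samples at {self.sample_rate_khz} kHz"
                )

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_levels)

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_khz

    def epoch_bounds(self) -> list:
        """Half-open ``(start, end)`` sample bounds for every epoch."""
        bounds = []
        start = 0
        for _, dur in self.epochs:
            n = int(round(dur * self.sample_rate_khz))
            bounds.append((start, start + n))
            start += n
        return bounds

    @property
    def n_samples(self) -> int:
        return self.epoch_bounds()[-1][1]

    def epoch_level(self, epoch_index: int, sweep_index: int) -> float:
        level = self.epochs[epoch_index][0]
        if level is VARIABLE:
            return self.sweep_levels[sweep_index]
        return float(level)

    def voltage_trace(self, sweep_index: int) -> np.ndarray:
        """Command voltage at every sample of one sweep."""
        v = np.empty(self.n_samples)
        for e, (b0, b1) in enumerate(self.epoch_bounds()):
            v[b0:b1] = self.epoch_level(e, sweep_index)
        return v


@dataclass
class SweepSet:
    """Time base plus aligned current sweeps with recording metadata."""

    time: np.ndarray  # ms, uniform grid
    sweeps: np.ndarray  # [n_sweeps, n_samples], pA
    sample_rate_khz: float
    protocol: Optional[VoltageProtocol] = None
    capacitance_pf: Optional[float] = None
    series_resistance_mohm: Optional[float] = None
    charge_carrier: Optional[str] = None  # "Ca" | "Ba"
    carrier_concentration_mm: Optional[float] = None
    leak_subtracted: str = "none"  # none | p4 | offline
    filter_cutoff_khz: Optional[float] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.time.ndim != 1:
            raise ValueError("time must be a 1-D vector")
        if self.sweeps.shape[1] != self.time.size:
            raise ValueError(
                f"sweep length {self.sweeps.shape[1]} != time length {self.time.size}"
            )
        if not np.all(np.isfinite(self.sweeps)):
            raise ValueError("sweeps contain non-finite values")
        self._check_grid()

    def _check_grid(self):
        if self.time.size < 2:
            return
        dt = 1.0 / self.sample_rate_khz
        dev = np.abs(np.diff(self.time) - dt)
        if dev.max() > 1e-6 * dt + 1e-12:
            raise GridError(
                f"non-uniform time grid: max deviation {dev.max():.3g} ms "
                f"from expected spacing {dt:.6g} ms"
            )

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_khz

    def copy_with(self, **kw) -> "SweepSet":
        fields = dict(
            time=self.time.copy(),
            sweeps=self.sweeps.copy(),
            sample_rate_khz=self.sample_rate_khz,
            protocol=self.protocol,
            capacitance_pf=self.capacitance_pf,
            series_resistance_mohm=self.series_resistance_mohm,
            charge_carrier=self.charge_carrier,
            carrier_concentration_mm=self.carrier_concentration_mm,
            leak_subtracted=self.leak_subtracted,
            filter_cutoff_khz=self.filter_cutoff_khz,
            annotations=dict(self.annotations),
        )
        fields.update(kw)
        return SweepSet(**fields)


@dataclass
class SweepSegment:
    """One windowed slice of one sweep (half-open in samples)."""

    sweep_index: int
    start_ms: float
    end_ms: float
    values: np.ndarray  # pA
    step_level: float  # mV
    sample_rate_khz: float

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("segment start must precede end")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_khz

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def times(self) -> np.ndarray:
        """Sample times in ms relative to segment onset."""
        return np.arange(self.values.size) * self.dt_ms


def segment(s: SweepSet, epoch_index: int) -> list:
    """Cut one protocol epoch out of every sweep.

    Returns one :class:`SweepSegment` per sweep; boundaries fall exactly
    on the epoch sample indices and the segments of consecutive epochs
    partition the sweep with no gap or overlap.
    """
    if s.protocol is None:
        raise ValueError("SweepSet has no protocol; cannot segment by epoch")
    proto = s.protocol
    if proto.n_sweeps != s.n_sweeps:
        raise ValueError(
            f"protocol describes {proto.n_sweeps} sweeps but the set has {s.n_sweeps}"
        )
    bounds = proto.epoch_bounds()
    if not 0 <= epoch_index < len(bounds):
        raise IndexError(f"epoch_index {epoch_index} out of range ({len(bounds)} epochs)")
    b0, b1 = bounds[epoch_index]
    if b1 > s.n_samples:
        raise ValueError(
            f"epoch {epoch_index} ends at sample {b1} but only "
            f"{s.n_samples} samples were recorded"
        )
    out = []
    for j in range(s.n_sweeps):
        out.append(
            SweepSegment(
                sweep_index=j,
                start_ms=b0 * s.dt_ms,
                end_ms=b1 * s.dt_ms,
                values=s.sweeps[j, b0:b1],
                step_level=proto.epoch_level(epoch_index, j),
                sample_rate_khz=s.sample_rate_khz,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV-S serialization
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("sample_rate_khz", "capacitance_pf", "charge_carrier", "protocol_name")

_OPTIONAL_KEYS = (
    "carrier_concentration_mm",
    "series_resistance_mohm",
    "leak_subtracted",
    "filter_cutoff_khz",
)


def _fmt_num(x: float) -> str:
    return repr(float(x))


def _protocol_header_items(p: VoltageProtocol) -> list:
    epochs = ",".join(
        ("var" if lv is VARIABLE else _fmt_num(lv)) + ":" + _fmt_num(d) for lv, d in p.epochs
    )
    levels = ",".join(_fmt_num(v) for v in p.sweep_levels)
    return [
        ("protocol.holding_mv", _fmt_num(p.holding_mv)),
        ("protocol.epochs", epochs),
        ("protocol.sweep_levels", levels),
        ("protocol.inter_sweep_interval_ms", _fmt_num(p.inter_sweep_interval_ms)),
    ]


def write_sweepset(s: SweepSet, path) -> None:
    """Serialize a SweepSet to the CSV-S text dialect.

    Deterministic: fixed key order, LF endings, ``%.17e`` numeric rows so
    the matrix round-trips bit-exactly.
    """
    if s.sweeps.size == 0 or s.n_sweeps == 0:
        raise ValueError("refusing to write an empty sweep matrix")
    lines = []
    lines.append(f"# sample_rate_khz={_fmt_num(s.sample_rate_khz)}")
    cap = "" if s.capacitance_pf is None else _fmt_num(s.capacitance_pf)
    lines.append(f"# capacitance_pf={cap}")
    lines.append(f"# charge_carrier={s.charge_carrier or ''}")
    lines.append(f"# protocol_name={s.protocol.name if s.protocol else ''}")
    for key in _OPTIONAL_KEYS:
        attr = {
            "carrier_concentration_mm": s.carrier_concentration_mm,
            "series_resistance_mohm": s.series_resistance_mohm,
            "leak_subtracted": s.leak_subtracted,
            "filter_cutoff_khz": s.filter_cutoff_khz,
        }[key]
        if attr is None:
            continue
        val = attr if isinstance(attr, str) else _fmt_num(attr)
        lines.append(f"# {key}={val}")
    if s.protocol is not None:
        for k, v in _protocol_header_items(s.protocol):
            lines.append(f"# {k}={v}")
    for k in sorted(s.annotations):
        lines.append(f"# annotation.{k}={s.annotations[k]}")
    cols = ["time_ms"] + [f"sweep_{j:03d}" for j in range(s.n_sweeps)]
    lines.append(",".join(cols))
    mat = np.column_stack([s.time, s.sweeps.T])
    for row in mat:
        lines.append(",".join(_FLOAT_FMT % x for x in row))
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def _parse_protocol_from_headers(meta: dict, name: str, rate: float):
    if "protocol.epochs" not in meta:
        return None
    epochs = []
    for tok in meta["protocol.epochs"].split(","):
        lv, dur = tok.split(":")
        epochs.append((VARIABLE if lv == "var" else float(lv), float(dur)))
    levels = [float(v) for v in meta["protocol.sweep_levels"].split(",") if v]
    return VoltageProtocol(
        name=name,
        holding_mv=float(meta["protocol.holding_mv"]),
        epochs=tuple(epochs),
        sweep_levels=tuple(levels),
        sample_rate_khz=rate,
        inter_sweep_interval_ms=float(meta.get("protocol.inter_sweep_interval_ms", 0.0)),
    )


def read_sweepset(path, dialect: str = "csv-s") -> SweepSet:
    """Read a CSV-S file back into a SweepSet.

    Metadata keys absent from the file stay ``None``; they are never
    silently defaulted.
    """
    if dialect not in ("csv-s", "axon-text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = {}
    rows = []
    header_cols = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise SweepFormatError(
                        f"{path}: line {lineno}: malformed header line {line!r}"
                    )
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
                continue
            fields = line.split(",")
            if header_cols is None:
                if fields[0] != "time_ms":
                    raise SweepFormatError(
                        f"{path}: line {lineno}: expected column header starting "
                        f"with 'time_ms', got {fields[0]!r}"
                    )
                header_cols = fields
                continue
            if len(fields) != len(header_cols):
                raise SweepFormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, "
                    f"expected {len(header_cols)}"
                )
            for j, f in enumerate(fields):
                if f == "":
                    raise SweepFormatError(
                        f"{path}: line {lineno}: sweep {j - 1} is missing a value "
                        "(ragged sweeps are not allowed)"
                    )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise SweepFormatError(f"{path}: line {lineno}: {exc}") from None
    for key in ("sample_rate_khz",):
        if key not in meta:
            raise SweepFormatError(f"{path}: missing required header key {key!r}")
    if header_cols is None or not rows:
        raise SweepFormatError(f"{path}: no numeric data found")
    mat = np.array(rows, dtype=float)
    rate = float(meta["sample_rate_khz"])
    time = mat[:, 0]
    sweeps = mat[:, 1:].T
    if time.size >= 2:
        dt = 1.0 / rate
        dev = np.abs(np.diff(time) - dt)
        if dev.max() > 1e-6 * dt + 1e-12:
            raise GridError(
                f"{path}: non-uniform time grid, max deviation {dev.max():.3g} ms"
            )
    proto = _parse_protocol_from_headers(meta, meta.get("protocol_name", ""), rate)

    def _opt_float(key):
        return float(meta[key]) if meta.get(key) not in (None, "") else None

    annotations = {
        k[len("annotation."):]: v for k, v in meta.items() if k.startswith("annotation.")
    }
    return SweepSet(
        time=time,
        sweeps=sweeps,
        sample_rate_khz=rate,
        protocol=proto,
        capacitance_pf=_opt_float("capacitance_pf"),
        series_resistance_mohm=_opt_float("series_resistance_mohm"),
        charge_carrier=meta.get("charge_carrier") or None,
        carrier_concentration_mm=_opt_float("carrier_concentration_mm"),
        leak_subtracted=meta.get("leak_subtracted", "none"),
        filter_cutoff_khz=_opt_float("filter_cutoff_khz"),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Protocol config files (flat key/value)
# ---------------------------------------------------------------------------

def write_protocol(p: VoltageProtocol, path) -> None:
    epochs = ",".join(
        ("var" if lv is VARIABLE else _fmt_num(lv)) + ":" + _fmt_num(d) for lv, d in p.epochs
    )
    lines = [
        f"name={p.name}",
        f"holding_mv={_fmt_num(p.holding_mv)}",
        f"sample_rate_khz={_fmt_num(p.sample_rate_khz)}",
        f"inter_sweep_interval_ms={_fmt_num(p.inter_sweep_interval_ms)}",
        f"epochs={epochs}",
        "sweep_levels=" + ",".join(_fmt_num(v) for v in p.sweep_levels),
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_protocol(path) -> VoltageProtocol:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SweepFormatError(f"{path}: line {lineno}: expected key=value")
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    try:
        epochs = []
        for tok in meta["epochs"].split(","):
            lv, dur = tok.split(":")
            epochs.append((VARIABLE if lv == "var" else float(lv), float(dur)))
        return VoltageProtocol(
            name=meta.get("name", ""),
            holding_mv=float(meta["holding_mv"]),
            epochs=tuple(epochs),
            sweep_levels=tuple(
                float(v) for v in meta.get("sweep_levels", "").split(",") if v
            ),
            sample_rate_khz=float(meta["sample_rate_khz"]),
            inter_sweep_interval_ms=float(meta.get("inter_sweep_interval_ms", 0.0)),
        )
    except KeyError as exc:
        raise SweepFormatError(f"{path}: missing protocol key {exc}") from None
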