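"""Cytometry event-table I/O, FCS reading, and gating.

Per-cell event data are carried as a :class:`FluxSeries`: a pandas frame of
timestamped fluorescence intensities (the two Indo-1 detection channels plus
expression and viability markers) together with sample metadata.  Events with
a non-positive value in either Indo-1 channel are dropped at read time — the
405/485 signal intensity ratio (SIR) is undefined for them — and counted in a
QC report rather than imputed.

The CSV dialect is UTF-8, comma-separated, header row required, ``.`` decimal.
FCS 3.0/3.1 list-mode files are read by a minimal built-in parser (no
installed package in this stack reads FCS); writing FCS is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FluxProtocol",
    "FluxSeries",
    "PhosphoSample",
    "QCReport",
    "GateReport",
    "read_flux_csv",
    "write_flux_csv",
    "read_fcs",
    "gate_events",
    "gfp_threshold_from_control",
]

#: Columns every event table must provide.
REQUIRED_COLUMNS = ("time_s", "ch405", "ch485", "gfp")
#: Optional columns preserved when present.
OPTIONAL_COLUMNS = ("dtomato", "viability")


@dataclass(frozen=True)
class FluxProtocol:
    """Timing and analysis parameters of a calcium-flux acquisition.

    The default protocol records a baseline, adds 4-OHT at 90 s to trigger
    any autonomous signal, follows the response for 450 s, and then measures
    the maximal response to anti-Ig crosslinking for a final 90 s.

    Parameters
    ----------
    t_4oht_s:
        Time of 4-OHT addition (end of the baseline window), seconds.
    autonomous_end_s:
        End of the autonomous-response window / time of crosslinking.
    crosslink_end_s:
        End of acquisition.
    bin_width_s:
        Width of the kinetic bins used to locate the crosslink peak.
    baseline_quantile:
        Quantile of baseline SIR defining the responder threshold.
    """

    t_4oht_s: float = 90.0
    autonomous_end_s: float = 540.0
    crosslink_end_s: float = 630.0
    bin_width_s: float = 20.0
    baseline_quantile: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.t_4oht_s < self.autonomous_end_s < self.crosslink_end_s):
            raise ValueError(
                "protocol windows must satisfy 0 < t_4oht_s < autonomous_end_s "
                f"< crosslink_end_s, got ({self.t_4oht_s}, "
                f"{self.autonomous_end_s}, {self.crosslink_end_s})"
            )
        if self.bin_width_s <= 0:
            raise ValueError(f"bin_width_s must be > 0, got {self.bin_width_s}")
        if not (0 < self.baseline_quantile < 1):
            raise ValueError(
                f"baseline_quantile must be in (0, 1), got {self.baseline_quantile}"
            )

    @property
    def crosslink_bins(self) -> list[tuple[float, float]]:
        """Consecutive full bins tiling the crosslink window.

        A trailing partial bin (when ``bin_width_s`` does not divide the
        window evenly) is dropped.
        """
        bins = []
        start = self.autonomous_end_s
        while start + self.bin_width_s <= self.crosslink_end_s + 1e-9:
            bins.append((start, start + self.bin_width_s))
            start += self.bin_width_s
        return bins


@dataclass
class QCReport:
    n_read: int
    n_dropped_nonpositive: int

    @property
    def n_retained(self) -> int:
        return self.n_read - self.n_dropped_nonpositive


@dataclass
class GateReport:
    n_in: int
    n_out: int
    thresholds: dict[str, float]

    @property
    def fraction_retained(self) -> float:
        return self.n_out / self.n_in if self.n_in else float("nan")


@dataclass
class FluxSeries:
    """One transduced sample's per-cell event stream.

    ``events`` holds one row per acquired cell with at least the columns
    ``time_s`` (seconds from acquisition start), ``ch405`` and ``ch485``
    (calcium-bound / calcium-free Indo-1 intensities) and ``gfp`` (BCR
    expression marker); ``dtomato`` (SLP65-ERT2 marker) and ``viability``
    (dead-cell dye) are optional.  Rows are kept sorted by time.
    """

    events: pd.DataFrame
    sample_id: str = ""
    replicate_index: int = 0
    qc: QCReport | None = None
    gate_report: GateReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing required column(s): {missing}")
        if not self.events["time_s"].is_monotonic_increasing:
            self.events = self.events.sort_values("time_s", kind="mergesort")
        self.events = self.events.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def sir(self) -> np.ndarray:
        """Per-event 405/485 signal intensity ratio."""
        return (self.events["ch405"] / self.events["ch485"]).to_numpy()

    @property
    def time_s(self) -> np.ndarray:
        return self.events["time_s"].to_numpy()


@dataclass
class PhosphoSample:
    """Per-cell phospho-flow readout for one target protein and condition."""

    cells: pd.DataFrame  # columns: intensity, gfp, dtomato, viability
    condition: str  # "unstimulated" | "crosslinked"
    target: str = ""

    ALLOWED_CONDITIONS = ("unstimulated", "crosslinked")

    def __post_init__(self) -> None:
        if self.condition not in self.ALLOWED_CONDITIONS:
            raise ValueError(
                f"condition must be one of {self.ALLOWED_CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if "intensity" not in self.cells.columns:
            raise ValueError("phospho cell table missing 'intensity' column")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _apply_qc(df: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    n_read = len(df)
    ok = (df["ch405"] > 0) & (df["ch485"] > 0)
    ok &= np.isfinite(df["ch405"]) & np.isfinite(df["ch485"])
    kept = df.loc[ok]
    return kept, QCReport(n_read=n_read, n_dropped_nonpositive=int((~ok).sum()))


def read_flux_csv(
    path: str | Path,
    dialect_config: Mapping[str, str] | None = None,
    sample_id: str = "",
    replicate_index: int = 0,
) -> FluxSeries:
    """Read a per-cell event table from CSV.

    ``dialect_config`` optionally maps semantic column names (``time_s``,
    ``ch405``, ...) to the column headers actually present in the file.
    Rows with non-positive Indo-1 intensities are dropped and counted in the
    returned series' ``qc`` report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty event table")
    if dialect_config:
        rename = {v: k for k, v in dialect_config.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df, qc = _apply_qc(df[keep])
    return FluxSeries(
        events=df, sample_id=sample_id or path.stem, replicate_index=replicate_index, qc=qc
    )


def write_flux_csv(series: FluxSeries, path: str | Path) -> Path:
    """Write the event table in the package CSV dialect (full float precision)."""
    path = Path(path)
    series.events.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Minimal FCS 3.0 / 3.1 reader
# ---------------------------------------------------------------------------

_DTYPE_MAP = {"F": "f4", "D": "f8"}


def _parse_text_segment(raw: bytes, begin: int, end: int) -> dict[str, str]:
    seg = raw[begin : end + 1]
    delim = seg[:1]
    parts = seg[1:].split(delim)
    # trailing delimiter produces an empty last element
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise ValueError("FCS text segment has an odd number of fields")
    out: dict[str, str] = {}
    for k, v in zip(parts[::2], parts[1::2]):
        out[k.decode("utf-8", "replace").strip().upper()] = v.decode("utf-8", "replace")
    return out


def _read_fcs_matrix(path: Path) -> tuple[dict[str, str], list[str], np.ndarray]:
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ValueError(f"{path}: unsupported FCS version {version!r} (need 3.0/3.1)")
    txt_begin = int(raw[10:18])
    txt_end = int(raw[18:26])
    data_begin = int(raw[26:34])
    data_end = int(raw[34:42])
    text = _parse_text_segment(raw, txt_begin, txt_end)
    if data_begin == 0:
        data_begin = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    if text.get("$MODE", "L").upper() != "L":
        raise ValueError(f"{path}: only list-mode ($MODE L) FCS is supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text["$DATATYPE"].upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    widths = {int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
    if datatype in _DTYPE_MAP:
        dtype = np.dtype(endian + _DTYPE_MAP[datatype])
        expected = {32} if datatype == "F" else {64}
        if widths - expected:
            raise ValueError(f"{path}: $PnB widths {widths} inconsistent with $DATATYPE {datatype}")
    elif datatype == "I":
        if len(widths) != 1 or next(iter(widths)) not in (16, 32, 64):
            raise ValueError(f"{path}: unsupported integer widths {widths}")
        dtype = np.dtype(f"{endian}u{next(iter(widths)) // 8}")
        for i in range(1, n_par + 1):
            amp = text.get(f"$P{i}E", "0,0").replace(" ", "")
            if amp not in ("0,0", "0.0,0.0", "0,0.0", "0.0,0"):
                raise ValueError(
                    f"{path}: log-amplified integer channel $P{i}E={amp} not supported"
                )
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")
    n_values = n_par * n_tot
    buf = raw[data_begin : data_end + 1]
    if len(buf) < n_values * dtype.itemsize:
        raise ValueError(f"{path}: data segment shorter than $TOT × $PAR values")
    mat = np.frombuffer(buf[: n_values * dtype.itemsize], dtype=dtype).reshape(n_tot, n_par)
    return text, names, mat.astype(np.float64)


def read_fcs(
    path: str | Path,
    channel_map: Mapping[str, str],
    sample_id: str = "",
    replicate_index: int = 0,
) -> FluxSeries:
    """Read an FCS 3.0/3.1 list-mode file into a :class:`FluxSeries`.

    ``channel_map`` maps semantic channels (``time_s``, ``ch405``, ``ch485``,
    ``gfp`` and optionally ``dtomato``, ``viability``) to the ``$PnN``
    detector names in the file.  The time channel is converted to seconds
    using the file's ``$TIMESTEP`` keyword.
    """
    path = Path(path)
    text, names, mat = _read_fcs_matrix(path)
    required = ("time_s", "ch405", "ch485", "gfp")
    for sem in required:
        if sem not in channel_map:
            raise ValueError(f"channel_map missing required semantic channel {sem!r}")
    cols: dict[str, np.ndarray] = {}
    for sem, det in channel_map.items():
        if det not in names:
            raise ValueError(f"{path}: detector {det!r} (for {sem!r}) not among {names}")
        cols[sem] = mat[:, names.index(det)]
    timestep = float(text.get("$TIMESTEP", 1.0))
    cols["time_s"] = cols["time_s"] * timestep
    df, qc = _apply_qc(pd.DataFrame(cols))
    return FluxSeries(
        events=df, sample_id=sample_id or path.stem, replicate_index=replicate_index, qc=qc
    )


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


def gfp_threshold_from_control(control: FluxSeries, quantile: float = 0.99) -> float:
    """GFP positivity cutoff learned from an untransduced control sample."""
    if not (0 < quantile < 1):
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    return float(np.quantile(control.events["gfp"], quantile))


def gate_events(
    series: FluxSeries,
    gfp_min: float | None = None,
    dtomato_min: float | None = None,
    viability_max: float | None = None,
) -> FluxSeries:
    """Subset events passing all specified gates.

    At least one gate must be given.  Raises if no event survives (the
    sample is unusable for quantification).  The returned series carries a
    :class:`GateReport`; gating an already-gated series with the same
    thresholds is the identity.
    """
    gates = {"gfp_min": gfp_min, "dtomato_min": dtomato_min, "viability_max": viability_max}
    active = {k: v for k, v in gates.items() if v is not None}
    if not active:
        raise ValueError("at least one gate threshold must be specified")
    for name, v in active.items():
        if not np.isfinite(v):
            raise ValueError(f"gate threshold {name} must be finite, got {v}")
    mask = np.ones(len(series), dtype=bool)
    if gfp_min is not None:
        mask &= series.events["gfp"].to_numpy() >= gfp_min
    if dtomato_min is not None:
        if "dtomato" not in series.events.columns:
            raise ValueError("dtomato gate requested but series has no dtomato column")
        mask &= series.events["dtomato"].to_numpy() >= dtomato_min
    if viability_max is not None:
        if "viability" not in series.events.columns:
            raise ValueError("viability gate requested but series has no viability column")
        mask &= series.events["viability"].to_numpy() <= viability_max
    n_out = int(mask.sum())
    if n_out == 0:
        raise ValueError(
            f"gate retained zero of {len(series)} events (thresholds {active}); sample unusable"
        )
    report = GateReport(n_in=len(series), n_out=n_out, thresholds=dict(active))
    return replace(
        series, events=series.events.loc[mask].reset_index(drop=True), gate_report=report
    )
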