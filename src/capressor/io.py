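"""Reading and writing recordings, drug-event annotations, and pipeline outputs.

The canonical recording format is delimited text: one header row, first
column ``time_s`` (seconds from recording start), remaining columns named
pressure/flow channels in mmHg.  Floats are written with 17 significant
digits so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: channel roles the pipeline understands; aortic pressure is mandatory
PRESSURE_ROLES = ("aortic_pressure", "right_atrial_pressure", "intracranial_pressure")
OPTIONAL_ROLES = ("ecg", "co2", "carotid_flow", "jugular_flow")
KNOWN_ROLES = PRESSURE_ROLES + OPTIONAL_ROLES

TIME_COLUMN = "time_s"
_FLOAT_FMT = "%.17g"


class Drug(str, enum.Enum):
    """Annotated drug types that delimit bolus segments."""

    CALCIUM = "calcium"
    EPINEPHRINE = "epinephrine"
    BICARBONATE = "bicarbonate"


@dataclasses.dataclass(frozen=True)
class DrugEvent:
    """A single annotated drug delivery on the recording clock."""

    time_s: float
    drug: Drug
    dose: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", Drug(self.drug))
        if not np.isfinite(self.time_s):
            raise ValueError(f"event time must be finite, got {self.time_s!r}")


@dataclasses.dataclass
class Recording:
    """A multi-channel, uniformly sampled physiological recording.

    Parameters
    ----------
    sampling_rate_hz : float
        Uniform sampling rate shared by all channels.
    channels : mapping of role -> 1-D float array
        Channel roles (``aortic_pressure`` mandatory); pressures in mmHg.
    start_time_s : float
        Clock value of the first sample; downstream stages use seconds from
        recording start, so this is 0 in normal operation.
    """

    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if "aortic_pressure" not in self.channels:
            raise ValueError("recording is missing the mandatory 'aortic_pressure' channel")
        self.channels = {
            role: np.asarray(vec, dtype=float) for role, vec in self.channels.items()
        }
        lengths = {role: v.shape for role, v in self.channels.items()}
        n = self.channels["aortic_pressure"].shape
        if len(n) != 1:
            raise ValueError("channel vectors must be one-dimensional")
        if any(shape != n for shape in lengths.values()):
            raise ValueError(f"channel length mismatch: {lengths}")

    @property
    def n_samples(self) -> int:
        return int(self.channels["aortic_pressure"].shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the recording on its own clock."""
        return (self.start_time_s, self.start_time_s + self.duration_s)

    def time(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, role: str) -> np.ndarray | None:
        return self.channels.get(role)


def write_recording(recording: Recording, path: str | Path, delimiter: str = ",") -> Path:
    """Write a recording in the canonical delimited-text format."""
    path = Path(path)
    roles = list(recording.channels)
    data = np.column_stack([recording.time()] + [recording.channels[r] for r in roles])
    header = delimiter.join([TIME_COLUMN] + roles)
    try:
        np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter=delimiter, header=header, comments="")
    except OSError as exc:
        raise OSError(f"failed to write recording to {path}: {exc}") from exc
    return path


def read_recording(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> Recording:
    """Read a canonical delimited-text recording.

    Parameters
    ----------
    channel_map : mapping of file column name -> channel role, optional
        Columns not mentioned keep their file name; unmapped, unknown names
        are carried through untouched (they are simply ignored downstream).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed rows in {path}: {exc}") from exc
    if TIME_COLUMN not in frame.columns:
        raise ValueError(f"{path}: first column must be '{TIME_COLUMN}', got {list(frame.columns)[:1]}")
    if channel_map:
        frame = frame.rename(columns=dict(channel_map))
    if "aortic_pressure" not in frame.columns:
        raise ValueError(
            f"{path}: missing required channel role 'aortic_pressure' "
            f"(columns: {[c for c in frame.columns if c != TIME_COLUMN]})"
        )
    t = frame[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    rate = 1.0 / float(np.mean(dt))
    # snap to an integer rate when within rounding error of one (1000 Hz etc.)
    if abs(rate - round(rate)) < 1e-6 * max(rate, 1.0):
        rate = float(round(rate))
    channels = {
        col: frame[col].to_numpy(dtype=float) for col in frame.columns if col != TIME_COLUMN
    }
    rec = Recording(sampling_rate_hz=rate, channels=channels, start_time_s=float(t[0]))
    logger.info("read %s: %d samples at %.6g Hz, channels=%s", path, rec.n_samples, rate, list(channels))
    return rec


def read_events(path: str | Path, delimiter: str = ",") -> list[DrugEvent]:
    """Read drug-event annotations (columns: time_s, drug, dose).

    Events are returned sorted ascending by time; ties keep file order.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype={"dose": str})
    required = {"time_s", "drug"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: events file needs columns {sorted(required)}, got {list(frame.columns)}")
    events: list[DrugEvent] = []
    for idx, row in frame.iterrows():
        try:
            t = float(row["time_s"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: unparseable time in row {idx}: {row['time_s']!r}") from exc
        try:
            drug = Drug(str(row["drug"]).strip().lower())
        except ValueError as exc:
            raise ValueError(f"{path}: unknown drug {row['drug']!r} in row {idx}") from exc
        dose = "" if "dose" not in frame.columns or pd.isna(row.get("dose")) else str(row["dose"])
        events.append(DrugEvent(time_s=t, drug=drug, dose=dose))
    events.sort(key=lambda e: e.time_s)  # stable: ties keep file order
    return events


def write_events(events: Iterable[DrugEvent], path: str | Path, delimiter: str = ",") -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [{"time_s": e.time_s, "drug": e.drug.value, "dose": e.dose} for e in events]
    )
    if frame.empty:
        frame = pd.DataFrame(columns=["time_s", "drug", "dose"])
    frame.to_csv(path, sep=delimiter, index=False)
    return path


def write_outputs(results, out_dir: str | Path) -> list[Path]:
    """Write pipeline outputs: segment manifest, per-bolus normalized tables,
    summary JSON, and band/histogram figures.

    ``results`` is a fitted :class:`~capressor.model.PressorResponseResults`
    (duck-typed, to keep this module free of analysis imports).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: list[Path] = []

    manifest = results.segment_manifest()
    p = out_dir / "segment_manifest.csv"
    manifest.to_csv(p, index=False, float_format=_FLOAT_FMT)
    written.append(p)

    for i, table in enumerate(results.normalized_tables()):
        p = out_dir / f"normalized_segment_{i:02d}.csv"
        table.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)

    p = out_dir / "summary.json"
    p.write_text(json.dumps(results.summary_dict(), indent=2, sort_keys=True) + "\n")
    written.append(p)

    band = results.band()
    if band is not None:
        p = out_dir / "band.csv"
        band.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
        fig = results.plot_band()
        p = out_dir / "band.png"
        fig.savefig(p, dpi=120)
        written.append(p)
        _close(fig)

    hist = results.delta_histogram()
    if hist is not None:
        counts, edges = hist
        p = out_dir / "delta_map_histogram.csv"
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
            p, index=False, float_format=_FLOAT_FMT
        )
        written.append(p)
        fig = results.plot_histogram()
        p = out_dir / "delta_map_histogram.png"
        fig.savefig(p, dpi=120)
        written.append(p)
        _close(fig)

    logger.info("wrote %d output files to %s", len(written), out_dir)
    return written


def _close(fig) -> None:
    import matplotlib.pyplot as plt

    plt.close(fig)
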