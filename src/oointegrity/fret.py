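"""FRET ratio normalization for CDK1-activity biosensor traces.

A trace carries a transmission (FRET acceptor) channel T(t), a donor
channel D(t) and their background levels dT(t), dD(t). Each channel is
background-subtracted and affinely rescaled so its minimum is 0 and its
maximum 1; the activity readout is the ratio

    F(t) = <T(t) - dT(t)>_0^1 / <D(t) - dD(t)>_0^1 ,

where <.>_0^1 denotes that min/max rescaling. Because the rescaled donor
attains 0 by construction, F is flagged undefined (NaN) wherever the
rescaled donor falls below ``epsilon`` rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FretTrace",
    "normalize_fret",
    "summarize_trace",
    "pre_event_peak",
    "read_trace_csv",
    "write_trace_csv",
]


class DegenerateChannelError(ValueError):
    """A channel is constant after background subtraction."""


@dataclass
class FretTrace:
    """Time series of one oocyte's FRET channels, minutes on the time axis."""

    t: np.ndarray
    T: np.ndarray
    D: np.ndarray
    dT: np.ndarray
    dD: np.ndarray
    F: np.ndarray | None = None
    events: dict[str, float] = field(default_factory=dict)
    trace_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("T", "D", "dT", "dD"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from t")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of time points where F is defined."""
        if self.F is None:
            raise ValueError("normalize first")
        return np.isfinite(self.F)


def _rescale01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateChannelError(
            "channel constant after background subtraction")
    return (x - lo) / (hi - lo)


def normalize_fret(trace: FretTrace, epsilon: float = 0.01) -> FretTrace:
    """Compute F(t) from the printed min/max-rescaled ratio.

    F is NaN wherever the rescaled donor is below ``epsilon`` (the rescaled
    denominator reaches 0 by construction, so some undefined points always
    exist). Raises :class:`DegenerateChannelError` on a constant channel.
    """
    num = _rescale01(np.asarray(trace.T, float) - np.asarray(trace.dT, float))
    den = _rescale01(np.asarray(trace.D, float) - np.asarray(trace.dD, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den >= epsilon, num / den, np.nan)
    return FretTrace(t=np.asarray(trace.t, float), T=trace.T, D=trace.D,
                     dT=trace.dT, dD=trace.dD, F=F,
                     events=dict(trace.events), trace_id=trace.trace_id)


def summarize_trace(traces: Sequence[FretTrace],
                    grid: np.ndarray | None = None) -> pd.DataFrame:
    """Pointwise mean F across traces on a common time grid.

    Traces are linearly interpolated onto the union grid (or the supplied
    one); no extrapolation beyond a trace's defined support, so the mean at
    each time runs over the traces covering it. Event markers are carried
    through as separate rows in the companion ``events`` attribute of the
    frame (``frame.attrs['events']``).
    """
    if not traces:
        raise ValueError("no traces")
    if any(tr.F is None for tr in traces):
        raise ValueError("normalize all traces first")
    if grid is None:
        grid = np.unique(np.concatenate([tr.t for tr in traces]))
    acc = np.zeros(grid.size)
    n = np.zeros(grid.size)
    for tr in traces:
        ok = np.isfinite(tr.F)
        if ok.sum() < 2:
            continue
        t_ok, f_ok = tr.t[ok], tr.F[ok]
        inside = (grid >= t_ok[0]) & (grid <= t_ok[-1])
        vals = np.interp(grid[inside], t_ok, f_ok)
        acc[inside] += vals
        n[inside] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, acc / np.maximum(n, 1), np.nan)
    out = pd.DataFrame({"t": grid, "mean_F": mean, "n_traces": n.astype(int)})
    out.attrs["events"] = [
        {"trace_id": tr.trace_id, "event": k, "t": v}
        for tr in traces for k, v in tr.events.items()]
    return out


def pre_event_peak(trace: FretTrace, event: str = "GVBD") -> int:
    """Index of the maximum of F before the named event.

    The activation peak of interest precedes the event (CDK1 activates
    shortly before nuclear-envelope breakdown); restricting the search also
    avoids the late-trace region where the rescaled donor approaches its
    zero point and the ratio amplifies noise.
    """
    if trace.F is None:
        raise ValueError("normalize first")
    if event not in trace.events:
        raise KeyError(f"trace has no {event!r} event")
    mask = trace.t <= trace.events[event]
    F = np.where(mask, trace.F, np.nan)
    if not np.isfinite(F).any():
        raise ValueError("F undefined everywhere before the event")
    return int(np.nanargmax(F))


def read_trace_csv(path) -> FretTrace:
    """Per-trace CSV with columns t, T, D, dT, dD [, event]."""
    df = pd.read_csv(path)
    events = {}
    if "event" in df.columns:
        for _, row in df[df["event"].notna()].iterrows():
            events[str(row["event"])] = float(row["t"])
    return FretTrace(
        t=df["t"].to_numpy(float), T=df["T"].to_numpy(float),
        D=df["D"].to_numpy(float), dT=df["dT"].to_numpy(float),
        dD=df["dD"].to_numpy(float), events=events,
        trace_id=Path(str(path)).stem)


def write_trace_csv(path, trace: FretTrace) -> None:
    df = pd.DataFrame({"t": trace.t, "T": trace.T, "D": trace.D,
                       "dT": trace.dT, "dD": trace.dD})
    if trace.F is not None:
        df["F"] = trace.F
    if trace.events:
        ev = pd.Series(index=df.index, dtype=object)
        for name, tt in trace.events.items():
            ev.iloc[int(np.argmin(np.abs(trace.t - tt)))] = name
        df["event"] = ev
    df.to_csv(path, index=False)
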