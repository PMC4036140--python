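"""Spike-train and behavioral-event containers and preprocessing.

Loads spike-time and event tables, pre-screens neurons by mean firing
rate, discretizes spike trains into binary matrices (2 ms bins by
default), extracts perievent spatio-temporal patterns around behavioral
events, and concatenates per-trial windows into the long input/output
matrices the encoding model consumes.

Conventions
-----------
* Bins are 0-based and half-open: bin ``i`` covers
  ``[t0 + i*dt, t0 + (i+1)*dt)``; a spike on the right edge falls in the
  next bin.
* Multiple spikes in one bin clip to 1 (the per-bin Bernoulli spike
  model requires binary series); at hippocampal rates and 2 ms bins
  this is rare.
* Memory labels are global: left = 1, right = 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "REGIONS",
    "EVENT_CODES",
    "SpikeTrainSet",
    "BinnedSpikeMatrix",
    "PerieventPattern",
    "ConcatenatedSession",
    "load_spike_times",
    "save_spike_times",
    "prescreen_neurons",
    "bin_spikes",
    "extract_perievent_patterns",
    "concatenate_trials",
    "export_binned_matrix",
]

REGIONS = ("CA3", "CA1")
#: side (L/R) x phase (S = sample, N = non-match)
EVENT_CODES = ("LS", "RS", "LN", "RN")

#: event codes belonging to each task phase
PHASE_CODES = {"sample": ("LS", "RS"), "nonmatch": ("LN", "RN")}

#: left = 1, right = 0 (global label convention)
SIDE_LABEL = {"L": 1, "R": 0}

SPIKE_COLUMNS = ["trial_id", "neuron_id", "region", "spike_time_s"]
EVENT_COLUMNS = ["trial_id", "event_code", "event_time_s"]


class FormatError(ValueError):
    """A CSV table does not have the documented columns."""


class ValidationError(ValueError):
    """A table row violates a domain constraint."""


@dataclass
class SpikeTrainSet:
    """Spike times plus behavioral events for one recording session.

    Attributes
    ----------
    neurons : pandas.DataFrame
        Columns ``neuron_id``, ``region`` (CA3 or CA1), one row per unit.
    spikes : pandas.DataFrame
        Columns ``trial_id``, ``neuron_id``, ``region``, ``spike_time_s``;
        sorted by time within each (trial, neuron).
    events : pandas.DataFrame
        Columns ``trial_id``, ``event_code``, ``event_time_s``.
    """

    neurons: pd.DataFrame
    spikes: pd.DataFrame
    events: pd.DataFrame

    @property
    def trials(self) -> list:
        ids = set(self.spikes["trial_id"]) | set(self.events["trial_id"])
        return sorted(ids)

    def neuron_ids(self, region: str | None = None) -> list:
        df = self.neurons
        if region is not None:
            if region not in REGIONS:
                raise ValidationError(f"unknown region {region!r}")
            df = df[df["region"] == region]
        return df["neuron_id"].tolist()

    def duration_s(self) -> float:
        """Session span: zero to the latest spike or event time."""
        t = 0.0
        if len(self.spikes):
            t = max(t, float(self.spikes["spike_time_s"].max()))
        if len(self.events):
            t = max(t, float(self.events["event_time_s"].max()))
        return t

    def mean_rates_hz(self) -> pd.Series:
        """Session-wide mean firing rate (count / session duration)."""
        dur = self.duration_s()
        counts = self.spikes.groupby("neuron_id").size()
        counts = counts.reindex(self.neurons["neuron_id"], fill_value=0)
        if dur <= 0:
            return counts.astype(float) * np.nan
        return counts / dur

    def subset_neurons(self, keep_ids) -> "SpikeTrainSet":
        keep = set(keep_ids)
        return SpikeTrainSet(
            neurons=self.neurons[self.neurons["neuron_id"].isin(keep)].reset_index(drop=True),
            spikes=self.spikes[self.spikes["neuron_id"].isin(keep)].reset_index(drop=True),
            events=self.events.copy(),
        )


@dataclass
class BinnedSpikeMatrix:
    """Binary N x T spike matrix for one trial window."""

    values: np.ndarray
    bin_width_s: float
    t0: float
    neuron_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("binned matrix entries must be 0/1")


@dataclass
class PerieventPattern:
    """Spatio-temporal pattern: N neurons x M time bins around one event.

    ``label`` is 1 for a left event, 0 for a right event.
    """

    pattern: np.ndarray
    label: int
    trial_id: object
    event_code: str
    neuron_ids: list = field(default_factory=list)
    bin_width_s: float = 0.002
    window_s: tuple = (-2.0, 2.0)

    @property
    def n_bins(self) -> int:
        return self.pattern.shape[1]


@dataclass
class ConcatenatedSession:
    """Trial windows laid side by side to form long input/output matrices.

    ``segment_bounds[i]`` is the column where trial segment ``i`` starts;
    convolution history must be reset at each bound because perievent
    windows are not contiguous in real time.
    """

    inputs: np.ndarray
    outputs: np.ndarray
    segment_bounds: list
    input_ids: list = field(default_factory=list)
    output_ids: list = field(default_factory=list)
    trial_ids: list = field(default_factory=list)
    bin_width_s: float = 0.002

    def __post_init__(self):
        b = list(self.segment_bounds)
        if not b or b[0] != 0 or any(y <= x for x, y in zip(b, b[1:])):
            raise ValidationError("segment_bounds must start at 0 and strictly increase")
        if self.inputs.shape[1] != self.outputs.shape[1]:
            raise ValidationError("inputs and outputs must share the time axis")

    @property
    def n_bins(self) -> int:
        return self.inputs.shape[1]

    @property
    def segment_slices(self) -> list[slice]:
        bounds = list(self.segment_bounds) + [self.n_bins]
        return [slice(a, b) for a, b in zip(bounds, bounds[1:])]

    def min_segment_length(self) -> int:
        return min(sl.stop - sl.start for sl in self.segment_slices)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def load_spike_times(spikes_path, events_path) -> SpikeTrainSet:
    """Read spike and event CSV tables into a validated :class:`SpikeTrainSet`.

    The spikes table has columns ``trial_id,neuron_id,region,spike_time_s``
    and the events table ``trial_id,event_code,event_time_s`` (UTF-8,
    header required). Rows with unknown region or event code raise a
    :class:`ValidationError` naming the offending row; negative times are
    rejected the same way. Spike times are sorted within (trial, neuron).
    """
    spikes = pd.read_csv(spikes_path)
    events = pd.read_csv(events_path)
    _require_columns(spikes, SPIKE_COLUMNS, spikes_path)
    _require_columns(events, EVENT_COLUMNS, events_path)

    bad = ~spikes["region"].isin(REGIONS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{spikes_path}: row {row}: unknown region {spikes['region'].iloc[row]!r}"
        )
    neg = spikes["spike_time_s"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValidationError(f"{spikes_path}: row {row}: negative spike time")

    bad = ~events["event_code"].isin(EVENT_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{events_path}: row {row}: unknown event code {events['event_code'].iloc[row]!r}"
        )
    neg = events["event_time_s"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValidationError(f"{events_path}: row {row}: negative event time")

    # one region per neuron id
    reg = spikes.groupby("neuron_id")["region"].nunique()
    multi = reg[reg > 1]
    if len(multi):
        raise ValidationError(f"neuron(s) {multi.index.tolist()} appear in multiple regions")

    spikes = spikes.sort_values(
        ["trial_id", "neuron_id", "spike_time_s"], kind="mergesort"
    ).reset_index(drop=True)
    neurons = (
        spikes[["neuron_id", "region"]]
        .drop_duplicates()
        .sort_values(["region", "neuron_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SpikeTrainSet(neurons=neurons, spikes=spikes, events=events.reset_index(drop=True))


def save_spike_times(s: SpikeTrainSet, spikes_path, events_path) -> None:
    """Write the tables back to CSV in the documented column order."""
    s.spikes[SPIKE_COLUMNS].to_csv(spikes_path, index=False)
    s.events[EVENT_COLUMNS].to_csv(events_path, index=False)


def prescreen_neurons(
    s: SpikeTrainSet, min_rate_hz: float = 0.5, max_rate_hz: float = 100.0
) -> SpikeTrainSet:
    """Retain neurons whose session-wide mean rate lies in [min, max] Hz.

    The original recordings were pre-screened on mean firing rate and
    perievent histograms; only the rate-band part is applied as a hard
    filter here (histogram inspection is a plotting concern). Dropped
    neurons are reported via a warning.
    """
    if not max_rate_hz > min_rate_hz or min_rate_hz < 0:
        raise ValueError("require max_rate_hz > min_rate_hz >= 0")
    rates = s.mean_rates_hz()
    keep = rates.index[(rates >= min_rate_hz) & (rates <= max_rate_hz)]
    dropped = [n for n in s.neurons["neuron_id"] if n not in set(keep)]
    if dropped:
        warnings.warn(f"prescreen dropped {len(dropped)} neuron(s): {dropped}")
    if not len(keep):
        warnings.warn("prescreen dropped every neuron; returning an empty set")
    return s.subset_neurons(keep)


def bin_spikes(
    s: SpikeTrainSet,
    bin_width_s: float,
    t_start: float,
    t_end: float,
    trial_id,
    region: str | None = None,
) -> BinnedSpikeMatrix:
    """Discretize one trial's spikes into a binary N x T matrix.

    ``T = round((t_end - t_start) / bin_width_s)``; spike at time t goes
    to bin ``floor((t - t_start)/dt)``; spikes outside ``[t_start, t_end)``
    are ignored; multiple spikes per bin clip to 1.
    """
    if not (t_end > t_start and bin_width_s > 0):
        raise ValueError("require t_end > t_start and bin_width_s > 0")
    if trial_id not in set(s.trials):
        raise KeyError(f"unknown trial_id {trial_id!r}")
    neuron_ids = s.neuron_ids(region)
    T = int(round((t_end - t_start) / bin_width_s))
    values = np.zeros((len(neuron_ids), T), dtype=np.int8)
    idx = {nid: i for i, nid in enumerate(neuron_ids)}
    sel = s.spikes[s.spikes["trial_id"] == trial_id]
    if region is not None:
        sel = sel[sel["region"] == region]
    t = sel["spike_time_s"].to_numpy(float)
    inside = (t >= t_start) & (t < t_end)
    cols = np.floor((t[inside] - t_start) / bin_width_s).astype(int)
    cols = np.clip(cols, 0, T - 1)  # right-edge float fuzz only
    rows = sel["neuron_id"].iloc[np.flatnonzero(inside)].map(idx).to_numpy()
    values[rows, cols] = 1
    return BinnedSpikeMatrix(values, bin_width_s, t_start, neuron_ids)


def extract_perievent_patterns(
    s: SpikeTrainSet,
    region: str,
    phase: str = "sample",
    window_s: tuple = (-2.0, 2.0),
    bin_width_s: float = 0.002,
) -> list[PerieventPattern]:
    """Extract one labeled perievent pattern per trial.

    For each trial with exactly one event of the requested phase, bin
    the region's spikes in ``[event + window_s[0], event + window_s[1])``.
    The default window and bin width give N x 2000 matrices. Labels
    follow the event side: LS/LN -> 1 (left), RS/RN -> 0 (right). Trials
    with zero or multiple phase events are skipped with a warning.
    """
    if phase not in PHASE_CODES:
        raise ValueError(f"phase must be one of {sorted(PHASE_CODES)}")
    codes = PHASE_CODES[phase]
    patterns = []
    for trial in s.trials:
        ev = s.events[(s.events["trial_id"] == trial) & (s.events["event_code"].isin(codes))]
        if len(ev) != 1:
            warnings.warn(f"trial {trial!r}: {len(ev)} {phase} events; skipped")
            continue
        code = ev["event_code"].iloc[0]
        t_ev = float(ev["event_time_s"].iloc[0])
        binned = bin_spikes(
            s, bin_width_s, t_ev + window_s[0], t_ev + window_s[1], trial, region=region
        )
        patterns.append(
            PerieventPattern(
                pattern=binned.values,
                label=SIDE_LABEL[code[0]],
                trial_id=trial,
                event_code=code,
                neuron_ids=binned.neuron_ids,
                bin_width_s=bin_width_s,
                window_s=tuple(window_s),
            )
        )
    return patterns


def concatenate_trials(
    patterns_in: list[PerieventPattern], patterns_out: list[PerieventPattern]
) -> ConcatenatedSession:
    """Concatenate matched input/output trial windows column-wise.

    Both lists must cover the same trials in the same order with equal
    bin counts. Segment start indices are recorded so that downstream
    convolutions can reset their history at every trial boundary.
    """
    if not patterns_in or not patterns_out:
        raise ValueError("pattern lists must be non-empty")
    trials_in = [p.trial_id for p in patterns_in]
    trials_out = [p.trial_id for p in patterns_out]
    if trials_in != trials_out:
        raise ValidationError("input and output pattern lists cover different trials")
    widths = {p.n_bins for p in patterns_in} | {p.n_bins for p in patterns_out}
    if len(widths) != 1:
        raise ValidationError(f"mixed pattern widths {sorted(widths)}")
    M = widths.pop()
    bounds = [i * M for i in range(len(patterns_in))]
    return ConcatenatedSession(
        inputs=np.concatenate([p.pattern for p in patterns_in], axis=1),
        outputs=np.concatenate([p.pattern for p in patterns_out], axis=1),
        segment_bounds=bounds,
        input_ids=list(patterns_in[0].neuron_ids),
        output_ids=list(patterns_out[0].neuron_ids),
        trial_ids=trials_in,
        bin_width_s=patterns_in[0].bin_width_s,
    )


def export_binned_matrix(m: BinnedSpikeMatrix, mtx_path, sidecar_path) -> None:
    """Write a binned matrix as Matrix Market coordinate format + JSON sidecar."""
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(m.values))
    meta = {
        "bin_width_s": m.bin_width_s,
        "t0": m.t0,
        "neuron_ids": [str(n) for n in m.neuron_ids],
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))
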