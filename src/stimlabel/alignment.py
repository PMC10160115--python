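"""Sentence-label → fMRI-volume alignment on the TR grid.

Each acquired volume covers a half-open window [t, t + TR).  A sentence with
onset o and duration d claims ceil(d / TR) consecutive volumes starting at
the volume containing its onset, floor((o - t_start) / TR) — the *ceil
rule*: a sentence spilling 0.3 s into a ninth second labels nine volumes,
not eight.  Volumes falling in silent gaps between dialogues carry the
previous sentence's label forward (``gap_policy='carry_previous'``); volumes
before the first sentence take that sentence's label (``initial_policy=
'backfill'``).  When the ceil rule extends a sentence past the next one's
onset the later sentence wins (last-writer-wins in onset order).  The
alignment is approximate by construction; the lead-in before subtitles start
is usually discarded instead of labeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: tolerance absorbing float representation error in duration / TR ratios
_EPS = 1e-9


@dataclass(frozen=True)
class TRLabelSeries:
    """One class label per fMRI volume on a regular TR grid."""

    tr: float
    t_start: float
    labels: np.ndarray  # shape (n_volumes,), integer class labels
    lead_in_discarded: float = 0.0

    @property
    def n_volumes(self) -> int:
        return int(self.labels.size)

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.n_volumes)
        return pd.DataFrame(
            {
                "volume_index": idx,
                "t_start": self.t_start + idx * self.tr,
                "label": self.labels,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float | None = None) -> "TRLabelSeries":
        df = pd.read_csv(path, sep="\t")
        t = df["t_start"].to_numpy(dtype=float)
        inferred_tr = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(
            tr=tr if tr is not None else inferred_tr,
            t_start=float(t[0]),
            labels=df["label"].to_numpy(dtype=int),
        )


def volumes_claimed(duration: float, tr: float) -> int:
    """Volume count a sentence claims under the ceil rule (minimum 1)."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    return max(1, math.ceil(duration / tr - _EPS))


def assign_tr_labels(
    onsets: Sequence[float],
    durations: Sequence[float],
    labels: Sequence[int],
    tr: float = 1.0,
    t_start: float = 0.0,
    t_end: float | None = None,
    gap_policy: str = "carry_previous",
    initial_policy: str = "backfill",
    neutral_label: int = 0,
) -> TRLabelSeries:
    """Assign one class label to every volume in [t_start, t_end).

    Parameters
    ----------
    onsets, durations, labels:
        Per-sentence onset (s), duration (s) and class label, sorted by
        onset (a sequential pass in time order resolves overlaps as
        last-writer-wins).
    gap_policy:
        ``'carry_previous'`` (labels persist through silent gaps) or
        ``'neutral'``.
    initial_policy:
        Label for volumes before the first sentence: ``'backfill'`` (first
        sentence's label) or ``'neutral'``.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (onsets.size == durations.size == labels.size):
        raise ValueError("onsets, durations and labels must have equal length")
    if onsets.size == 0:
        raise ValueError("no sentences to align")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if gap_policy not in {"carry_previous", "neutral"}:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if initial_policy not in {"backfill", "neutral"}:
        raise ValueError(f"unknown initial_policy {initial_policy!r}")
    if np.any(np.diff(onsets) < 0):
        raise ValueError("sentences must be sorted by onset")

    if t_end is None:
        t_end = float(onsets[-1] + durations[-1])
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n_volumes = math.ceil((t_end - t_start) / tr - _EPS)

    in_window = (onsets < t_end) & (onsets + durations > t_start)
    if not np.all(in_window):
        warnings.warn(
            f"{int((~in_window).sum())} sentence(s) fall outside "
            f"[{t_start}, {t_end}); clipping",
            stacklevel=2,
        )
        onsets, durations, labels = (
            onsets[in_window], durations[in_window], labels[in_window],
        )
        if onsets.size == 0:
            raise ValueError("no sentences within the alignment window")

    out = np.full(n_volumes, -1, dtype=int)
    for onset, duration, label in zip(onsets, durations, labels):
        first = math.floor((onset - t_start) / tr + _EPS)
        n_claim = volumes_claimed(duration, tr)
        lo = max(0, first)
        hi = min(n_volumes, first + n_claim)
        if hi > lo:
            out[lo:hi] = label

    # fill volumes no sentence claimed: leading ones per initial_policy,
    # interior/trailing gaps per gap_policy
    unfilled = out == -1
    if unfilled.any():
        first_filled = int(np.argmax(~unfilled)) if (~unfilled).any() else n_volumes
        lead_label = (
            out[first_filled]
            if initial_policy == "backfill" and first_filled < n_volumes
            else neutral_label
        )
        out[:first_filled] = lead_label
        if gap_policy == "carry_previous":
            for i in range(first_filled + 1, n_volumes):
                if out[i] == -1:
                    out[i] = out[i - 1]
        else:
            out[out == -1] = neutral_label

    return TRLabelSeries(tr=tr, t_start=t_start, labels=out)


def discard_lead_in(n_total_volumes: int, lead_in: float, tr: float = 1.0) -> int:
    """Remaining volume count after dropping the pre-subtitle lead-in.

    ``floor(lead_in / tr)`` whole volumes are removed from the front; e.g.
    1805 volumes at TR 1 s minus a 61 s lead-in leaves 1744.
    """
    if lead_in < 0:
        raise ValueError("lead_in must be non-negative")
    if tr <= 0:
        raise ValueError("tr must be positive")
    dropped = math.floor(lead_in / tr + _EPS)
    if dropped > n_total_volumes:
        raise ValueError(
            f"lead-in of {lead_in} s ({dropped} volumes) exceeds the "
            f"{n_total_volumes} available volumes"
        )
    return n_total_volumes - dropped


def trim_lead_in(series: TRLabelSeries, lead_in: float) -> TRLabelSeries:
    """Drop the first ``floor(lead_in / tr)`` volumes from a label series."""
    n_keep = discard_lead_in(series.n_volumes, lead_in, series.tr)
    dropped = series.n_volumes - n_keep
    return TRLabelSeries(
        tr=series.tr,
        t_start=series.t_start + dropped * series.tr,
        labels=series.labels[dropped:].copy(),
        lead_in_discarded=dropped * series.tr,
    )
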