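"""Re-referencing, epoching, baseline correction and artifact rejection.

The stages mirror a conventional ERP preprocessing chain: common-average
(or electrode-pair) re-referencing of the continuous signal, segmentation
into stimulus-locked epochs over a half-open window, subtraction of the
pre-stimulus baseline mean, and automatic rejection of trials containing
samples beyond an absolute amplitude threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import EpochSet, Recording, ms_to_samples

logger = logging.getLogger(__name__)


def rereference(rec: Recording, scheme) -> Recording:
    """Re-reference a continuous recording.

    ``scheme`` is either the string ``"average"`` (subtract the per-sample
    mean of all channels) or a sequence of channel labels whose per-sample
    mean is subtracted (e.g. ``("P7", "P8")`` as a mastoid proxy).
    """
    if isinstance(scheme, str) and scheme == "average":
        ref = rec.signal.mean(axis=0)
        name = "average"
    else:
        labels = tuple(scheme)
        ref = rec.pick(labels).mean(axis=0)
        name = "mean(" + ",".join(labels) + ")"
    return rec.copy_with(signal=rec.signal - ref[None, :], reference=name)


def rereference_epochs(ep: EpochSet, scheme) -> EpochSet:
    """Per-sample re-referencing applied to already-epoched data."""
    if isinstance(scheme, str) and scheme == "average":
        ref = ep.data.mean(axis=1, keepdims=True)
        name = "average"
    else:
        labels = tuple(scheme)
        idx = ep.roi_indices(labels)
        ref = ep.data[:, idx, :].mean(axis=1, keepdims=True)
        name = "mean(" + ",".join(labels) + ")"
    out = ep.copy_with(data=ep.data - ref)
    out.meta = {**ep.meta, "reference": name}
    return out


def extract_epochs(
    rec: Recording,
    window_ms: tuple[float, float],
    label_filter: Iterable[str] | None = None,
) -> EpochSet:
    """Segment a recording into stimulus-locked epochs.

    Samples are taken over the half-open interval
    ``[onset + start_ms, onset + end_ms)``; the onset sample maps to t = 0.
    Events whose window would exceed the recording bounds are dropped and
    counted in ``meta["n_dropped"]`` (with a logged warning).
    """
    start_ms, end_ms = window_ms
    if not start_ms < 0 < end_ms:
        raise ValueError(f"window {window_ms} must span the stimulus onset")
    offset = ms_to_samples(start_ms, rec.fs)
    length = ms_to_samples(end_ms - start_ms, rec.fs)
    wanted = set(label_filter) if label_filter is not None else None

    data, labels = [], []
    n_dropped = 0
    for sample, label in rec.events:
        if wanted is not None and label not in wanted:
            continue
        lo = sample + offset
        hi = lo + length
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        data.append(rec.signal[:, lo:hi])
        labels.append(label)
    if n_dropped:
        logger.warning("dropped %d/%d epochs exceeding recording bounds",
                       n_dropped, n_dropped + len(data))
    if not data and wanted is not None:
        logger.warning("no events matched labels %s", sorted(wanted))
    arr = (np.stack(data) if data
           else np.empty((0, len(rec.channels), length)))
    return EpochSet(
        data=arr, fs=rec.fs, channels=rec.channels, window_ms=window_ms,
        conditions=np.array(labels, dtype=object),
        valid=np.ones(len(labels), dtype=bool),
        meta={"n_dropped": n_dropped, "reference": rec.reference},
    )


def baseline_correct(ep: EpochSet,
                     interval_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline interval."""
    lo_ms, hi_ms = interval_ms
    if lo_ms < ep.window_ms[0] - 1e-9 or hi_ms > ep.window_ms[1] + 1e-9:
        raise ValueError(f"baseline {interval_ms} outside epoch window {ep.window_ms}")
    t = ep.times_ms
    mask = (t >= lo_ms) & (t <= hi_ms)
    if not mask.any():
        raise ValueError(f"baseline {interval_ms} contains no samples")
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    out = ep.copy_with(data=ep.data - base, baseline_interval_ms=tuple(interval_ms))
    return out


@dataclass
class RejectionReport:
    """Outcome of threshold-based artifact rejection."""

    threshold_uV: float
    n_total: int
    n_rejected: int
    retained_by_condition: dict
    rejected_indices: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_rejected


def reject_artifacts(ep: EpochSet, threshold_uV: float) -> tuple[EpochSet, RejectionReport]:
    """Invalidate trials containing any sample beyond ``±threshold_uV``.

    Already-invalid trials stay invalid.  Rejection is monotone in the
    threshold: raising it never invalidates a previously valid trial.
    """
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    exceeded = np.abs(ep.data).max(axis=(1, 2)) > threshold_uV
    new_valid = ep.valid & ~exceeded
    rejected = np.flatnonzero(ep.valid & exceeded)
    retained: dict = {}
    for cond in np.unique(ep.conditions.astype(str)):
        sel = ep.conditions.astype(str) == cond
        retained[cond] = int((new_valid & sel).sum())
    if new_valid.sum() == 0:
        logger.warning("artifact rejection at ±%g uV left no valid trials",
                       threshold_uV)
    report = RejectionReport(threshold_uV, ep.n_trials, len(rejected),
                             retained, rejected)
    return ep.copy_with(valid=new_valid), report


def select_trials(ep: EpochSet, condition: str | Sequence[str] | None = None) -> np.ndarray:
    """Boolean mask of valid trials, optionally restricted to condition(s)."""
    mask = ep.valid.copy()
    if condition is not None:
        labels = {condition} if isinstance(condition, str) else set(condition)
        mask &= np.isin(ep.conditions.astype(str), sorted(labels))
    return mask
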