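"""Caller-combination statuses, the Venn partition, and set-operation combiners.

With K callers every ascertained site falls into exactly one of the
``2^K - 1`` non-empty detection patterns ("combination call statuses").
This partition carries the per-subset validation statistics that drive the
cumulative combined caller, and also defines the naive set-operation
combiners (intersections, unions, at-least-m-of-K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from callstack.data_model import CallDataset, DataError


@dataclass(frozen=True, order=True)
class ComboStatus:
    """One of the 2^K - 1 non-zero caller detection patterns."""

    mask: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if not any(self.mask):
            raise DataError("all-zero combination status cannot occur under union ascertainment")
        if not set(self.mask) <= {0, 1}:
            raise DataError(f"mask must be binary, got {self.mask}")


def combo_status(call_row: Sequence[int], caller_names: Sequence[str]) -> ComboStatus:
    """Map one site's K-vector of calls to its combination status.

    The canonical label joins the detecting callers' names with '+' in
    input caller order, e.g. ``(1, 0, 1)`` with callers A, B, C -> "A+C".
    """
    mask = tuple(int(c) for c in call_row)
    if len(mask) != len(caller_names):
        raise DataError("call row length does not match number of callers")
    label = "+".join(name for name, c in zip(caller_names, mask) if c)
    return ComboStatus(mask=mask, label=label)


def all_statuses(caller_names: Sequence[str]) -> list[ComboStatus]:
    """All 2^K - 1 statuses, ordered from all-callers down by mask as a binary number."""
    K = len(caller_names)
    masks = sorted(range(1, 2**K), reverse=True)
    out = []
    for m in masks:
        row = tuple((m >> (K - 1 - k)) & 1 for k in range(K))
        out.append(combo_status(row, caller_names))
    return out


@dataclass(frozen=True)
class SubsetStats:
    """Validation statistics of one combination-status subset.

    ``val_rate`` is the percentage of the subset confirmed somatic,
    ``None`` when the subset is empty. Full precision is kept; rounding
    to one decimal is display-only.
    """

    status: ComboStatus
    n_fp: int
    n_tp: int

    def __post_init__(self) -> None:
        if self.n_fp < 0 or self.n_tp < 0:
            raise DataError("counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_fp + self.n_tp

    @property
    def val_rate(self) -> float | None:
        if self.size == 0:
            return None
        return 100.0 * self.n_tp / self.size


def partition_stats(dataset: CallDataset) -> list[SubsetStats]:
    """Per-status FP/TP counts and validation rates over the full partition.

    All 2^K - 1 statuses are reported, empty ones included (a test set may
    lack statuses present in training). Counts across statuses sum to n.
    """
    if dataset.labels is None:
        raise DataError("partition_stats requires validation labels")
    statuses = all_statuses(dataset.caller_names)
    index = {s.mask: s for s in statuses}
    fp = {s.mask: 0 for s in statuses}
    tp = {s.mask: 0 for s in statuses}
    for row, y in zip(dataset.calls, dataset.labels):
        mask = tuple(int(c) for c in row)
        if y:
            tp[mask] += 1
        else:
            fp[mask] += 1
    out = [SubsetStats(status=index[m], n_fp=fp[m], n_tp=tp[m]) for m in index]
    assert sum(s.size for s in out) == dataset.n
    return out


def stats_from_counts(
    counts: Iterable[tuple[Sequence[int], int, int]], caller_names: Sequence[str]
) -> list[SubsetStats]:
    """Build SubsetStats directly from published (mask, n_fp, n_tp) triples."""
    given = {tuple(int(c) for c in mask): (int(n_fp), int(n_tp)) for mask, n_fp, n_tp in counts}
    out = []
    for status in all_statuses(caller_names):
        n_fp, n_tp = given.get(status.mask, (0, 0))
        out.append(SubsetStats(status=status, n_fp=n_fp, n_tp=n_tp))
    return out


def set_operation_caller(
    dataset: CallDataset,
    rule: str = "intersection",
    callers: Sequence[str] | None = None,
    min_callers: int | None = None,
) -> np.ndarray:
    """Predicted calls of a set-operation combined caller.

    rule:
        ``"intersection"`` — call iff every caller in ``callers`` detected
        the site; ``"union"`` — call iff any did; ``"at_least"`` — call iff
        at least ``min_callers`` of all K callers detected it.
    """
    if rule == "at_least":
        if min_callers is None or not (1 <= min_callers <= dataset.n_callers):
            raise DataError(f"min_callers must lie in [1, {dataset.n_callers}]")
        return (dataset.calls.sum(axis=1) >= min_callers).astype(np.int8)
    idx = [dataset.caller_index(c) for c in (callers or dataset.caller_names)]
    if not idx:
        raise DataError("caller subset must be non-empty")
    sub = dataset.calls[:, idx]
    if rule == "intersection":
        return sub.all(axis=1).astype(np.int8)
    if rule == "union":
        return sub.any(axis=1).astype(np.int8)
    raise DataError(f"unknown rule {rule!r}; expected intersection, union, or at_least")
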