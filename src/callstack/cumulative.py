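"""The cumulative combined caller: sort Venn subsets by validation rate, add them in order.

Ordering the ``2^K - 1`` disjoint combination-status subsets by their
training-set validation rate defines a sequence of combined callers of
decreasing stringency: the most stringent calls only the top subset, and
each prefix of the order is one caller. Evaluated on a test partition,
the prefix (cumulative FP rate, cumulative TP rate) pairs trace a
step-wise ROC curve ending at (100, 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from callstack.data_model import DataError
from callstack.venn import ComboStatus, SubsetStats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetOrdering:
    """A stringency order over all combination statuses, with the training rates behind it."""

    ordered_statuses: tuple[ComboStatus, ...]
    train_val_rates: tuple[float | None, ...]

    def __post_init__(self) -> None:
        rates = [r for r in self.train_val_rates if r is not None]
        if any(a < b for a, b in zip(rates, rates[1:])):
            raise DataError("training validation rates must be non-increasing along the order")


def order_by_validation_rate(train_stats: list[SubsetStats], near_tie_epsilon: float = 0.5) -> SubsetOrdering:
    """Sort subsets by training validation rate, descending.

    Ties are broken by larger subset size first (a larger subset gives a
    more reliable rate estimate), then by label lexicographic order. Empty
    subsets carry no rate estimate and go last, label-lexicographic.
    Training rates within ``near_tie_epsilon`` percentage points of each
    other are logged as near-ties: the learned order is then fragile and
    may not transfer to a test set.
    """
    non_empty = [s for s in train_stats if s.size > 0]
    empty = [s for s in train_stats if s.size == 0]
    non_empty.sort(key=lambda s: (-s.val_rate, -s.size, s.status.label))
    empty.sort(key=lambda s: s.status.label)
    ordered = non_empty + empty
    for a, b in zip(non_empty, non_empty[1:]):
        if abs(a.val_rate - b.val_rate) < near_tie_epsilon:
            logger.warning(
                "near-tie in training validation rates: %s (%.2f%%) vs %s (%.2f%%); "
                "ordering may not be stable between training and test data",
                a.status.label, a.val_rate, b.status.label, b.val_rate,
            )
    return SubsetOrdering(
        ordered_statuses=tuple(s.status for s in ordered),
        train_val_rates=tuple(s.val_rate for s in ordered),
    )


def cumulative_rates(ordering: SubsetOrdering, test_stats: list[SubsetStats]) -> list[tuple[float, float]]:
    """Cumulative (FP rate, TP rate) percent pairs, one per prefix of the order.

    Prefix m covers the first m subsets of the ordering; its rates are the
    FP/TP counts accumulated over those subsets divided by the test-set
    union totals. The full prefix is always (100, 100).
    """
    by_mask = {s.status.mask: s for s in test_stats}
    missing = [st.label for st in ordering.ordered_statuses if st.mask not in by_mask]
    if missing:
        raise DataError(f"test statistics missing statuses {missing}")
    total_fp = sum(s.n_fp for s in test_stats)
    total_tp = sum(s.n_tp for s in test_stats)
    if total_fp == 0 or total_tp == 0:
        raise DataError("cumulative rates undefined: test data must contain both classes")
    out = []
    cum_fp = cum_tp = 0
    for status in ordering.ordered_statuses:
        s = by_mask[status.mask]
        cum_fp += s.n_fp
        cum_tp += s.n_tp
        out.append((100.0 * cum_fp / total_fp, 100.0 * cum_tp / total_tp))
    assert out[-1] == (100.0, 100.0)
    return out
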