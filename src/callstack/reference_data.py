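"""Published validation counts from the motivating three-caller study.

The TCGA endometrial validation exercise reported, for the whole-exome
calls of 20 patients, the false/true positive counts of each of the seven
caller-combination subsets (callers anonymized as A, B, C). These seven
(status, FP count, TP count) triples are the canonical worked example for
the Venn partition and the cumulative combined caller: 977 false and
3,461 true positives over 4,438 union-ascertained sites, a 78.0%
validation rate overall.
"""

from __future__ import annotations

from callstack.venn import SubsetStats, stats_from_counts

#: Caller identifiers, in the order the masks below refer to.
ENDOMETRIAL_CALLERS = ("A", "B", "C")

#: (mask over A,B,C; FP count; TP count), in decreasing validation rate.
ENDOMETRIAL_SUBSET_COUNTS: tuple[tuple[tuple[int, int, int], int, int], ...] = (
    ((1, 1, 1), 12, 1914),   # all three callers
    ((1, 0, 1), 11, 294),    # A and C only
    ((1, 1, 0), 7, 184),     # A and B only
    ((0, 1, 1), 2, 34),      # B and C only
    ((0, 0, 1), 11, 43),     # C only
    ((1, 0, 0), 632, 935),   # A only
    ((0, 1, 0), 302, 57),    # B only
)


def endometrial_subset_stats() -> list[SubsetStats]:
    """The published seven-subset counts as :class:`SubsetStats`."""
    return stats_from_counts(ENDOMETRIAL_SUBSET_COUNTS, ENDOMETRIAL_CALLERS)


def endometrial_marginal_counts(caller: str) -> tuple[int, int]:
    """(FP, TP) counts of one caller: the sum over subsets containing it."""
    k = ENDOMETRIAL_CALLERS.index(caller)
    fp = sum(n_fp for mask, n_fp, _ in ENDOMETRIAL_SUBSET_COUNTS if mask[k])
    tp = sum(n_tp for mask, _, n_tp in ENDOMETRIAL_SUBSET_COUNTS if mask[k])
    return fp, tp
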