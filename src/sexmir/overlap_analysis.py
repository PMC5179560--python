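"""Directional gene-list overlap by one-sided hypergeometric (Fisher) tests.

Two differential lists drawn from a fixed candidate universe of size N are
compared by the enrichment tail of the hypergeometric distribution: with
list sizes n_A and n_B and observed intersection k, the p-value is
P(X >= k) for X ~ Hypergeometric(N, n_A, n_B).  The universe is held fixed
across all comparisons of an assay (e.g. all candidate mRNAs or all
candidate miRs that entered differential analysis).  No multiple-testing
correction is applied across the pairwise family; raw p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from scipy import stats


@dataclass
class OverlapResult:
    """One pairwise directional-list comparison against a fixed background."""

    name_a: str
    name_b: str
    n_a: int
    n_b: int
    background: int
    intersection: list[str]
    p_value: float

    @property
    def k(self) -> int:
        return len(self.intersection)

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.background

    def as_row(self) -> dict:
        return {
            "list_a": self.name_a,
            "list_b": self.name_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "background": self.background,
            "k": self.k,
            "expected": self.expected,
            "p_value": self.p_value,
            "members": ",".join(sorted(self.intersection)),
        }


def fisher_overlap(n_a: int, n_b: int, k: int, background: int) -> float:
    """Enrichment p-value P(X >= k), X ~ Hypergeometric(N=background, n_a, n_b)."""
    if n_a > background or n_b > background:
        raise ValueError(
            f"list sizes ({n_a}, {n_b}) cannot exceed background {background}"
        )
    if k > min(n_a, n_b):
        raise ValueError(f"intersection {k} exceeds min list size {min(n_a, n_b)}")
    if k < 0 or n_a < 0 or n_b < 0 or background <= 0:
        raise ValueError("sizes must be non-negative and background positive")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, background, n_a, n_b))


def pairwise_overlaps(
    lists: Mapping[str, Sequence[str]],
    background: int,
    pairs: Sequence[tuple[str, str]] | None = None,
    universe: set[str] | None = None,
) -> list[OverlapResult]:
    """All (or selected) unordered pairwise overlaps among named directional lists.

    Lists are deduplicated.  By default every unordered pair of the supplied
    lists is tested — covering both same-direction (upA vs upB, downA vs
    downB) and opposite-direction comparisons when both sexes' up and down
    lists are supplied.  Pass ``pairs`` to restrict to an explicit selection.
    Output order is lexicographic in the pair names, hence deterministic.
    """
    sets = {name: set(members) for name, members in lists.items()}
    if universe is not None:
        for name, members in sets.items():
            stray = members - universe
            if stray:
                raise ValueError(
                    f"list {name!r} has members outside the universe: {sorted(stray)[:5]}"
                )
    for name, members in sets.items():
        if len(members) > background:
            raise ValueError(f"list {name!r} larger than background {background}")
    if pairs is None:
        pairs = list(combinations(sorted(sets), 2))
    results = []
    for a, b in sorted(tuple(sorted(p)) for p in pairs):
        if a not in sets or b not in sets:
            missing = a if a not in sets else b
            raise KeyError(f"unknown list {missing!r} in pair selection")
        inter = sorted(sets[a] & sets[b])
        p = fisher_overlap(len(sets[a]), len(sets[b]), len(inter), background)
        results.append(OverlapResult(a, b, len(sets[a]), len(sets[b]), background, inter, p))
    return results
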