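"""Fisher's-exact overrepresentation of a query gene list in named gene sets.

A generic ORA core: for each set in a GMT collection, the overlap between
the query list and the set (both restricted to an analysis universe) is
tested with the one-sided hypergeometric tail, and a term is flagged
significant when -log10(p) >= 1.3 (i.e. p <= 0.05).  BH-adjusted p-values
are reported alongside but the raw -log10 rule is the significance flag.
The default universe is the filtered differential-analysis universe rather
than the whole genome — standard ORA practice when the query derives from
that universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sexmir.io_formats import GeneSetCollection
from sexmir.mir_target_network import bh_adjust
from sexmir.overlap_analysis import fisher_overlap


@dataclass
class EnrichmentResult:
    set_name: str
    set_size_in_universe: int
    query_size: int
    overlap: list[str]
    p_value: float
    p_adjusted: float

    @property
    def k(self) -> int:
        return len(self.overlap)

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf

    @property
    def significant(self) -> bool:
        return self.neg_log10_p >= 1.3

    def as_row(self) -> dict:
        return {
            "set_name": self.set_name,
            "set_size_in_universe": self.set_size_in_universe,
            "query_size": self.query_size,
            "overlap_size": self.k,
            "p_value": self.p_value,
            "neg_log10_p": self.neg_log10_p,
            "significant": self.significant,
            "p_adjusted": self.p_adjusted,
            "overlap_members": ",".join(sorted(self.overlap)),
        }


def overrepresentation_test(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of ``query`` in each gene set.

    Query members outside the universe are dropped with a warning; results
    are sorted by p-value then set name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    stray = q - uni
    if stray:
        warnings.warn(
            f"{len(stray)} query genes outside the universe were dropped "
            f"(e.g. {sorted(stray)[:3]})"
        )
        q &= uni
    N = len(uni)
    results = []
    for name, members in sets.sets.items():
        in_uni = members & uni
        if not in_uni:
            continue
        overlap = sorted(in_uni & q)
        p = fisher_overlap(len(in_uni), len(q), len(overlap), N)
        results.append(EnrichmentResult(name, len(in_uni), len(q), overlap, p, np.nan))
    if results:
        adjusted, _ = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adjusted):
            r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
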