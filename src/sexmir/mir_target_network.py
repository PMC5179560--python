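"""Per-miR target-direction enrichment and anti-correlated network assembly.

This is the bespoke integration step of the pipeline.  For each
differentially expressed miR (per sex), the direction composition of its
predicted targets — how many are up, down, or neutral in the same-sex stress
contrast — is compared by a chi-squared goodness-of-fit test against the
direction composition of the whole analyzed transcriptome.  miRs whose
targets deviate from background survive a Benjamini-Hochberg selection at
alpha = 0.05 (family = all tested miRs within one sex).  Each surviving
miR's differentially expressed targets become network edges, signed by the
direction rule: negative association when miR and target move in opposite
directions (the canonical repressive relationship), positive when they move
together.  Neutral targets never enter the network.

Target sets come from the intersection of >= 2 prediction sources, restricted
to the filtered analysis universe so that target and background direction
frequencies are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sexmir.differential_expression import DEResult
from sexmir.io_formats import TargetPredictionTable

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "neutral")


# ---------------------------------------------------------------------------
# Target map
# ---------------------------------------------------------------------------


def intersect_target_sources(
    predictions: TargetPredictionTable,
    required_sources: list[str],
    universe: set[str] | None = None,
) -> dict[str, set[str]]:
    """(mir, gene) pairs predicted by *every* required source.

    Optionally restricted to the differential-analysis universe, which is
    required downstream for direction frequencies to be comparable with the
    background.  Raises if a required source is absent from the table.
    """
    if len(required_sources) < 1:
        raise ValueError("at least one required source must be named")
    available = set(predictions.sources)
    for src in required_sources:
        if src not in available:
            raise ValueError(f"required source {src!r} not present in prediction table")
    per_source = [predictions.targets_by_source(src) for src in required_sources]
    mirs = set(per_source[0])
    for maps in per_source[1:]:
        mirs &= set(maps)
    out: dict[str, set[str]] = {}
    for mir in mirs:
        targets = set(per_source[0][mir])
        for maps in per_source[1:]:
            targets &= maps[mir]
        if universe is not None:
            targets &= universe
        if targets:
            out[mir] = targets
    return out


# ---------------------------------------------------------------------------
# Chi-squared direction-frequency enrichment
# ---------------------------------------------------------------------------


def background_frequencies(de: DEResult, contrast: str) -> tuple[int, int, int]:
    """(n_up, n_down, n_neutral) over every analyzed feature for one contrast."""
    dirs = de.directions(contrast)
    n_up = int((dirs == "up").sum())
    n_down = int((dirs == "down").sum())
    n_neutral = int((dirs == "neutral").sum())
    return n_up, n_down, n_neutral


@dataclass
class ChiSqEnrichment:
    """Per-miR chi-squared goodness-of-fit of target directions vs background."""

    mir_id: str
    mir_direction: str
    observed: tuple[int, int, int]  # up, down, neutral
    expected: tuple[float, float, float]
    chi2: float
    p_value: float
    low_expected: bool  # any expected cell < 1
    p_adjusted: float = np.nan
    survives: bool = False

    @property
    def n_targets(self) -> int:
        return int(sum(self.observed))

    def as_row(self) -> dict:
        return {
            "mir_id": self.mir_id,
            "mir_direction": self.mir_direction,
            "targets_up": self.observed[0],
            "targets_down": self.observed[1],
            "targets_neutral": self.observed[2],
            "expected_up": self.expected[0],
            "expected_down": self.expected[1],
            "expected_neutral": self.expected[2],
            "chi2": self.chi2,
            "p_value": self.p_value,
            "low_expected": self.low_expected,
            "p_adjusted": self.p_adjusted,
            "survives": self.survives,
        }


def chi_squared_target_enrichment(
    targets: dict[str, set[str]],
    de: DEResult,
    contrast: str,
    mir_directions: pd.Series,
    background: tuple[int, int, int] | None = None,
    min_targets: int = 5,
    mode: str = "goodness_of_fit",
) -> list[ChiSqEnrichment]:
    """Chi-squared tests of target direction frequencies against background.

    Run only for differentially expressed miRs (``mir_directions`` maps miR id
    to its own up/down call; neutral miRs are not tested).  Each tested miR
    needs at least ``min_targets`` targets inside the analysis universe; miRs
    with no in-universe targets are excluded with a warning.  ``mode``
    selects the default goodness-of-fit test (expected counts proportional to
    background frequencies, df = 2) or a 2x3 ``contingency`` variant of
    targets vs the rest of the universe.
    """
    if mode not in ("goodness_of_fit", "contingency"):
        raise ValueError(f"unknown mode {mode!r}")
    if background is None:
        background = background_frequencies(de, contrast)
    bg = np.asarray(background, dtype=float)
    if bg.sum() <= 0:
        raise ValueError("empty background")
    dirs = de.directions(contrast)
    universe = set(dirs.index)

    results: list[ChiSqEnrichment] = []
    for mir, direction in mir_directions.items():
        if direction not in ("up", "down"):
            continue
        tset = targets.get(mir, set()) & universe
        if not tset:
            warnings.warn(f"miR {mir!r} has no targets in the analysis universe; excluded")
            continue
        if len(tset) < min_targets:
            logger.info("miR %s has %d < %d in-universe targets; skipped", mir, len(tset), min_targets)
            continue
        tdirs = dirs.loc[sorted(tset)]
        obs = np.array(
            [(tdirs == "up").sum(), (tdirs == "down").sum(), (tdirs == "neutral").sum()],
            dtype=float,
        )
        if mode == "goodness_of_fit":
            exp = obs.sum() * bg / bg.sum()
            chi2 = float(((obs - exp) ** 2 / exp).sum())
            p = float(stats.chi2.sf(chi2, df=2))
        else:
            rest = bg - obs
            table = np.vstack([obs, rest])
            chi2, p, _, exp2 = stats.chi2_contingency(table, correction=False)
            exp = exp2[0]
            chi2, p = float(chi2), float(p)
        results.append(
            ChiSqEnrichment(
                mir_id=mir,
                mir_direction=direction,
                observed=(int(obs[0]), int(obs[1]), int(obs[2])),
                expected=(float(exp[0]), float(exp[1]), float(exp[2])),
                chi2=chi2,
                p_value=p,
                low_expected=bool((exp < 1).any()),
            )
        )
    results.sort(key=lambda r: r.mir_id)
    return results


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags.

    adjusted_(i) = min over j >= i of p_(j) * m / j, capped at 1 (cumulative
    minimum from the largest rank down); reject iff adjusted < alpha.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


def select_surviving(
    enrichments: list[ChiSqEnrichment], alpha: float = 0.05
) -> list[ChiSqEnrichment]:
    """BH selection across all tested miRs of one sex; annotates in place."""
    if not enrichments:
        return []
    adjusted, reject = bh_adjust([e.p_value for e in enrichments], alpha)
    for e, a, r in zip(enrichments, adjusted, reject):
        e.p_adjusted = float(a)
        e.survives = bool(r)
    return [e for e in enrichments if e.survives]


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


@dataclass
class MiRGeneNetwork:
    """Bipartite signed miR-gene network.

    ``mir_nodes`` / ``gene_nodes`` map id -> (direction, log2FC); ``edges``
    are (mir, gene, association) with association ``negative`` iff the two
    directions are opposite.  Only differentially expressed nodes appear.
    """

    mir_nodes: dict[str, tuple[str, float]] = field(default_factory=dict)
    gene_nodes: dict[str, tuple[str, float]] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def iter_edges(self):
        return iter(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        for mir, gene, assoc in self.edges:
            if mir not in self.mir_nodes or gene not in self.gene_nodes:
                raise ValueError(f"edge ({mir}, {gene}) references a missing node")
            md, gd = self.mir_nodes[mir][0], self.gene_nodes[gene][0]
            if md == "neutral" or gd == "neutral":
                raise ValueError(f"edge ({mir}, {gene}) touches a neutral node")
            expect = "negative" if md != gd else "positive"
            if assoc != expect:
                raise ValueError(
                    f"edge ({mir}, {gene}) association {assoc!r} inconsistent with "
                    f"directions ({md}, {gd})"
                )


def classify_associations(
    surviving: list[ChiSqEnrichment],
    targets: dict[str, set[str]],
    de: DEResult,
    contrast: str,
) -> MiRGeneNetwork:
    """Signed edges from surviving miRs to their differentially expressed targets.

    Association is negative when the miR and target directions are opposite
    (canonical repression), positive when equal; neutral targets are dropped.
    """
    dirs = de.directions(contrast)
    lfc = de.log2fc(contrast)
    net = MiRGeneNetwork()
    for e in surviving:
        assert e.mir_direction in ("up", "down"), "surviving miR must be DE"
        mir_lfc = np.nan
        net.mir_nodes[e.mir_id] = (e.mir_direction, mir_lfc)
        for gene in sorted(targets.get(e.mir_id, set())):
            if gene not in dirs.index:
                continue
            gdir = dirs.loc[gene]
            if gdir == "neutral":
                continue
            net.gene_nodes[gene] = (gdir, float(lfc.loc[gene]))
            assoc = "negative" if gdir != e.mir_direction else "positive"
            net.edges.append((e.mir_id, gene, assoc))
    net.edges.sort()
    return net


def annotate_mir_log2fc(net: MiRGeneNetwork, mir_de: DEResult, contrast: str) -> None:
    """Fill miR node log2FCs from the miR differential results."""
    lfc = mir_de.log2fc(contrast)
    for mir, (direction, _) in net.mir_nodes.items():
        if mir in lfc.index:
            net.mir_nodes[mir] = (direction, float(lfc.loc[mir]))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class NetworkSummary:
    """Pie-chart style composition of a sex's miR-gene network.

    Fractions are relative to the sex's DE gene / DE miR list sizes; the
    association and multiplicity partitions are over targeted genes only.
    """

    n_de_genes: int
    n_genes_targeted: int
    genes_negative_only: int
    genes_positive_only: int
    genes_both: int
    genes_by_one_mir: int
    genes_by_multiple_mirs: int
    n_de_mirs: int
    n_mirs_surviving: int

    @property
    def fraction_genes_targeted(self) -> float:
        return self.n_genes_targeted / self.n_de_genes if self.n_de_genes else 0.0

    @property
    def fraction_mirs_surviving(self) -> float:
        return self.n_mirs_surviving / self.n_de_mirs if self.n_de_mirs else 0.0

    def validate(self) -> None:
        assert self.genes_negative_only + self.genes_positive_only + self.genes_both == self.n_genes_targeted
        assert self.genes_by_one_mir + self.genes_by_multiple_mirs == self.n_genes_targeted
        assert self.n_genes_targeted <= self.n_de_genes
        assert self.n_mirs_surviving <= self.n_de_mirs

    def as_row(self) -> dict:
        return {
            "n_de_genes": self.n_de_genes,
            "n_genes_targeted": self.n_genes_targeted,
            "fraction_genes_targeted": self.fraction_genes_targeted,
            "genes_negative_only": self.genes_negative_only,
            "genes_positive_only": self.genes_positive_only,
            "genes_both": self.genes_both,
            "genes_by_one_mir": self.genes_by_one_mir,
            "genes_by_multiple_mirs": self.genes_by_multiple_mirs,
            "n_de_mirs": self.n_de_mirs,
            "n_mirs_surviving": self.n_mirs_surviving,
            "fraction_mirs_surviving": self.fraction_mirs_surviving,
        }


def summarize_network(
    network: MiRGeneNetwork,
    de: DEResult,
    contrast: str,
    surviving: list[ChiSqEnrichment],
    n_de_mirs: int,
) -> NetworkSummary:
    """Targeted-gene and surviving-miR composition of one sex's network."""
    dirs = de.directions(contrast)
    n_de_genes = int(((dirs == "up") | (dirs == "down")).sum())
    assoc_by_gene: dict[str, set[str]] = {}
    mirs_by_gene: dict[str, set[str]] = {}
    for mir, gene, assoc in network.iter_edges():
        assoc_by_gene.setdefault(gene, set()).add(assoc)
        mirs_by_gene.setdefault(gene, set()).add(mir)
    targeted = sorted(assoc_by_gene)
    neg_only = sum(1 for g in targeted if assoc_by_gene[g] == {"negative"})
    pos_only = sum(1 for g in targeted if assoc_by_gene[g] == {"positive"})
    both = sum(1 for g in targeted if len(assoc_by_gene[g]) == 2)
    one = sum(1 for g in targeted if len(mirs_by_gene[g]) == 1)
    multi = sum(1 for g in targeted if len(mirs_by_gene[g]) >= 2)
    summary = NetworkSummary(
        n_de_genes=n_de_genes,
        n_genes_targeted=len(targeted),
        genes_negative_only=neg_only,
        genes_positive_only=pos_only,
        genes_both=both,
        genes_by_one_mir=one,
        genes_by_multiple_mirs=multi,
        n_de_mirs=n_de_mirs,
        n_mirs_surviving=len(surviving),
    )
    summary.validate()
    return summary


def negative_subnetwork(network: MiRGeneNetwork) -> MiRGeneNetwork:
    """The rendering default: only canonical negative (repressive) edges."""
    edges = [e for e in network.edges if e[2] == "negative"]
    mirs = {m for m, _, _ in edges}
    genes = {g for _, g, _ in edges}
    return MiRGeneNetwork(
        {m: network.mir_nodes[m] for m in sorted(mirs)},
        {g: network.gene_nodes[g] for g in sorted(genes)},
        edges,
    )
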