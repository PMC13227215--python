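"""DEG set algebra and biotype (lncRNA) enrichment.

Core sets are intersections of per-diet DEG lists within a stock ("always
differentially expressed on any protein/lipid diet"); Venn accounting
compares the two stocks' core sets; enrichment asks whether a biotype such
as lncRNA is over-represented in a DEG set relative to the post-filter gene
universe, via a 2x2 chi-square test (no continuity correction by default,
with a Fisher exact fallback when expected cells are small).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DEGSet:
    """A named set of differentially expressed genes with optional signs."""

    name: str
    genes: set[str]
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.directions) - self.genes
        if extra:
            raise ValueError(f"directions for genes outside the set: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


class VennCounts(NamedTuple):
    only_a: int
    only_b: int
    shared: int
    union: int


@dataclass
class EnrichmentResult:
    """2x2 biotype enrichment: chi-square statistic, p, and direction."""

    table: np.ndarray  # rows: in target / not; cols: biotype / not
    chi2: float
    p: float
    direction: str  # "enriched" or "depleted"
    fisher_p: float | None = None  # reported when an expected cell < 1


def intersect_core(degsets: Sequence[DEGSet]) -> DEGSet:
    """Genes present in every input set (e.g. DEGs on all three PL diets)."""
    if len(degsets) < 2:
        raise ValueError("need at least two DEG sets to intersect")
    genes = set.intersection(*(s.genes for s in degsets))
    name = " & ".join(s.name for s in degsets)
    directions = {
        g: degsets[0].directions[g]
        for g in genes
        if g in degsets[0].directions
    }
    return DEGSet(name=name, genes=genes, directions=directions)


def union_sets(degsets: Sequence[DEGSet]) -> DEGSet:
    genes = set.union(*(s.genes for s in degsets))
    name = " | ".join(s.name for s in degsets)
    return DEGSet(name=name, genes=genes)


def venn_counts(a: DEGSet, b: DEGSet) -> VennCounts:
    shared = len(a.genes & b.genes)
    return VennCounts(
        only_a=len(a.genes) - shared,
        only_b=len(b.genes) - shared,
        shared=shared,
        union=len(a.genes) + len(b.genes) - shared,
    )


def biotype_enrichment(
    target: DEGSet,
    background: pd.Series,
    biotype: str = "lncRNA",
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Chi-square test of ``biotype`` over-representation in ``target``.

    ``background`` maps every gene in the universe (typically the
    post-filter gene list) to its biotype; the target set must be contained
    in it.
    """
    universe = set(background.index)
    if not target.genes <= universe:
        missing = sorted(target.genes - universe)[:5]
        raise ValueError(f"target genes missing from background: {missing}")
    is_bio = background == biotype
    if is_bio.all() or not is_bio.any():
        raise ValueError(f"background must contain both {biotype!r} and other genes")
    in_target = background.index.isin(target.genes)
    table = np.array(
        [
            [int((in_target & is_bio).sum()), int((in_target & ~is_bio).sum())],
            [int((~in_target & is_bio).sum()), int((~in_target & ~is_bio).sum())],
        ]
    )
    chi2, p, _, expected = stats.chi2_contingency(
        table, correction=continuity_correction
    )
    fisher_p = None
    if (expected < 1).any():
        fisher_p = float(stats.fisher_exact(table)[1])
    direction = "enriched" if table[0, 0] > expected[0, 0] else "depleted"
    return EnrichmentResult(
        table=table, chi2=float(chi2), p=float(p), direction=direction, fisher_p=fisher_p
    )
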