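"""Cross-dataset meta-analysis of bimodal gene sets.

Bimodal calls made independently in several cohorts are compared by (a)
pairwise intersection within the genes shared by both platforms, scored by a
one-sided hypergeometric (Fisher exact) test, and (b) a "commonly bimodal"
call for genes bimodal in at least *k* datasets.  The same hypergeometric
tail also scores enrichment of a gene list against an annotation set (e.g.
disease genes, drug targets) within a fixed gene universe.  Tail sums are
accumulated in log space so that magnitudes around 1e-112 stay exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """A 2x2 overlap and its one-sided hypergeometric p-value."""

    list_size: int
    annotation_size: int
    overlap: int
    universe: int
    p_value: float
    alternative: str = "greater"


@dataclass
class IntersectionRecord:
    """Pairwise comparison of two datasets' bimodal calls on their shared genes."""

    set_a: str
    set_b: str
    shared_universe: int
    bimodal_a: int
    bimodal_b: int
    overlap: int
    p_value: float | None


def hypergeom_enrichment(
    list_size: int,
    annotation_size: int,
    overlap: int,
    universe: int,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Exact hypergeometric test of an overlap between two sets in a universe.

    ``alternative="greater"`` (default, the over-representation reading of
    the Fisher exact test) returns P(X >= overlap) where X is the overlap of
    a random *list_size*-subset with the annotation; ``"two-sided"`` sums all
    point masses not exceeding the observed one.
    """
    if min(list_size, annotation_size, overlap, universe) < 0:
        raise ValidationError("counts must be non-negative")
    if overlap > min(list_size, annotation_size):
        raise ValidationError("overlap exceeds one of the set sizes")
    if max(list_size, annotation_size) > universe:
        raise ValidationError("set larger than the universe")
    if overlap < list_size + annotation_size - universe:
        raise ValidationError("overlap below its feasible minimum")

    lo = max(0, list_size + annotation_size - universe)
    hi = min(list_size, annotation_size)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, universe, annotation_size, list_size)

    if alternative == "greater":
        if overlap == lo:
            p = 1.0
        else:
            p = float(np.exp(logsumexp(logpmf[support >= overlap])))
    elif alternative == "two-sided":
        obs = logpmf[support == overlap][0]
        # standard Fisher convention: sum all outcomes no more likely than observed
        p = float(np.exp(logsumexp(logpmf[logpmf <= obs + 1e-12])))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    return EnrichmentResult(
        list_size=list_size,
        annotation_size=annotation_size,
        overlap=overlap,
        universe=universe,
        p_value=p,
        alternative=alternative,
    )


def _norm_set(genes) -> set[str]:
    return {str(g).strip().upper() for g in genes}


def pairwise_intersections(
    bimodal_sets: dict[str, set[str]],
    platform_genes: dict[str, set[str]],
) -> list[IntersectionRecord]:
    """Pairwise overlap of bimodal calls restricted to each pair's shared genes.

    For every unordered dataset pair the universe is the intersection of the
    two platforms' gene complements; each bimodal set is restricted to that
    universe before counting the overlap and computing the one-sided
    hypergeometric p-value.  Genes absent from a platform are "not assayed",
    never "not bimodal".
    """
    if len(bimodal_sets) < 2:
        raise ValidationError("need at least 2 datasets")
    missing = set(bimodal_sets) - set(platform_genes)
    if missing:
        raise ValidationError(f"no platform gene list for dataset(s): {sorted(missing)}")
    records = []
    for a, b in combinations(bimodal_sets, 2):
        shared = _norm_set(platform_genes[a]) & _norm_set(platform_genes[b])
        ba = _norm_set(bimodal_sets[a]) & shared
        bb = _norm_set(bimodal_sets[b]) & shared
        ov = len(ba & bb)
        if not shared:
            logger.warning("datasets %s/%s share no genes; p-value undefined", a, b)
            p = None
        else:
            p = hypergeom_enrichment(len(ba), len(bb), ov, len(shared)).p_value
        records.append(IntersectionRecord(
            set_a=a, set_b=b, shared_universe=len(shared),
            bimodal_a=len(ba), bimodal_b=len(bb), overlap=ov, p_value=p,
        ))
    return records


def commonly_bimodal(
    bimodal_sets: dict[str, set[str]], min_datasets: int = 3
) -> set[str]:
    """Genes called bimodal in at least *min_datasets* of the supplied sets."""
    if min_datasets < 1:
        raise ValidationError("min_datasets must be >= 1")
    if min_datasets > len(bimodal_sets):
        raise ValidationError(
            f"min_datasets={min_datasets} exceeds the {len(bimodal_sets)} supplied datasets"
        )
    counts: dict[str, int] = {}
    for genes in bimodal_sets.values():
        for g in _norm_set(genes):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_datasets}
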