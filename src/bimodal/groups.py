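"""'Close neighbors' groups: co-expressed bimodal genes, group profiles, barcodes.

After normalization every bimodal gene is a vector of values near -1/+1
across the cohort.  Genes driven by the same underlying switch (an amplicon,
a shared regulator) have near-parallel profiles, so the cosine distance
rho = 1 - cos(x, y) from a query gene to its co-expressed partners forms an
isolated cluster near 0, clearly separated from the bulk of unrelated genes
whose distances concentrate around 1.  A group is called only when that
separation is witnessed by an empty gap in the binned distance distribution;
absence of a group is a perfectly normal outcome for most queries.

The per-sample mean of a group's normalized values (the group profile) is a
robust binary descriptor of the sample; reading its sign across several
groups yields a short barcode such as "1-1-2-1-2" that stratifies the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedDistanceError, ValidationError
from .normalize import NormalizedDataset

logger = logging.getLogger(__name__)


@dataclass
class NeighborScan:
    """Distances from one query gene to every other normalized gene."""

    query_gene: str
    gene_ids: list[str]            # scanned genes, query excluded
    distances: np.ndarray          # same order as gene_ids, values in [0, 2]
    bin_width: float = 0.05


@dataclass
class GeneGroup:
    """A query gene plus its close neighbors, with the group's profile."""

    name: str
    members: list[str]             # query first, then neighbors by distance
    member_distances: list[float]  # aligned with members (query -> 0)
    profile: np.ndarray | None = None  # per-sample mean normalized value
    flipped_members: list[str] = field(default_factory=list)  # anti-correlated, sign-inverted


@dataclass
class Barcode:
    """Per-sample group-mode codes ('1' = low mode, '2' = high mode)."""

    sample_id: str
    codes: list[int]

    @property
    def rendered(self) -> str:
        return "-".join(str(c) for c in self.codes)


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cosine similarity over the shared non-missing entries, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    if not mask.any():
        raise UndefinedDistanceError("no shared non-missing entries")
    xv, yv = x[mask], y[mask]
    nx = float(np.linalg.norm(xv))
    ny = float(np.linalg.norm(yv))
    if nx == 0.0 or ny == 0.0:
        raise UndefinedDistanceError("zero-norm vector")
    d = 1.0 - float(np.dot(xv, yv)) / (nx * ny)
    return min(max(d, 0.0), 2.0)


def scan_neighbors(
    query: str, normalized: NormalizedDataset, bin_width: float = 0.05
) -> NeighborScan:
    """Cosine distances from *query* to every other usable normalized gene.

    Genes with no finite values (e.g. excluded by control orientation) are
    skipped.
    """
    qi = normalized.gene_index(query)
    qv = normalized.values[qi]
    if not np.isfinite(qv).any():
        raise UndefinedDistanceError(f"query {query!r} has no normalized values")
    gene_ids: list[str] = []
    dists: list[float] = []
    for i, gene in enumerate(normalized.gene_ids):
        if i == qi:
            continue
        row = normalized.values[i]
        if not np.isfinite(row).any():
            continue
        try:
            d = cosine_distance(qv, row)
        except UndefinedDistanceError:
            continue
        gene_ids.append(gene)
        dists.append(d)
    return NeighborScan(
        query_gene=normalized.gene_ids[qi],
        gene_ids=gene_ids,
        distances=np.asarray(dists),
        bin_width=bin_width,
    )


def _gap_candidates(
    scan: NeighborScan, min_gap_bins: int = 2, median_factor: float = 0.5
) -> np.ndarray | None:
    """Indices (into scan.gene_ids) of the isolated near-zero distance cluster.

    The distances (query's trivial self-distance excluded by construction)
    are binned over [0, 1].  Leading empty bins are skipped; the candidate
    cluster runs from the first populated bin to the first *run* of
    ``min_gap_bins`` consecutive empty bins (single empty bins inside a
    sparse cluster of a handful of genes are tolerated).  The gap must open
    below ``median_factor`` times the median distance — a cluster is only an
    "outlier towards zero" when it sits well below the bulk of unrelated
    genes, whose distances concentrate around 1.
    """
    d = scan.distances
    if d.size == 0:
        return None
    bw = scan.bin_width
    edges = np.arange(0.0, 1.0 + bw / 2, bw)
    counts, _ = np.histogram(d[(d >= 0) & (d <= 1.0)], bins=edges)
    populated = np.flatnonzero(counts)
    if populated.size == 0:
        return None
    first = populated[0]
    gap_start = None
    run = 0
    for j in range(first, counts.size):
        if counts[j] == 0:
            run += 1
            if run >= min_gap_bins:
                gap_start = j - run + 1
                break
        else:
            run = 0
    if gap_start is None:
        return None  # no separating gap inside [0, 1]
    gap_edge = edges[gap_start]
    if gap_edge >= median_factor * float(np.median(d)):
        return None  # the "cluster" is just the left tail of the bulk
    return np.flatnonzero(d < gap_edge)


def find_close_group(
    query: str,
    normalized: NormalizedDataset,
    strategy: str = "gap",
    bin_width: float = 0.05,
    fixed_threshold: float = 0.25,
    min_group: int = 2,
    include_anticorrelated: bool = False,
) -> GeneGroup | None:
    """Search for the close-neighbors group around *query*.

    strategy "gap" calls the isolated near-zero cluster of the distance
    histogram (see :func:`_gap_candidates`); strategy "fixed" simply takes
    all genes with distance <= *fixed_threshold*.  Returns ``None`` when no
    separating gap exists or fewer than *min_group* genes (query included)
    would remain — a normal outcome, not an error.

    With ``include_anticorrelated`` the distances are folded (d -> min(d,
    2-d)) so that perfectly opposed profiles also qualify; such members are
    recorded in ``flipped_members`` and sign-inverted when averaging.  Off by
    default: after control-based orientation, co-regulated genes point the
    same way.
    """
    scan = scan_neighbors(query, normalized, bin_width)
    raw = scan.distances
    eff = np.minimum(raw, 2.0 - raw) if include_anticorrelated else raw
    eff_scan = NeighborScan(scan.query_gene, scan.gene_ids, eff, bin_width)
    if strategy == "gap":
        cand = _gap_candidates(eff_scan)
    elif strategy == "fixed":
        cand = np.flatnonzero(eff <= fixed_threshold)
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")
    if cand is None or cand.size + 1 < min_group:
        return None
    order = cand[np.argsort(eff[cand], kind="stable")]
    members = [scan.query_gene] + [scan.gene_ids[i] for i in order]
    dists = [0.0] + [float(raw[i]) for i in order]
    flipped = [scan.gene_ids[i] for i in order if raw[i] > 1.0] if include_anticorrelated else []
    group = GeneGroup(name=scan.query_gene, members=members,
                      member_distances=dists, flipped_members=flipped)
    group.profile = group_profile(group, normalized)
    return group


def group_profile(group: GeneGroup, normalized: NormalizedDataset) -> np.ndarray:
    """Per-sample mean of the members' normalized values.

    Members absent from the dataset (a gene missing on this platform) are
    skipped, so a group remains usable even when one member is not assayed.
    Members listed in ``flipped_members`` enter with inverted sign.  Raises
    :class:`ValidationError` when no member is available at all.
    """
    flipped = {m.strip().upper() for m in group.flipped_members}
    rows = []
    for m in group.members:
        try:
            row = normalized.gene_values(m)
        except KeyError:
            logger.info("group %s: member %s absent from dataset, skipped", group.name, m)
            continue
        rows.append(-row if m.strip().upper() in flipped else row)
    if not rows:
        raise ValidationError(f"group {group.name!r}: no members present in dataset")
    stacked = np.asarray(rows)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def barcode_samples(
    groups: list[GeneGroup], normalized: NormalizedDataset
) -> list[Barcode]:
    """Barcode every sample by the sign of each group's profile.

    Code 1 when the group profile is negative (low mode), code 2 when it is
    >= 0 (high mode; exactly 0 reads as the high mode).  Group order is the
    caller's, and determines code order in the rendered string.
    """
    if not groups:
        raise ValidationError("need at least one group to barcode")
    profiles = np.asarray([group_profile(g, normalized) for g in groups])
    barcodes = []
    for j, sample in enumerate(normalized.sample_ids):
        codes = [1 if profiles[gi, j] < 0 else 2 for gi in range(len(groups))]
        barcodes.append(Barcode(sample_id=sample, codes=codes))
    return barcodes
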