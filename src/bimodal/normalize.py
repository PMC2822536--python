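"""Bimodal normalization: per-gene rescaling of signals to the -1/+1 scale.

Each bimodal gene's raw signals are mapped through a strictly increasing
piecewise-linear transform anchored at the partition landmarks: the lower
mode mean ``l`` goes to -1, the threshold ``T`` to 0 and the upper mode mean
``u`` to +1.  Two linear segments hinged at T are required because T is not
in general the midpoint of (l, u).  Values outside [l, u] map beyond +-1 and
are deliberately not clipped.

Because the landmarks transform covariantly under any positive affine
distortion of the raw signals (platform effects), the normalized profiles
are platform-independent, which is what makes cross-study comparison of
bimodal genes possible.

When the cohort contains control (normal) samples the sign of each gene can
be oriented biologically: if the controls' mean raw value falls below T the
gene is flipped so that the control mode reads +1; genes whose controls
straddle T are excluded as unorientable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import DegenerateAnchorError, ValidationError
from .partition import BimodalFit

logger = logging.getLogger(__name__)

ORIENT_AS_IS = "as-is"
ORIENT_FLIPPED = "flipped"
ORIENT_EXCLUDED = "excluded"


@dataclass
class NormalizedDataset:
    """Per-gene -1/+1 normalized expression values.

    Rows are the genes that were normalized (typically the bimodal calls);
    ``orientation`` records whether each gene was kept as-is, sign-flipped to
    put the control mode at +1, or excluded (values NaN).  ``nu`` holds the
    per-gene mean raw control value when controls were used.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    orientation: dict[str, str] = field(default_factory=dict)
    nu: dict[str, float] = field(default_factory=dict)
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("normalized matrix shape does not match id lists")
        for g in self.gene_ids:
            self.orientation.setdefault(g, ORIENT_AS_IS)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        key = gene_id.strip().upper()
        for i, g in enumerate(self.gene_ids):
            if g.strip().upper() == key:
                return i
        raise KeyError(gene_id)

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def normalize_gene(signals: np.ndarray, fit: BimodalFit) -> np.ndarray:
    """Map one gene's raw signals onto the -1/+1 scale.

    x <= T  ->  (x - T) / (T - l)        (so l -> -1, T -> 0)
    x  > T  ->  (x - T) / (u - T)        (so u -> +1)

    Missing values stay NaN.  Raises :class:`DegenerateAnchorError` when the
    anchors collapse (T == l or T == u).
    """
    if not fit.u > fit.l:
        raise DegenerateAnchorError(f"gene {fit.gene_id!r}: u <= l")
    if fit.T <= fit.l or fit.T >= fit.u:
        raise DegenerateAnchorError(
            f"gene {fit.gene_id!r}: threshold T={fit.T} collapses onto an anchor "
            f"(l={fit.l}, u={fit.u})"
        )
    x = np.asarray(signals, dtype=float)
    out = np.full_like(x, np.nan)
    finite = np.isfinite(x)
    lower = finite & (x <= fit.T)
    upper = finite & (x > fit.T)
    out[lower] = (x[lower] - fit.T) / (fit.T - fit.l)
    out[upper] = (x[upper] - fit.T) / (fit.u - fit.T)
    return out


def normalize_dataset(
    dataset: ExpressionDataset,
    fits: list[BimodalFit],
    *,
    bimodal_only: bool = True,
) -> NormalizedDataset:
    """Normalize every usable gene of *dataset* given its fits.

    By default only genes called bimodal are normalized; genes whose
    anchors are degenerate are skipped with a log message.
    """
    by_gene = {f.gene_id.strip().upper(): f for f in fits}
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for i, gene in enumerate(dataset.gene_ids):
        fit = by_gene.get(gene.strip().upper())
        if fit is None or fit.flag != "ok":
            continue
        if bimodal_only and not fit.is_bimodal:
            continue
        try:
            rows.append(normalize_gene(dataset.values[i], fit))
        except DegenerateAnchorError as exc:
            logger.warning("skipping %s: %s", gene, exc)
            continue
        gene_ids.append(gene)
    return NormalizedDataset(
        gene_ids=gene_ids,
        sample_ids=list(dataset.sample_ids),
        values=np.asarray(rows) if rows else np.empty((0, dataset.n_samples)),
        platform=dataset.platform,
    )


def orient_by_controls(
    normalized: NormalizedDataset,
    dataset: ExpressionDataset,
    fits: list[BimodalFit],
) -> NormalizedDataset:
    """Orient each normalized gene so the control (normal) mode reads +1.

    Per gene, nu = mean raw control value.  Controls all above T (the raw
    side that normalizes to +1, boundary value T counted as upper): keep
    as-is.  All strictly below T: flip the sign.  Controls on both sides:
    the gene is unorientable and excluded (values set to NaN).

    Without any control samples this is a no-op (with a warning).
    """
    if dataset.control_mask is None or not dataset.control_mask.any():
        logger.warning("no control samples: orientation left as-is")
        return normalized
    by_gene = {f.gene_id.strip().upper(): f for f in fits}
    ctrl = dataset.control_mask
    values = normalized.values.copy()
    orientation: dict[str, str] = {}
    nu: dict[str, float] = {}
    for i, gene in enumerate(normalized.gene_ids):
        fit = by_gene.get(gene.strip().upper())
        if fit is None:
            raise ValidationError(f"no fit available for normalized gene {gene!r}")
        raw = dataset.gene_values(gene)[ctrl]
        raw = raw[np.isfinite(raw)]
        if raw.size == 0:
            orientation[gene] = ORIENT_AS_IS
            continue
        nu[gene] = float(raw.mean())
        below = bool(np.any(raw < fit.T))
        above = bool(np.any(raw >= fit.T))
        if below and above:
            orientation[gene] = ORIENT_EXCLUDED
            values[i] = np.nan
        elif below:
            orientation[gene] = ORIENT_FLIPPED
            values[i] = -values[i]
        else:
            orientation[gene] = ORIENT_AS_IS
    return NormalizedDataset(
        gene_ids=list(normalized.gene_ids),
        sample_ids=list(normalized.sample_ids),
        values=values,
        orientation=orientation,
        nu=nu,
        platform=normalized.platform,
    )
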