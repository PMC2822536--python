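"""Optimal two-way partition of a gene's signals and the tau bimodality statistic.

For one gene observed in ``n`` samples the signals are sorted and every split
into a lower subset ``L`` (the ``k`` smallest values, ``k = 1..n-1``) and an
upper subset ``U`` is scored by

    gamma(k) = SS(L) + SS(U),

the total within-subset sum of squared deviations (the 1-D two-means
objective).  The optimal partition minimizes gamma; its subset means are
``l`` and ``u`` and the threshold ``T`` separating the two modes is the
midpoint between the largest lower-subset and smallest upper-subset signal.

The bimodality statistic is the relative separation of the modes in units of
pooled within-mode spread,

    tau = (u - l) / sqrt(gamma / M),

with ``M`` the number of signals entering the partition.  For values drawn
from a single normal distribution the optimal split sits near the mean and
tau tends to 2 * sqrt(2/pi) / sqrt(1 - 2/pi) ~ 2.647 as M grows (half-normal
mean and variance); genes whose tau clearly exceeds that baseline are
candidates for genuinely two-mode expression.  tau is invariant under
positive affine transforms of the signals, which is what makes the calls
comparable across array platforms.

Note that because the split is *optimized* on the sample, finite cohorts
inflate tau slightly above the asymptotic 2.647 (about +0.03 at M ~ 300);
the conventional cutoff 2.64 is therefore a deliberately liberal filter that
admits roughly the upper half of null genes and relies on the companion
variance filter and downstream grouping to sharpen the selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import DegenerateGeneError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: tau of an asymptotically large normal sample (optimal split at the mean)
NORMAL_BASELINE_TAU = 2.0 * math.sqrt(2.0 / math.pi) / math.sqrt(1.0 - 2.0 / math.pi)

#: default bimodality cutoff: the normal baseline rounded as conventionally quoted
DEFAULT_TAU_THRESHOLD = 2.64


@dataclass
class BimodalFit:
    """Result of the optimal two-way partition for one gene.

    Attributes
    ----------
    K : int
        Number of samples in the lower subset (1 <= K <= n-1).
    l, u : float
        Means of the lower / upper subsets; ``l < u`` always.
    T : float
        Threshold between the modes: midpoint of the boundary signals,
        ``max(L) <= T <= min(U)``.
    gamma : float
        Minimized within-subset sum of squared deviations.
    tau : float
        Separation statistic; ``inf`` when gamma == 0 with u > l.
    outlier_samples : list of str
        Sample ids removed by the small-subset outlier rule (empty when the
        fit came straight from :func:`optimal_partition`).
    std : float or None
        Per-gene sample standard deviation before outlier trimming.
    flag : str
        "ok", or why the gene could not be fit ("degenerate",
        "insufficient_data").
    """

    gene_id: str
    K: int
    l: float
    u: float
    T: float
    gamma: float
    tau: float = float("nan")
    n_lower: int = 0
    n_upper: int = 0
    outlier_samples: list[str] = field(default_factory=list)
    std: float = float("nan")
    is_bimodal: bool = False
    flag: str = "ok"


def _partition_sorted(xs: np.ndarray) -> tuple[int, float, float, float, float]:
    """Scan all n-1 splits of sorted *xs*; return (K, l, u, T, gamma).

    Centered prefix sums keep the O(n) scan numerically stable; gamma is
    clamped at 0 against rounding.  Ties in gamma resolve to the smallest K.
    """
    n = xs.size
    xc = xs - xs.mean()
    s = np.cumsum(xc)
    q = np.cumsum(xc * xc)
    ks = np.arange(1, n, dtype=float)
    ss_lower = q[:-1] - s[:-1] ** 2 / ks
    ss_upper = (q[-1] - q[:-1]) - (s[-1] - s[:-1]) ** 2 / (n - ks)
    gamma_k = np.maximum(ss_lower + ss_upper, 0.0)
    K = int(np.argmin(gamma_k)) + 1  # argmin takes the first minimum: smallest K
    l = float(xs[:K].mean())
    u = float(xs[K:].mean())
    T = float((xs[K - 1] + xs[K]) / 2.0)
    return K, l, u, T, float(gamma_k[K - 1])


def optimal_partition(signals: np.ndarray, gene_id: str = "") -> BimodalFit:
    """Find the split of *signals* minimizing the within-subset sum of squares.

    Missing values (NaN) are dropped first.  Raises
    :class:`InsufficientDataError` for fewer than 2 usable values and
    :class:`DegenerateGeneError` when all values are identical (no partition
    with ``u > l`` exists).
    """
    x = np.asarray(signals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError(f"gene {gene_id!r}: {x.size} usable signals, need >= 2")
    xs = np.sort(x)
    if xs[0] == xs[-1]:
        raise DegenerateGeneError(f"gene {gene_id!r}: all {x.size} signals identical")
    K, l, u, T, gamma = _partition_sorted(xs)
    return BimodalFit(
        gene_id=gene_id, K=K, l=l, u=u, T=T, gamma=gamma,
        n_lower=K, n_upper=x.size - K,
    )


def tau_statistic(fit: BimodalFit, M: int) -> float:
    """tau = (u - l) / sqrt(gamma / M); ``inf`` when gamma == 0 and u > l."""
    if M < 2:
        raise ValidationError("M must be >= 2")
    if fit.gamma <= 0.0:
        if fit.u > fit.l:
            return float("inf")
        raise DegenerateGeneError("gamma == 0 with u == l")  # pragma: no cover
    return (fit.u - fit.l) / math.sqrt(fit.gamma / M)


def trim_outliers(
    signals: np.ndarray, fraction: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iteratively remove small isolated subsets as outliers.

    The optimal partition is computed; if the smaller subset holds fewer
    than ``fraction`` of the *original* number of signals, its values are
    outliers (e.g. 3 extreme signals out of 100 would otherwise claim a whole
    mode): they are removed and the remainder re-partitioned, until both
    subsets reach the fraction or the data degenerate.  ``fraction = 0``
    disables the rule.

    Returns the surviving signals (original order) and the removed positions
    (indices into the original vector).  Raises
    :class:`InsufficientDataError` when fewer than 4 values survive.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValidationError("fraction must be in [0, 0.5)")
    x = np.asarray(signals, dtype=float)
    keep = np.flatnonzero(np.isfinite(x))
    n0 = keep.size
    outliers: list[int] = []
    while True:
        if keep.size < 4:
            raise InsufficientDataError(
                f"only {keep.size} signals survive outlier trimming, need >= 4"
            )
        if fraction == 0.0:
            break
        try:
            fit = optimal_partition(x[keep])
        except DegenerateGeneError:
            break  # constant remainder: nothing left to isolate
        smaller_is_lower = fit.n_lower <= fit.n_upper
        smaller = fit.n_lower if smaller_is_lower else fit.n_upper
        if smaller >= fraction * n0:
            break
        order = np.argsort(x[keep], kind="stable")
        drop_local = order[:fit.K] if smaller_is_lower else order[fit.K:]
        removed = keep[drop_local]
        outliers.extend(int(i) for i in removed)
        keep = np.setdiff1d(keep, removed)
    outliers.sort()
    return x[keep], outliers


def std_percentile_filter(
    dataset: ExpressionDataset, percentile: float = 25.0
) -> set[str]:
    """Genes whose standard deviation exceeds the given percentile of all genes'.

    Sample standard deviation (n-1 denominator) over non-missing entries;
    the threshold is the linear-interpolation percentile of the per-gene
    std distribution; the comparison is strict, so with all stds equal no
    gene passes.
    """
    if dataset.n_genes < 2:
        raise ValidationError("need at least 2 genes for a std distribution")
    stds = per_gene_std(dataset.values)
    threshold = float(np.nanpercentile(stds, percentile))
    return {
        g for g, s in zip(dataset.gene_ids, stds)
        if np.isfinite(s) and s > threshold
    }


def per_gene_std(values: np.ndarray) -> np.ndarray:
    """Row-wise sample std (ddof=1) over non-missing entries; NaN if < 2 values."""
    counts = np.sum(np.isfinite(values), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stds = np.nanstd(values, axis=1, ddof=1)
    stds = np.where(counts >= 2, stds, np.nan)
    return stds


def detect_bimodal(
    dataset: ExpressionDataset,
    tau_threshold: float = DEFAULT_TAU_THRESHOLD,
    outlier_fraction: float = 0.05,
    std_percentile: float = 25.0,
    min_samples: int = 10,
) -> list[BimodalFit]:
    """Fit every gene and call bimodality.

    Per gene: drop missing values, trim small isolated subsets
    (:func:`trim_outliers`), partition the remainder, compute tau with M =
    number of signals entering the partition.  A gene is called bimodal when
    ``tau > tau_threshold`` *and* its pre-trim standard deviation clears the
    cohort's ``std_percentile`` (both strict).  Genes that cannot be fit are
    returned flagged ("degenerate", "insufficient_data"), never raised.
    """
    if dataset.n_genes >= 2:
        passing = std_percentile_filter(dataset, std_percentile)
    else:
        # no std distribution to rank against: the variance filter is moot
        passing = set(dataset.gene_ids)
    stds = per_gene_std(dataset.values)
    fits: list[BimodalFit] = []
    samples = np.asarray(dataset.sample_ids, dtype=object)
    for i, gene in enumerate(dataset.gene_ids):
        row = dataset.values[i]
        std = float(stds[i])
        n_finite = int(np.sum(np.isfinite(row)))
        if n_finite < min_samples:
            fits.append(BimodalFit(
                gene_id=gene, K=0, l=float("nan"), u=float("nan"), T=float("nan"),
                gamma=float("nan"), std=std, flag="insufficient_data",
            ))
            continue
        try:
            trimmed, out_idx = trim_outliers(row, outlier_fraction)
            fit = optimal_partition(trimmed, gene_id=gene)
        except (InsufficientDataError, DegenerateGeneError) as exc:
            flag = "degenerate" if isinstance(exc, DegenerateGeneError) else "insufficient_data"
            logger.debug("gene %s not fit: %s", gene, exc)
            fits.append(BimodalFit(
                gene_id=gene, K=0, l=float("nan"), u=float("nan"), T=float("nan"),
                gamma=float("nan"), std=std, flag=flag,
            ))
            continue
        fit.tau = tau_statistic(fit, trimmed.size)
        fit.outlier_samples = [str(samples[j]) for j in out_idx]
        fit.std = std
        fit.is_bimodal = (fit.tau > tau_threshold) and (gene in passing)
        fits.append(fit)
    return fits


def fits_to_frame(fits: list[BimodalFit]) -> pd.DataFrame:
    """Tabular form of a list of fits (one row per gene, indexed by gene id)."""
    rows = []
    for f in fits:
        rows.append({
            "n": f.n_lower + f.n_upper,
            "K": f.K,
            "l": f.l,
            "u": f.u,
            "T": f.T,
            "gamma": f.gamma,
            "tau": f.tau,
            "std": f.std,
            "n_outliers": len(f.outlier_samples),
            "is_bimodal": f.is_bimodal,
            "flag": f.flag,
        })
    return pd.DataFrame(rows, index=pd.Index([f.gene_id for f in fits], name="gene"))


def frame_to_fits(frame: pd.DataFrame) -> list[BimodalFit]:
    """Inverse of :func:`fits_to_frame` (outlier sample ids are not recoverable)."""
    fits = []
    for gene, row in frame.iterrows():
        n = int(row["n"])
        k = int(row["K"])
        fits.append(BimodalFit(
            gene_id=str(gene), K=k, l=float(row["l"]), u=float(row["u"]),
            T=float(row["T"]), gamma=float(row["gamma"]), tau=float(row["tau"]),
            n_lower=k, n_upper=max(n - k, 0), std=float(row["std"]),
            is_bimodal=_as_bool(row["is_bimodal"]), flag=str(row["flag"]),
        ))
    return fits


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes"}
    return bool(v)
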