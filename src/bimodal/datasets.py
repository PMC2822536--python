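"""Expression-matrix containers and plain-text I/O.

The package works on gene x sample matrices of continuous (log-scale-like)
expression values stored as tab-separated text: first column is the gene
identifier, the header row carries sample identifiers.  Missing values are
tolerated at parse time ("", "NA", "NaN"); downstream per-gene analyses drop
them.  Sample annotations (control/normal flags) and flat gene lists use
equally simple formats so that nothing in the pipeline depends on a binary
file or an external identifier service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: cell contents treated as missing when parsing expression matrices
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "na"})

#: supported rules for collapsing duplicate gene identifiers
COLLAPSE_RULES = ("max-variance", "mean", "error")


def _norm_id(gene_id: str) -> str:
    """Case-normalized form used for identifier matching."""
    return gene_id.strip().upper()


@dataclass
class ExpressionDataset:
    """A gene x sample matrix of continuous expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers, unique after case normalization.
    sample_ids : sequence of str
        Column identifiers, unique.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; ``NaN`` marks missing entries.
    control_mask : ndarray of bool, optional
        Per-sample flag, ``True`` for control/normal samples.
    platform : str
        Free-text label of the measurement platform / study.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    control_mask: np.ndarray | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.n_samples < 2:
            raise ValidationError("a dataset needs at least 2 samples")
        normed = [_norm_id(g) for g in self.gene_ids]
        if len(set(normed)) != len(normed):
            raise ValidationError("gene identifiers not unique after case normalization")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample identifiers not unique")
        if self.control_mask is not None:
            self.control_mask = np.asarray(self.control_mask, dtype=bool)
            if self.control_mask.shape != (self.n_samples,):
                raise ValidationError("control_mask length does not match sample count")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        """Row index of *gene_id* (case-insensitive)."""
        key = _norm_id(gene_id)
        for i, g in enumerate(self.gene_ids):
            if _norm_id(g) == key:
                return i
        raise KeyError(gene_id)

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSet:
    """A named set of case-normalized gene identifiers."""

    name: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = {_norm_id(m) for m in self.members if _norm_id(m)}
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return _norm_id(gene_id) in self.members


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    *,
    collapse: str = "max-variance",
    platform: str | None = None,
    missing_tokens: Iterable[str] = MISSING_TOKENS,
) -> ExpressionDataset:
    """Read a tab-separated expression matrix.

    Row 1 is the header (first cell ignored, remaining cells sample ids);
    each following row is one gene: identifier, then one value per sample.
    Lines starting with ``#`` are treated as comments and skipped.

    Parameters
    ----------
    collapse : {"max-variance", "mean", "error"}
        What to do with duplicate gene identifiers (multiple probes per
        gene): keep the highest-variance row, average the rows, or raise.
    """
    if collapse not in COLLAPSE_RULES:
        raise ValidationError(f"unknown collapse rule {collapse!r}; choose from {COLLAPSE_RULES}")
    path = Path(path)
    missing = {t.lower() for t in missing_tokens} | {""}

    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells[1:]]
                if not header:
                    raise ParseError(f"{path}: header row has no sample columns")
                continue
            if len(cells) != len(header) + 1:
                raise ParseError(
                    f"{path}: line {lineno} has {len(cells)} fields, expected {len(header) + 1}"
                )
            gene_ids.append(cells[0].strip())
            row = []
            for j, cell in enumerate(cells[1:], start=2):
                cell = cell.strip()
                if cell.lower() in missing:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}, field {j}: cannot parse {cell!r}"
                        ) from exc
            rows.append(row)
    if header is None:
        raise ParseError(f"{path}: empty file")
    if not rows:
        raise ParseError(f"{path}: no data rows")

    values = np.asarray(rows, dtype=float)
    gene_ids, values = _collapse_duplicates(gene_ids, values, collapse, str(path))
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=header,
        values=values,
        platform=platform if platform is not None else path.stem,
    )


def _collapse_duplicates(
    gene_ids: list[str], values: np.ndarray, rule: str, source: str
) -> tuple[list[str], np.ndarray]:
    """Collapse rows sharing a case-normalized gene id, preserving row order."""
    normed = [_norm_id(g) for g in gene_ids]
    if len(set(normed)) == len(normed):
        return gene_ids, values
    if rule == "error":
        dupes = sorted({n for n in normed if normed.count(n) > 1})
        raise ParseError(f"{source}: duplicate gene identifiers: {dupes[:10]}")

    first_pos: dict[str, int] = {}
    groups: dict[str, list[int]] = {}
    for i, n in enumerate(normed):
        groups.setdefault(n, []).append(i)
        first_pos.setdefault(n, i)

    out_ids: list[str] = []
    out_rows: list[np.ndarray] = []
    n_collapsed = 0
    for n in sorted(groups, key=first_pos.__getitem__):
        idx = groups[n]
        if len(idx) == 1:
            out_ids.append(gene_ids[idx[0]])
            out_rows.append(values[idx[0]])
            continue
        n_collapsed += len(idx) - 1
        sub = values[idx]
        if rule == "mean":
            out_rows.append(np.nanmean(sub, axis=0))
            out_ids.append(gene_ids[idx[0]])
        else:  # max-variance: the most informative probe
            with np.errstate(invalid="ignore"):
                var = np.nanvar(sub, axis=1, ddof=1)
            best = idx[int(np.nanargmax(var))]
            out_rows.append(values[best])
            out_ids.append(gene_ids[best])
    logger.info("%s: collapsed %d duplicate rows (rule=%s)", source, n_collapsed, rule)
    return out_ids, np.asarray(out_rows)


def read_annotations(path: str | Path) -> dict[str, bool]:
    """Read a sample-annotation TSV with columns ``sample`` and ``is_control``.

    Returns a mapping sample id -> control flag.  A header row is detected by
    a non-numeric second column on line 1.
    """
    path = Path(path)
    out: dict[str, bool] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            flag = cells[1].strip()
            if lineno == 1 and flag.lower() in {"is_control", "control"}:
                continue
            if flag not in {"0", "1"}:
                raise ParseError(f"{path}: line {lineno}: is_control must be 0 or 1, got {flag!r}")
            out[cells[0].strip()] = flag == "1"
    if not out:
        raise ParseError(f"{path}: no annotation rows")
    return out


def apply_annotations(dataset: ExpressionDataset, annotations: dict[str, bool]) -> ExpressionDataset:
    """Return a copy of *dataset* with ``control_mask`` set from *annotations*."""
    mask = np.array([bool(annotations.get(s, False)) for s in dataset.sample_ids])
    return ExpressionDataset(
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        values=dataset.values.copy(),
        control_mask=mask,
        platform=dataset.platform,
    )


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene list: one identifier per line, blank lines ignored."""
    path = Path(path)
    members = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                members.append(line)
    if not members:
        raise ParseError(f"{path}: gene-set file is empty")
    return GeneSet(name=name if name is not None else path.stem, members=set(members))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(
    obj: pd.DataFrame | ExpressionDataset,
    path: str | Path,
    *,
    header_lines: Sequence[str] = (),
    index_label: str = "gene",
) -> None:
    """Write a tabular result as TSV, with optional ``#``-comment provenance lines.

    ``ExpressionDataset`` objects are written in the matrix layout that
    :func:`read_expression` reads back; plain DataFrames are written with
    their index as the first column.
    """
    path = Path(path)
    if isinstance(obj, ExpressionDataset):
        frame = obj.to_frame()
    else:
        frame = obj
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


def write_dataset(
    dataset: ExpressionDataset, path: str | Path, *, header_lines: Sequence[str] = ()
) -> None:
    """Write an :class:`ExpressionDataset` so that ``read_expression`` round-trips it."""
    write_table(dataset, path, header_lines=header_lines)
    if dataset.control_mask is not None:
        ann = Path(path).with_suffix(".controls.tsv")
        with open(ann, "w", encoding="utf-8") as fh:
            fh.write("sample\tis_control\n")
            for s, c in zip(dataset.sample_ids, dataset.control_mask):
                fh.write(f"{s}\t{int(c)}\n")
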