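"""NEST scoring: confidence-weighted neighbor sums over a gene network.

A gene's NEST score is the sum, over its network neighbors, of the
interaction weight times the neighbor's value:

    score(g) = sum_{n in N(g)} w(g, n) * v(n)

equivalently the connectivity matrix times the value vector. The value may
be mean-centered expression, a CRISPR screen fold change, or a ChIP-seq
regulatory-potential score — the scoring step is identical. A gene's own
value never enters its own score, which keeps the score orthogonal to the
gene's own expression for downstream confounder analysis.

Value tables are plain :class:`pandas.DataFrame` objects, genes as the
index and samples as columns; NaN marks a missing value. Centering
subtracts each gene's across-sample mean, so 0 becomes the neutral
("average") value and missing neighbors naturally contribute nothing.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import ValidationError
from .network import WeightedGeneNetwork

logger = logging.getLogger(__name__)

ValueVector = Union[Mapping[str, float], pd.Series]


# ---------------------------------------------------------------------------
# value matrices
# ---------------------------------------------------------------------------

def read_value_matrix(path) -> pd.DataFrame:
    """Read a gene × sample TSV: first column gene, header of sample names.

    Empty cells and ``NA`` are treated as missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    validate_value_matrix(df)
    return df


def write_value_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def validate_value_matrix(m: pd.DataFrame) -> None:
    if m.shape[1] < 1:
        raise ValidationError("value matrix needs at least one sample column")
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate gene identifiers in value matrix: {dups}")
    with np.errstate(invalid="ignore"):
        if np.isinf(m.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValidationError("value matrix contains non-finite (inf) entries")


def center_values(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples (missing entries excluded).

    A single-sample matrix therefore centers to all zeros; genes whose
    values are all missing stay all-missing (with a warning).
    """
    validate_value_matrix(m)
    all_missing = m.isna().all(axis=1)
    if all_missing.any():
        logger.warning("center_values: %d gene(s) have no observed values", int(all_missing.sum()))
    return m.sub(m.mean(axis=1, skipna=True), axis=0)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class NestScoreTable:
    """Per-gene NEST scores for one value vector.

    ``scores`` is indexed by every network node (numeric score) plus any
    genes that carried a value but are absent from the network (NaN score,
    so downstream ranking can exclude them explicitly). ``percentiles``,
    when filled in by :func:`rank_percentile`, are fractional ascending
    ranks in ``(0, 1]`` over the scored (non-NaN) genes — essential genes
    concentrate near 1.
    """

    scores: pd.Series
    sample: Optional[str] = None
    missing_policy: str = "zero"
    coverage: Optional[pd.Series] = None  # neighbors with observed values (policy "exclude")
    percentiles: Optional[pd.Series] = None
    metadata: dict = field(default_factory=dict)

    def scored(self) -> pd.Series:
        """Scores restricted to genes that actually have one (network nodes)."""
        return self.scores.dropna()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"nest_score": self.scores})
        if self.percentiles is not None:
            out["rank_percentile"] = self.percentiles
        if self.coverage is not None:
            out["n_neighbors_observed"] = self.coverage
        out.index.name = "gene"
        return out


def _as_series(values: ValueVector) -> pd.Series:
    s = values if isinstance(values, pd.Series) else pd.Series(dict(values), dtype=float)
    if s.index.has_duplicates:
        raise ValidationError("value vector has duplicate gene identifiers")
    return s.astype(float)


def nest_scores(
    net: WeightedGeneNetwork,
    values: ValueVector,
    missing_policy: str = "zero",
) -> NestScoreTable:
    """Weighted neighbor sum for every network node.

    Neighbors with missing values contribute 0 under policy ``"zero"`` and
    are skipped under ``"exclude"`` — numerically identical, but
    ``"exclude"`` additionally records per-gene counts of neighbors with
    observed values. Isolated nodes score 0. Genes present in ``values``
    but not in the network are reported with a NaN score.
    """
    if missing_policy not in ("zero", "exclude"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    if net.n_nodes == 0:
        raise ValidationError("network is empty")
    v = _as_series(values)
    order = net.nodes
    node_set = set(order)
    overlap = v.index.intersection(order)
    if len(overlap) == 0:
        raise ValidationError("no overlap between value genes and network nodes")

    aligned = v.reindex(order)
    observed = aligned.notna().to_numpy()
    w = net.adjacency(order)
    filled = np.where(observed, aligned.to_numpy(), 0.0)
    raw = w @ filled

    scores = pd.Series(raw, index=order, dtype=float)
    coverage = None
    if missing_policy == "exclude":
        indicator = w.copy()
        indicator.data = np.ones_like(indicator.data)
        coverage = pd.Series((indicator @ observed.astype(float)).astype(int), index=order)

    extra = [g for g in v.index if g not in node_set]
    if extra:
        scores = pd.concat([scores, pd.Series(np.nan, index=extra)])
        if coverage is not None:
            coverage = pd.concat([coverage, pd.Series(0, index=extra)])
    return NestScoreTable(scores=scores, missing_policy=missing_policy, coverage=coverage)


def nest_scores_matrix(net: WeightedGeneNetwork, m: pd.DataFrame) -> dict[str, NestScoreTable]:
    """Per-sample NEST scores as one sparse connectivity × matrix product.

    Returns ``{sample: NestScoreTable}``; each table equals
    :func:`nest_scores` applied to that column.
    """
    validate_value_matrix(m)
    if net.n_nodes == 0:
        raise ValidationError("network is empty")
    order = net.nodes
    node_set = set(order)
    if len(m.index.intersection(order)) == 0:
        raise ValidationError("no overlap between value genes and network nodes")
    aligned = m.reindex(order)
    filled = np.nan_to_num(aligned.to_numpy(dtype=float), nan=0.0)
    w = net.adjacency(order)
    scored = w @ filled  # (n_nodes, n_samples)
    extra = [g for g in m.index if g not in node_set]
    out: dict[str, NestScoreTable] = {}
    for j, sample in enumerate(m.columns):
        s = pd.Series(scored[:, j], index=order, dtype=float)
        if extra:
            s = pd.concat([s, pd.Series(np.nan, index=extra)])
        out[str(sample)] = NestScoreTable(scores=s, sample=str(sample))
    return out


def rank_percentile(table: NestScoreTable) -> NestScoreTable:
    """Attach fractional ascending-rank percentiles in ``(0, 1]``.

    percentile(g) = rank(score(g), ties → average rank) / N over the N
    genes with a score; the unique maximum gets exactly 1. Percentiles are
    invariant under any strictly increasing transform of the scores.
    """
    scored = table.scores.dropna()
    if len(scored) == 0:
        raise ValidationError("no scored genes to rank")
    pct = pd.Series(rankdata(scored.to_numpy(), method="average") / len(scored),
                    index=scored.index)
    return NestScoreTable(
        scores=table.scores,
        sample=table.sample,
        missing_policy=table.missing_policy,
        coverage=table.coverage,
        percentiles=pct.reindex(table.scores.index),
        metadata=dict(table.metadata),
    )
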