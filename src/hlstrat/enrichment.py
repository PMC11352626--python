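"""Single-sample gene-set enrichment (ssGSEA) and reduced major axis regression.

The per-sample enrichment score ranks a sample's genes by expression (ties
receive their average rank), weights in-set genes by rank raised to an
exponent alpha, and integrates the difference between the weighted in-set
empirical distribution and the unweighted out-of-set distribution over the
descending-rank walk.  Scores are rank-based, hence invariant to any
strictly monotone transform of a sample's expression values.

Reduced major axis (geometric-mean) regression quantifies the association
between an enrichment score and a transcript: slope = sign(r) * sd(y)/sd(x),
symmetric in x and y, with the p-value from the two-sided t test on the
Pearson correlation (n - 2 degrees of freedom).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, EmptyOverlapError, ValidationError

__all__ = [
    "GeneSet",
    "EnrichmentScore",
    "RMAFit",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "score_matrix",
    "rma_regression",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentScore:
    sample_id: str
    set_name: str
    es: float
    alpha: float


@dataclass(frozen=True)
class RMAFit:
    """Reduced-major-axis fit: slope, intercept, Pearson r and its p-value."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int


def read_gmt(path) -> List[GeneSet]:
    """Parse a GMT file: one tab-separated line per set
    (name, description, gene, gene, ...)."""
    sets: List[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, genes=unique, source=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na"] + sorted(s.genes)) + "\n")


def _es_from_values(values: np.ndarray, names: Sequence[str], in_set: np.ndarray, alpha: float) -> float:
    n = len(values)
    m = int(in_set.sum())
    if m == 0:
        raise EmptyOverlapError("gene set has no overlap with the expression universe")
    if m == n:
        return 0.0  # the set is the whole universe: no contrast to integrate
    ranks = stats.rankdata(values)  # ties -> average rank; highest expression = rank n
    # walk in descending expression; break rank ties by gene name for determinism
    order = np.lexsort((np.asarray(names), -ranks))
    ranks_o = ranks[order]
    in_o = in_set[order]
    weights = np.abs(ranks_o) ** alpha
    w_in = np.where(in_o, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_o) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expression: Union[pd.Series, Dict[str, float]],
    gene_set: GeneSet,
    alpha: float = 0.75,
) -> EnrichmentScore:
    """Enrichment score of one gene set in one sample's expression profile."""
    series = pd.Series(expression) if not isinstance(expression, pd.Series) else expression
    names = series.index.to_numpy(dtype=object)
    values = series.to_numpy(dtype=float)
    in_set = np.isin(names, list(gene_set.genes))
    if not in_set.any():
        raise EmptyOverlapError(
            f"gene set {gene_set.name!r} has no overlap with the expression universe"
        )
    es = _es_from_values(values, names, in_set, alpha)
    return EnrichmentScore(
        sample_id=str(series.name) if series.name is not None else "",
        set_name=gene_set.name,
        es=es,
        alpha=alpha,
    )


def score_matrix(
    expression: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.75,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every (gene set, sample) pair; rows = sets, columns = samples.

    ``normalize=True`` divides every score by the (max - min) spread across
    the whole result, the conventional z-range normalisation of the method.
    """
    names = expression.index.to_numpy(dtype=object)
    out = np.empty((len(gene_sets), expression.shape[1]))
    masks = [np.isin(names, list(s.genes)) for s in gene_sets]
    for s, mask in zip(gene_sets, masks):
        if not mask.any():
            raise EmptyOverlapError(
                f"gene set {s.name!r} has no overlap with the expression universe"
            )
    for j, sample in enumerate(expression.columns):
        values = expression.iloc[:, j].to_numpy(dtype=float)
        for i, (s, mask) in enumerate(zip(gene_sets, masks)):
            out[i, j] = _es_from_values(values, names, mask, alpha)
    result = pd.DataFrame(out, index=[s.name for s in gene_sets], columns=expression.columns)
    if normalize:
        spread = float(out.max() - out.min())
        if spread > 0:
            result = result / spread
    return result


def rma_regression(x: Sequence[float], y: Sequence[float]) -> RMAFit:
    """Reduced major axis regression of y on x.

    slope = sign(r) * sd(y)/sd(x); intercept through the means; r and its
    two-sided p-value from the Pearson correlation t test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"RMA regression needs n >= 3, got {n}")
    sd_x = float(np.std(x, ddof=1))
    sd_y = float(np.std(y, ddof=1))
    if sd_x == 0.0 or sd_y == 0.0:
        raise DegenerateInputError("RMA regression requires non-zero variance in x and y")
    r, p = stats.pearsonr(x, y)
    slope = math.copysign(sd_y / sd_x, r if r != 0 else 1.0)
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    return RMAFit(slope=float(slope), intercept=intercept, r=float(r), p=float(p), n=n)
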