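"""Correlation maps within and across heterogeneous omics matrices.

Up to four sample matrices (metagenome, metatranscriptome, metabolome,
biomass, ...) sharing one column count are stacked row-wise and the full
symmetric all-pairs correlation matrix over the stacked rows is
computed: element (i, j) is the correlation coefficient between row i
and row j across samples. With a single input matrix this is the
STOCSY-type self-correlation map of spectral variables.

Three coefficients are supported: Pearson's product-moment r, Spearman's
rank correlation (average ranks on ties), and the cosine similarity.
Rows for which a coefficient is undefined (zero variance for Pearson/
Spearman, zero norm for cosine) yield NaN entries — an explicit
"undefined" marker, never an exception — which downstream consumers
(top-pair extraction, the r-value histogram, the heatmap renderer) skip
or render neutral.

Significance: under the null of no correlation, r * sqrt((n-2)/(1-r^2))
follows a t distribution on n-2 degrees of freedom, so the two-sided
critical value at level alpha is r* = t* / sqrt(n - 2 + t*^2). At n = 7
samples and alpha = 0.05 this gives r* ~= 0.75, the cutoff used to call
correlations significant in small time-series designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import SampleMatrix

__all__ = [
    "METHODS",
    "CorrelationMap",
    "PairRecord",
    "correlate",
    "build_hetmap",
    "critical_r",
    "top_pairs",
    "r_distribution",
]

METHODS = ("pearson", "spearman", "cosine")
MAX_MATRICES = 4


@dataclass
class CorrelationMap:
    """Symmetric block-labelled matrix of correlation coefficients.

    ``labels`` are ``block_label:row_id`` for every row of every input,
    concatenated in input order; ``blocks`` records, per input matrix,
    ``(block_label, start, stop)`` into that concatenation. Undefined
    entries are NaN.
    """

    labels: list[str]
    values: np.ndarray
    method: str
    n_samples: int
    blocks: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix shape does not match labels")

    @property
    def size(self) -> int:
        return len(self.labels)

    def to_sample_matrix(self) -> SampleMatrix:
        """The labelled symmetric r matrix as a writable SampleMatrix."""
        return SampleMatrix(
            row_ids=list(self.labels),
            sample_labels=list(self.labels),
            values=self.values,
            block_label=f"{self.method}-r",
        )


@dataclass(frozen=True)
class PairRecord:
    """One unordered row pair with its correlation coefficient."""

    label_a: str
    label_b: str
    r: float

    def __post_init__(self) -> None:
        if not self.label_a < self.label_b:
            raise ValueError("pair labels must be in canonical (sorted) order")

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average", axis=-1)


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Correlation between two equal-length vectors; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("correlation requires n >= 2")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            return float("nan")
        return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
    if method == "spearman":
        x, y = _rank(x), _rank(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def _corr_matrix(rows: np.ndarray, method: str) -> np.ndarray:
    """All-pairs correlation over the rows of a 2-D array (NaN-marked)."""
    k, n = rows.shape
    if method == "cosine":
        norms = np.linalg.norm(rows, axis=1)
        ok = norms > 0
        unit = np.zeros_like(rows)
        unit[ok] = rows[ok] / norms[ok, None]
        r = unit @ unit.T
        r[~ok, :] = np.nan
        r[:, ~ok] = np.nan
    else:
        data = _rank(rows) if method == "spearman" else rows
        sd = np.std(data, axis=1)
        ok = sd > 0
        centered = data - data.mean(axis=1, keepdims=True)
        denom = np.sqrt((centered**2).sum(axis=1))
        safe = np.where(ok, denom, 1.0)
        unit = centered / safe[:, None]
        r = unit @ unit.T
        r[~ok, :] = np.nan
        r[:, ~ok] = np.nan
    r = np.clip(r, -1.0, 1.0)
    r[np.ix_(ok, ok)] = (r[np.ix_(ok, ok)] + r[np.ix_(ok, ok)].T) / 2  # enforce symmetry
    idx = np.where(ok)[0]
    r[idx, idx] = 1.0
    return r


def build_hetmap(
    matrices: list[SampleMatrix] | SampleMatrix,
    method: str = "pearson",
    *,
    max_matrices: int = MAX_MATRICES,
    require_matching_columns: bool = False,
) -> CorrelationMap:
    """Stack 1-4 sample matrices and correlate all row pairs.

    All inputs must share one column count; columns are aligned by
    position (set ``require_matching_columns`` to additionally demand
    identical sample labels). Row labels are prefixed with each matrix's
    block label so the map's block structure stays visible.
    """
    if isinstance(matrices, SampleMatrix):
        matrices = [matrices]
    if not 1 <= len(matrices) <= max_matrices:
        raise ValueError(
            f"between 1 and {max_matrices} input matrices are accepted, got {len(matrices)}"
        )
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    n_cols = {m.n_samples for m in matrices}
    if len(n_cols) > 1:
        raise ValueError(
            "the number of columns must be the same for all of the input matrices; "
            f"found {sorted(n_cols)}"
        )
    n_samples = n_cols.pop()
    if n_samples < 2:
        raise ValueError("correlation requires at least 2 sample columns")
    if require_matching_columns:
        ref = matrices[0].sample_labels
        for m in matrices[1:]:
            if m.sample_labels != ref:
                raise ValueError("sample labels differ between input matrices")

    labels: list[str] = []
    blocks: list[tuple[str, int, int]] = []
    chunks: list[np.ndarray] = []
    for i, m in enumerate(matrices):
        block = m.block_label or f"block{i + 1}"
        start = len(labels)
        labels.extend(f"{block}:{rid}" for rid in m.row_ids)
        blocks.append((block, start, len(labels)))
        chunks.append(m.values)
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate prefixed row labels: {sorted(dupes)}")

    r = _corr_matrix(np.vstack(chunks), method)
    return CorrelationMap(labels, r, method, n_samples, blocks)


def critical_r(n: int, alpha: float = 0.05, *, n_tests: int = 1) -> float:
    """Two-sided critical |r| of the Pearson coefficient under the null.

    Derived from the exact t relation on n-2 degrees of freedom:
    r* = t* / sqrt(n - 2 + t*^2) with t* the upper alpha/2 t quantile.
    ``n_tests`` > 1 applies a Bonferroni correction (alpha / n_tests).
    """
    if n < 3:
        raise ValueError("critical_r requires n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    t_star = stats.t.ppf(1 - (alpha / n_tests) / 2, df=n - 2)
    return float(t_star / np.sqrt(n - 2 + t_star**2))


def top_pairs(
    cmap: CorrelationMap, cutoff: float = 0.75, k: int | None = None
) -> list[PairRecord]:
    """Unique row pairs with defined |r| strictly above the cutoff.

    Sorted by |r| descending, ties broken by canonical label order;
    truncated to the top ``k`` when given. Self-pairs are excluded;
    within-block and between-block pairs are both included.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    pairs: list[PairRecord] = []
    vals = cmap.values
    for i in range(cmap.size):
        for j in range(i + 1, cmap.size):
            r = vals[i, j]
            if np.isnan(r) or abs(r) <= cutoff:
                continue
            a, b = sorted((cmap.labels[i], cmap.labels[j]))
            pairs.append(PairRecord(a, b, float(r)))
    pairs.sort(key=lambda p: (-p.abs_r, p.label_a, p.label_b))
    return pairs[:k] if k is not None else pairs


def r_distribution(cmap: CorrelationMap, n_bins: int = 20) -> tuple[np.ndarray, bool]:
    """Histogram fractions of off-diagonal defined r values over [-1, 1].

    Equal-width bins (last bin closed), normalized to sum to 1; returns
    ``(fractions, empty)`` where ``empty`` flags a map with no defined
    off-diagonal entries.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    iu = np.triu_indices(cmap.size, k=1)
    vals = cmap.values[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return np.zeros(n_bins), True
    counts, _ = np.histogram(vals, bins=n_bins, range=(-1.0, 1.0))
    return counts / counts.sum(), False
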