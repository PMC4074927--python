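"""Kullback-Leibler and Jensen-Shannon divergences between entropy histograms.

Genomes are compared through their block-entropy distributions p and q on a
shared binning. The Jensen-Shannon divergence uses the equal-weight mixture
m = (p + q) / 2 as the intermediate distribution:

    D_JS(p, q) = 1/2 D_KL(p || m) + 1/2 D_KL(q || m),

which is symmetric, always finite, and bounded by 1 bit with base-2
logarithms. Its square root d = sqrt(D_JS) is a true metric (it satisfies the
triangle inequality) and is the default distance used for clustering; the raw
divergence is available for comparison.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distribution import EntropyDistribution


class DistanceError(ValueError):
    """Raised for invalid divergence inputs (support, normalization, binning)."""


def _as_prob_vector(x, name: str) -> np.ndarray:
    p = x.probs if isinstance(x, EntropyDistribution) else np.asarray(x, dtype=float)
    if p.ndim != 1:
        raise DistanceError(f"{name} must be a 1-D probability vector")
    if (p < 0).any():
        raise DistanceError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DistanceError(f"{name} sums to {p.sum()!r}, not 1")
    return p


def _check_schemes(p, q) -> None:
    if isinstance(p, EntropyDistribution) and isinstance(q, EntropyDistribution):
        if not p.same_scheme(q):
            raise DistanceError(
                "distributions were built on different binning schemes; "
                "rebuild them on one shared scheme instead of rebinning"
            )


def kl_divergence(p, m) -> float:
    """Relative entropy D_KL(p || m) in bits; terms with p_j == 0 contribute 0.

    Requires ``m_j > 0`` wherever ``p_j > 0``; a support violation raises
    :class:`DistanceError` rather than returning infinity.
    """
    pv = _as_prob_vector(p, "p")
    mv = _as_prob_vector(m, "m")
    if pv.shape != mv.shape:
        raise DistanceError(f"length mismatch: {pv.shape} vs {mv.shape}")
    mask = pv > 0
    if (mv[mask] == 0).any():
        raise DistanceError("support violation: p has mass where m is zero")
    return float((pv[mask] * np.log2(pv[mask] / mv[mask])).sum())


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence (bits) via the equal-weight mixture.

    Accepts :class:`EntropyDistribution` objects (their binning schemes must
    match exactly) or bare probability vectors of equal length. Bins where
    both inputs are zero contribute nothing.
    """
    _check_schemes(p, q)
    pv = _as_prob_vector(p, "p")
    qv = _as_prob_vector(q, "q")
    if pv.shape != qv.shape:
        raise DistanceError(f"length mismatch: {pv.shape} vs {qv.shape}")
    m = 0.5 * (pv + qv)
    return 0.5 * kl_divergence(pv, m) + 0.5 * kl_divergence(qv, m)


def js_metric(p, q) -> float:
    """The Jensen-Shannon metric d = sqrt(D_JS(p, q)), in [0, 1]."""
    d2 = js_divergence(p, q)
    # guard tiny negative round-off
    return float(np.sqrt(d2)) if d2 > 0 else 0.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with genome labels."""

    labels: tuple[str, ...]
    values: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise DistanceError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DistanceError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DistanceError("matrix diagonal is not zero")
        if (v < 0).any():
            raise DistanceError("matrix has negative entries")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if sorted(labels) != sorted(self.labels):
            raise DistanceError("reorder labels must be a permutation of matrix labels")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=tuple(labels), values=self.values[np.ix_(idx, idx)], meta=self.meta
        )

    def to_tsv(self) -> str:
        """Square tab-separated matrix with a label header row and column."""
        lines = ["\t".join(["genome", *self.labels])]
        for lab, row in zip(self.labels, self.values):
            lines.append("\t".join([lab, *(f"{x:.6f}" for x in row)]))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        """PHYLIP square (lower+upper) distance matrix format."""
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            name = lab.replace(" ", "_")
            lines.append("  ".join([name, *(f"{x:.6f}" for x in row)]))
        return "\n".join(lines) + "\n"


def read_phylip(path_or_text: str | Path) -> DistanceMatrix:
    """Parse a PHYLIP square distance matrix (whitespace-separated)."""
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str) and "\n" not in path_or_text and Path(path_or_text).exists()
    ):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    lines = [l for l in io.StringIO(text).read().splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels=tuple(labels), values=np.array(rows))


def distance_matrix(
    dists: Sequence[EntropyDistribution],
    metric: str = "sqrt_js",
) -> DistanceMatrix:
    """All pairwise Jensen-Shannon metric distances over a genome set.

    All distributions must share one binning scheme and carry unique labels.
    ``metric`` is ``"sqrt_js"`` (default, a true metric) or ``"raw_js"``
    (the divergence itself, for comparison).
    """
    if len(dists) < 2:
        raise DistanceError("need at least 2 distributions for a distance matrix")
    labels = [d.genome_label for d in dists]
    if len(set(labels)) != len(labels):
        raise DistanceError("duplicate genome labels in distribution set")
    first = dists[0]
    for d in dists[1:]:
        if not first.same_scheme(d):
            raise DistanceError("mixed binning schemes in distribution set")
    if metric not in ("sqrt_js", "raw_js"):
        raise DistanceError(f"unknown metric mode {metric!r}")
    fn = js_metric if metric == "sqrt_js" else js_divergence
    n = len(dists)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(dists[i], dists[j])
    meta = {
        "B": first.block_size,
        "M": first.scheme.n_bins,
        "range": (first.scheme.lower, first.scheme.upper),
        "metric": metric,
    }
    return DistanceMatrix(labels=tuple(labels), values=values, meta=meta)
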