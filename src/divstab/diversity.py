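"""Alpha, gamma, and beta diversity at the block (10-plot) scale.

Alpha-diversity is the mean per-plot index value, gamma-diversity the
block-pooled value, and beta-diversity the mean multivariate distance of
plots to their block centroid in Jaccard-dissimilarity principal-coordinate
space (the ``betadisper`` construction), with Whittaker's multiplicative and
additive variants as companions.

The primary indices are presence/absence based (richness, binary Jaccard);
Shannon entropy, inverse Simpson, and ENS_PIE are available as
abundance-based alternatives, plus an abundance-based Ružička dissimilarity
for the dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BlockCoverMatrix",
    "UndefinedPlotError",
    "plot_richness",
    "alpha_diversity",
    "gamma_diversity",
    "beta_jaccard_dispersion",
    "beta_whittaker",
    "beta_additive",
    "DIVERSITY_INDICES",
]

DIVERSITY_INDICES = ("richness", "shannon", "inv_simpson", "s_pie")


class UndefinedPlotError(ValueError):
    """An abundance-based index was requested for a plot with zero cover."""


@dataclass
class BlockCoverMatrix:
    """Plots x taxa percent-cover matrix for one block.

    Rows follow ``plot_ids`` order; taxa with zero total cover are allowed
    (they simply never register as present).
    """

    plot_ids: Sequence[str]
    taxa: Sequence[str]
    cover: np.ndarray

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=float)
        if self.cover.shape != (len(self.plot_ids), len(self.taxa)):
            raise ValueError(
                f"cover matrix shape {self.cover.shape} does not match "
                f"{len(self.plot_ids)} plots x {len(self.taxa)} taxa"
            )
        if (self.cover < 0).any():
            raise ValueError("cover values must be >= 0")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def presence(self) -> np.ndarray:
        return self.cover > 0


def plot_richness(row: np.ndarray) -> int:
    """Number of taxa with cover > 0 in one plot."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("cover values must be >= 0")
    return int(np.count_nonzero(row > 0))


def _per_plot_index(row: np.ndarray, index: str, plot_id: str) -> float:
    if index == "richness":
        return float(plot_richness(row))
    total = row.sum()
    if total <= 0:
        raise UndefinedPlotError(
            f"abundance index {index!r} undefined for all-zero plot {plot_id!r}"
        )
    p = row[row > 0] / total
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index in ("inv_simpson", "s_pie"):
        # ENS_PIE and inverse Simpson share the formula 1 / sum(p^2)
        return float(1.0 / (p**2).sum())
    raise ValueError(f"unknown diversity index {index!r}")


def alpha_diversity(m: BlockCoverMatrix, index: str = "richness") -> float:
    """Mean per-plot diversity across the block's plots."""
    if m.n_plots < 1:
        raise ValueError("alpha_diversity requires at least one plot")
    vals = [
        _per_plot_index(m.cover[i], index, m.plot_ids[i]) for i in range(m.n_plots)
    ]
    return float(np.mean(vals))


def gamma_diversity(m: BlockCoverMatrix, index: str = "richness", pooling: str = "mean") -> float:
    """Block-pooled diversity.

    Richness counts taxa present in at least one plot.  Abundance indices
    are computed on pooled relative cover: by default each plot is first
    converted to relative cover and taxa are averaged across plots
    (``pooling="mean"``); ``pooling="sum"`` pools raw summed cover instead.
    """
    if m.n_plots < 1:
        raise ValueError("gamma_diversity requires at least one plot")
    if index == "richness":
        return float(np.count_nonzero(m.presence().any(axis=0)))
    totals = m.cover.sum(axis=1)
    if (totals <= 0).any():
        bad = m.plot_ids[int(np.argmax(totals <= 0))]
        raise UndefinedPlotError(
            f"abundance index {index!r} undefined: plot {bad!r} has zero total cover"
        )
    if pooling == "mean":
        pooled = (m.cover / totals[:, None]).mean(axis=0)
    elif pooling == "sum":
        pooled = m.cover.sum(axis=0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return _per_plot_index(pooled, index, "<pooled>")


# ---------------------------------------------------------------------------
# beta diversity: mean distance to centroid in PCoA space
# ---------------------------------------------------------------------------

def _dissimilarity(m: BlockCoverMatrix, metric: str) -> np.ndarray:
    if metric == "jaccard":
        pres = m.presence()
        empty = ~pres.any(axis=1)
        if empty.any():
            bad = m.plot_ids[int(np.argmax(empty))]
            raise UndefinedPlotError(
                f"Jaccard dissimilarity undefined for species-free plot {bad!r}"
            )
        return squareform(pdist(pres, metric="jaccard"))
    if metric == "ruzicka":
        # abundance-based analog: 1 - sum(min) / sum(max)
        x = m.cover
        empty = x.sum(axis=1) <= 0
        if empty.any():
            bad = m.plot_ids[int(np.argmax(empty))]
            raise UndefinedPlotError(
                f"Ruzicka dissimilarity undefined for zero-cover plot {bad!r}"
            )
        mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
        maxs = np.maximum(x[:, None, :], x[None, :, :]).sum(axis=2)
        return 1.0 - mins / maxs
    raise ValueError(f"unknown beta metric {metric!r}")


def beta_jaccard_dispersion(m: BlockCoverMatrix, metric: str = "jaccard") -> float:
    """Mean distance of plots to their centroid in PCoA space.

    The dissimilarity matrix is embedded by principal coordinates via Gower
    double-centering, retaining axes with negative eigenvalues ("imaginary"
    axes).  Each plot's distance to the group centroid is
    ``sqrt(max(d_real^2 - d_imag^2, 0))`` — the standard correction for
    non-Euclidean dissimilarities — and the block's beta-diversity is the
    mean of these distances.
    """
    if m.n_plots < 2:
        raise ValueError("beta dispersion requires at least 2 plots")
    d = _dissimilarity(m, metric)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    keep = np.abs(eigval) > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    centroid = coords.mean(axis=0)
    delta2 = (coords - centroid) ** 2
    pos = eigval > 0
    d2 = delta2[:, pos].sum(axis=1) - delta2[:, ~pos].sum(axis=1)
    return float(np.sqrt(np.maximum(d2, 0.0)).mean())


def beta_whittaker(alpha: float, gamma: float, convention: str = "as_printed") -> float:
    """Whittaker's multiplicative beta-diversity.

    ``as_printed`` returns alpha/gamma (a value in (0, 1]); ``conventional``
    returns the textbook gamma/alpha (>= 1).  Both are exposed because the
    two conventions are reciprocal and sources differ in which they report.
    """
    if not (gamma >= alpha > 0):
        raise ValueError(
            f"inconsistent diversities: need gamma >= alpha > 0, got alpha={alpha}, gamma={gamma}"
        )
    if convention == "as_printed":
        return float(alpha / gamma)
    if convention == "conventional":
        return float(gamma / alpha)
    raise ValueError(f"unknown convention {convention!r}")


def beta_additive(alpha: float, gamma: float) -> float:
    """Additive beta-diversity, gamma - alpha."""
    if gamma < alpha:
        raise ValueError(
            f"inconsistent diversities: gamma ({gamma}) < alpha ({alpha})"
        )
    return float(gamma - alpha)
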