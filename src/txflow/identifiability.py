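"""Collinearity-index analysis of practical parameter identifiability.

The collinearity index of a parameter subset is 1 / sigma_min, the inverse of
the smallest singular value of the column-normalized sensitivity submatrix.
gamma = 1 means orthogonal sensitivity directions (independently identifiable
parameters); gamma -> infinity means a direction in parameter space leaves the
observables unchanged (perfectly covariant, unidentifiable parameters).

Experiments sharing parameters can be pooled by stacking their sensitivity
rows into one design matrix; shared columns then accumulate information from
every experiment, which is how a database of related circuits breaks
covariance that no single experiment can.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .circuit_model import CATEGORIES, ParameterSet
from .simulator import SensitivityMatrix

DEFAULT_CEILING = 1e6


@dataclass
class CollinearityResult:
    """Pairwise collinearity indices with optional category lumping."""

    labels: tuple[str, ...]
    pairwise: np.ndarray  # symmetric, diagonal 1 by convention
    ceiling: float = DEFAULT_CEILING

    def gamma(self, a: str, b: str) -> float:
        return float(self.pairwise[self.labels.index(a), self.labels.index(b)])


def _normalized_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize columns; returns (normalized, zero-column mask)."""
    norms = np.linalg.norm(matrix, axis=0)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    return matrix / safe, zero


def collinearity_index(
    S: SensitivityMatrix | np.ndarray,
    subset: Sequence[str] | Sequence[int] | None = None,
    ceiling: float = DEFAULT_CEILING,
) -> float:
    """Collinearity index gamma = 1/sigma_min of a normalized sensitivity submatrix.

    Columns (one per parameter, flattened over time x observables) are scaled
    to unit norm before the SVD.  An all-zero column marks a structurally
    unidentifiable parameter; the subset is then reported at the ceiling
    rather than raising.
    """
    if isinstance(S, SensitivityMatrix):
        mat = S.flattened()
        if subset is None:
            cols = list(range(len(S.labels)))
        elif subset and isinstance(subset[0], str):
            cols = [S.labels.index(l) for l in subset]
        else:
            cols = list(subset)  # type: ignore[arg-type]
    else:
        mat = np.asarray(S, dtype=float)
        cols = list(range(mat.shape[1])) if subset is None else list(subset)  # type: ignore[arg-type]
    if len(cols) < 2:
        raise ValueError("collinearity needs at least 2 parameters")
    sub = mat[:, cols]
    normed, zero = _normalized_columns(sub)
    if zero.any():
        return float(ceiling)
    smin = np.linalg.svd(normed, compute_uv=False)[-1]
    if smin <= 1.0 / ceiling:
        return float(ceiling)
    return float(1.0 / smin)


def structurally_unidentifiable(S: SensitivityMatrix) -> tuple[str, ...]:
    """Labels whose sensitivity column is identically zero."""
    _, zero = _normalized_columns(S.flattened())
    return tuple(l for l, z in zip(S.labels, zero) if z)


def pairwise_collinearity(
    S: SensitivityMatrix, ceiling: float = DEFAULT_CEILING
) -> CollinearityResult:
    """gamma over every 2-subset of parameters; diagonal 1 by convention."""
    p = len(S.labels)
    mat = np.ones((p, p))
    flat = S.flattened()
    for a, b in itertools.combinations(range(p), 2):
        g = collinearity_index(flat, [a, b], ceiling=ceiling)
        mat[a, b] = mat[b, a] = g
    return CollinearityResult(labels=S.labels, pairwise=mat, ceiling=ceiling)


def pool_experiments(matrices: Sequence[SensitivityMatrix]) -> SensitivityMatrix:
    """Stack experiments row-wise on the union of their parameter labels.

    Shared labels share columns (their rows accumulate across experiments);
    experiment-specific labels get zero rows in the other experiments.
    """
    if not matrices:
        raise ValueError("no experiments to pool")
    all_labels: list[str] = []
    for S in matrices:
        for l in S.labels:
            if l not in all_labels:
                all_labels.append(l)
    blocks = []
    for S in matrices:
        flat = S.flattened()
        block = np.zeros((flat.shape[0], len(all_labels)))
        for j, l in enumerate(S.labels):
            block[:, all_labels.index(l)] = flat[:, j]
        blocks.append(block)
    stacked = np.vstack(blocks)
    # reshaped back into [rows, 1, p] so flattened() round-trips
    return SensitivityMatrix(
        entries=stacked[:, None, :],
        times=np.arange(stacked.shape[0], dtype=float),
        observable_species=("pooled",),
        labels=tuple(all_labels),
    )


def lumped_category_matrix(
    result: CollinearityResult,
    mapping: Mapping[str, str] | None = None,
    reference: np.ndarray | float | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Mean pairwise gamma per category pair over {K_TX, K_TL, K_reg, K_deg}.

    ``reference`` normalizes the matrix (default: no normalization); pass the
    maximum entry of the batch-design scenario to mirror a batch-normalized
    comparison across designs.
    """
    mapping = mapping or {l: ParameterSet.category_of(l) for l in result.labels}
    for l in result.labels:
        if l not in mapping:
            raise KeyError(f"parameter {l!r} not mapped to a category")
    cats = tuple(c for c in CATEGORIES if c in set(mapping.values()))
    out = np.full((len(cats), len(cats)), np.nan)
    for i, ci in enumerate(cats):
        for j, cj in enumerate(cats):
            vals = []
            for a, la in enumerate(result.labels):
                for b, lb in enumerate(result.labels):
                    if a == b or mapping[la] != ci or mapping[lb] != cj:
                        continue
                    if a < b or ci != cj:
                        vals.append(result.pairwise[a, b])
            if vals:
                out[i, j] = float(np.mean(vals))
    if reference is not None:
        ref = float(np.nanmax(reference)) if isinstance(reference, np.ndarray) else float(reference)
        out = out / ref
    return out, cats


def mean_lumped_index(result: CollinearityResult, log_scale: bool = True) -> float:
    """Grand mean of the lumped category matrix -- the scalar used to rank designs.

    By default gammas are averaged on a log scale (geometric mean): structurally
    collinear pairs sit at the ceiling in every design, and an arithmetic mean
    would let them swamp the differences between designs.
    """
    if log_scale:
        logged = CollinearityResult(
            labels=result.labels,
            pairwise=np.log10(result.pairwise),
            ceiling=result.ceiling,
        )
        mat, _ = lumped_category_matrix(logged)
        return float(10 ** np.nanmean(mat))
    mat, _ = lumped_category_matrix(result)
    return float(np.nanmean(mat))


def export_json(result: CollinearityResult, path) -> None:
    doc = {
        "labels": list(result.labels),
        "pairwise": result.pairwise.tolist(),
        "ceiling": result.ceiling,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def plot_heatmap(matrix: np.ndarray, labels: Sequence[str], path, title: str = "") -> None:
    """Heatmap of a (lumped or pairwise) collinearity matrix (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(matrix, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="collinearity index")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
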