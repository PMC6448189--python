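"""Setting topic profiles, Pearson similarity, and the clustered image map.

A practice setting's *topic profile* is the arithmetic mean of the
p(topic | term) rows of its representative concepts — a mean of simplex
vectors, hence itself a probability vector over topics.  Profiles are
compared by Pearson correlation; the resulting setting × setting matrix
is reordered by agglomerative clustering (distance 1 − r) and
quantile-binned for display, the data behind a clustered image map (CIM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import DataError
from .lda import TermTopicMatrix

__all__ = [
    "SettingProfile",
    "SimilarityMatrix",
    "CIMResult",
    "setting_profile",
    "profile_from_counts",
    "pearson_matrix",
    "cluster_image_map",
    "write_profiles_tsv",
    "write_similarity_tsv",
    "plot_cim",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SettingProfile:
    """Probability vector over topics for one practice setting."""

    setting: str
    vector: np.ndarray
    n_terms: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if self.n_terms < 1:
            raise DataError(f"profile for {self.setting!r} built from no terms")
        if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
            raise DataError(f"profile for {self.setting!r} is not a probability vector")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pearson correlations between setting profiles."""

    settings: list[str]
    matrix: np.ndarray            # S×S, unit diagonal, NaN where undefined

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())


@dataclass(frozen=True)
class CIMResult:
    """Clustered-image-map data: leaf ordering, binned colors, dendrogram."""

    order: list[str]              # settings in dendrogram leaf order
    ordered_matrix: np.ndarray    # correlations reordered rows+columns
    binned_matrix: np.ndarray     # quantile bin index per cell (ordered)
    bin_edges: np.ndarray
    linkage_matrix: np.ndarray


def setting_profile(
    ttm: TermTopicMatrix,
    representative: Mapping[str, set[str]],
) -> list[SettingProfile]:
    """Mean p(topic | term) over each setting's representative terms.

    Terms missing from the model vocabulary are ignored; a setting whose
    representative terms are all out of vocabulary is an error.
    """
    index = {w: i for i, w in enumerate(ttm.vocabulary)}
    profiles: list[SettingProfile] = []
    missing: list[str] = []
    for setting in sorted(representative):
        rows = [index[t] for t in sorted(representative[setting]) if t in index]
        if not rows:
            missing.append(setting)
            continue
        vec = ttm.matrix[rows].mean(axis=0)
        profiles.append(SettingProfile(setting, vec / vec.sum(), len(rows)))
    if missing:
        raise DataError(
            "no in-vocabulary representative terms for setting(s): "
            + ", ".join(missing))
    return profiles


def profile_from_counts(
    term_topic_counts: np.ndarray,
    setting: str,
) -> SettingProfile:
    """Profile from held-out term–topic assignment counts.

    Each term with any accumulated assignments contributes its normalized
    topic-count row; the profile is the unweighted mean of those rows,
    mirroring how training profiles average representative-term rows.
    """
    counts = np.asarray(term_topic_counts, dtype=float)
    row_sums = counts.sum(axis=1)
    observed = row_sums > 0
    if not observed.any():
        raise DataError(f"no observed terms for held-out setting {setting!r}")
    rows = counts[observed] / row_sums[observed, None]
    vec = rows.mean(axis=0)
    return SettingProfile(setting, vec / vec.sum(), int(observed.sum()))


def pearson_matrix(profiles: Sequence[SettingProfile]) -> SimilarityMatrix:
    """Pairwise Pearson correlation of setting topic vectors.

    A zero-variance (uniform) profile has no defined correlation; its
    entries are recorded as NaN with a warning.
    """
    if len(profiles) < 2:
        raise DataError("need at least 2 profiles")
    lengths = {len(p.vector) for p in profiles}
    if len(lengths) != 1 or lengths.pop() < 2:
        raise DataError("profiles must share one topic dimension K >= 2")
    data = np.vstack([p.vector for p in profiles])
    constant = data.std(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(data)
    if constant.any():
        names = [p.setting for p, c in zip(profiles, constant) if c]
        logger.warning("zero-variance profile(s), correlations undefined: %s",
                       ", ".join(names))
        corr[constant, :] = np.nan
        corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return SimilarityMatrix([p.setting for p in profiles], corr)


def cluster_image_map(
    sim: SimilarityMatrix,
    linkage_method: str = "average",
    n_bins: int = 10,
) -> CIMResult:
    """Reorder the correlation matrix by hierarchical clustering.

    Rows and columns (identical, the matrix being symmetric) are clustered
    agglomeratively on distance 1 − r and ordered by the dendrogram
    leaves.  Cell colors are quantile bins (default deciles) of the
    off-diagonal correlations.
    """
    if linkage_method not in {"average", "complete", "single"}:
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    m = sim.matrix
    if np.isnan(m).any():
        raise DataError(
            "similarity matrix contains undefined correlations; exclude the "
            "degenerate settings before building the clustered image map")
    dist = 1.0 - m
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)   # enforce exact symmetry
    lm = linkage(squareform(dist, checks=False), method=linkage_method)
    order_idx = list(leaves_list(lm))
    ordered = m[np.ix_(order_idx, order_idx)]

    off_diag = ordered[~np.eye(len(order_idx), dtype=bool)]
    quantiles = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(off_diag, quantiles) if off_diag.size else np.array([])
    binned = np.digitize(ordered, edges)
    np.fill_diagonal(binned, n_bins - 1)            # diagonal shown as the top bin
    return CIMResult(
        order=[sim.settings[i] for i in order_idx],
        ordered_matrix=ordered,
        binned_matrix=binned,
        bin_edges=edges,
        linkage_matrix=lm,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_profiles_tsv(profiles: Sequence[SettingProfile], path: str | Path) -> None:
    k = len(profiles[0].vector)
    df = pd.DataFrame(
        [[p.setting, *p.vector] for p in profiles],
        columns=["setting", *[f"topic_{i + 1}" for i in range(k)]],
    )
    df.to_csv(path, sep="\t", index=False)


def write_similarity_tsv(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.matrix, index=sim.settings, columns=sim.settings
                 ).to_csv(path, sep="\t")


def plot_cim(cim: CIMResult, path: str | Path, cmap: str = "RdBu_r") -> None:
    """Optional heatmap rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.4 * len(cim.order) + 2,) * 2)
    im = ax.imshow(cim.ordered_matrix, cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(len(cim.order)), cim.order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cim.order)), cim.order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
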