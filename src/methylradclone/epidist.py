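"""Epigenetic distances: Euclidean distances in the 2-D PCA plane of RPM.

Methylome dissimilarity between shoots is summarized by projecting the
reads-per-million matrix onto its first two principal components and taking
Euclidean distances between sample scores in that plane, per sequence
context. Columns (sites) are centered and, by default, scaled to unit
variance before projection; zero-variance sites are dropped first since
scaling them is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .distances import DistanceMatrix, euclidean_distance_matrix


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x 2
    explained_fractions: np.ndarray  # length 2, descending
    dropped_zero_variance: int
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.sample_ids, columns=["PC1", "PC2"]
        )


def pca_scores(
    rpm: pd.DataFrame, scale_unit_variance: bool = True, label: str = ""
) -> PCAResult:
    """Top-2 PCA scores of samples from a sites x samples RPM frame.

    Scores are deterministic up to sign; the sign convention makes the first
    sample's score nonnegative on each component. Explained-variance
    fractions are relative to the total variance of all components.
    """
    if rpm.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = rpm.to_numpy(dtype=float).T  # samples x sites
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("all sites have zero variance")
    X = X - X.mean(axis=0)
    if scale_unit_variance:
        X = X / sd[keep]
    n_comp = min(2, min(X.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    if n_comp < 2:  # degenerate rank-1 data: pad a zero second component
        scores = np.hstack([scores, np.zeros((scores.shape[0], 2 - n_comp))])
        explained = np.concatenate(
            [pca.explained_variance_ratio_, np.zeros(2 - n_comp)]
        )
    else:
        explained = pca.explained_variance_ratio_[:2]
    for j in range(scores.shape[1]):
        if scores[0, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(
        sample_ids=list(rpm.columns),
        scores=scores,
        explained_fractions=np.asarray(explained, dtype=float),
        dropped_zero_variance=dropped,
        label=label,
    )


def distance_2d(pca: PCAResult) -> DistanceMatrix:
    """Euclidean distances between 2-D score pairs (sign-flip invariant)."""
    return euclidean_distance_matrix(pca.scores, pca.sample_ids, label=pca.label)


def relative_distances(D: DistanceMatrix) -> DistanceMatrix:
    """Distances divided by the maximum distance; entries in [0, 1]."""
    return D.relative()


def context_distances(
    rpm: pd.DataFrame,
    contexts: pd.DataFrame,
    which: dict[str, dict[str, str]] | None = None,
    scale_unit_variance: bool = True,
) -> dict[str, DistanceMatrix]:
    """Per-context PCA distances.

    ``which`` maps a label to column filters on the context table, e.g.
    ``{"gene-CG": {"genic": "gene", "motif_class": "CG"}}``. The label
    ``"all"`` (no filters) is always included.
    """
    if which is None:
        which = default_contexts()
    out: dict[str, DistanceMatrix] = {}
    ctx = contexts.set_index("site_id")
    for label, filters in {"all": {}, **which}.items():
        mask = pd.Series(True, index=ctx.index)
        for col, val in filters.items():
            mask &= ctx[col] == val
        site_ids = [s for s in rpm.index if mask.get(s, False)]
        sub = rpm.loc[site_ids]
        if sub.shape[0] < 2:
            continue
        try:
            pca = pca_scores(sub, scale_unit_variance=scale_unit_variance, label=label)
        except ValueError:
            continue  # e.g. all zero-variance in this context
        out[label] = distance_2d(pca)
    return out


def default_contexts() -> dict[str, dict[str, str]]:
    """The gene/intergenic x TE/non-TE x CG/CHG stratification grid."""
    out = {}
    for genic in ("gene", "intergenic"):
        for mclass in ("CG", "CHG"):
            out[f"{genic}-{mclass}"] = {"genic": genic, "motif_class": mclass}
            out[f"{genic}-TE-{mclass}"] = {
                "genic": genic,
                "te": "TE",
                "motif_class": mclass,
            }
    return out
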