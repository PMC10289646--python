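"""PCA of the AH feature matrix, statsmodels-style.

The feature matrix holds one row per helix and 28 columns: the 8 summary
descriptors (length, net charge, mean hydrophobicity, hydrophobic moment,
polar / apolar / charged / bulky class counts) followed by the 20 per-residue
counts in alphabetical order. Every feature is z-scored (mean 0, SD 1);
zero-variance columns are dropped with a warning, because they carry no
information and cannot be scaled. PCA is the eigendecomposition of the
covariance of the z-scored matrix (equivalently, correlation PCA), with
components ordered by descending eigenvalue and each eigenvector's sign
fixed so its largest-magnitude loading is positive — eigenvector sign is
otherwise arbitrary and tests need determinism.

Usage follows the Model/Results pattern::

    fm = build_matrix(profiles, labels)
    res = AmphipathicPCA(fm, n_components=3).fit()
    res.explained_variance_ratio  # fractions of total variance
    res.loadings                  # features x components DataFrame
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .physchem import AMINO_ACIDS, PhyschemProfile
from .sequence_io import profiles_to_frame

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "AmphipathicPCA",
    "PCAResults",
    "build_matrix",
    "zscore",
    "group_summary",
]

#: Canonical column order: 8 summary features, then the 20 AA counts
#: (alphabetical by one-letter code).
FEATURE_COLUMNS: tuple[str, ...] = tuple(PhyschemProfile.SUMMARY_FEATURES) + tuple(
    f"count_{aa}" for aa in AMINO_ACIDS
)


@dataclass
class FeatureMatrix:
    """Feature table (rows = AHs) with per-row group labels."""

    data: pd.DataFrame
    labels: pd.DataFrame  # columns: family, phylum; same index as data

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes}")
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share the same index")

    @property
    def n_rows(self) -> int:
        return len(self.data)


def build_matrix(
    profiles: Sequence[PhyschemProfile],
    labels: Mapping[str, tuple[str, str]] | pd.DataFrame,
) -> FeatureMatrix:
    """Assemble the feature matrix from profiles and (family, phylum) labels.

    ``labels`` maps record id -> (family, phylum), or is a DataFrame with
    'family' and 'phylum' columns indexed by id. At least two profiles are
    required (a single row cannot be normalized) and ids must be unique.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to build a feature matrix")
    ids = [p.id for p in profiles]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate profile id {i!r}")
        seen.add(i)
    data = profiles_to_frame(profiles).loc[:, list(FEATURE_COLUMNS)].astype(float)
    if isinstance(labels, pd.DataFrame):
        lab = labels.loc[ids, ["family", "phylum"]]
    else:
        lab = pd.DataFrame(
            [labels[i] for i in ids], index=data.index, columns=["family", "phylum"]
        )
    return FeatureMatrix(data=data, labels=lab)


def zscore(
    data: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Z-score each column: subtract the mean, divide by the SD (ddof=1).

    Returns ``(normalized, means, sds, dropped)``. Zero-variance columns are
    dropped with a warning naming them; if every column is constant, raises.
    """
    if len(data) < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    means = data.mean()
    sds = data.std(ddof=1)
    dropped = sds.index[sds == 0.0].tolist()
    if len(dropped) == len(data.columns):
        raise ValueError("all feature columns have zero variance")
    if dropped:
        warnings.warn(
            f"dropping zero-variance columns: {dropped}", UserWarning, stacklevel=2
        )
    kept = [c for c in data.columns if c not in dropped]
    z = (data[kept] - means[kept]) / sds[kept]
    return z, means[kept], sds[kept], dropped


class AmphipathicPCA:
    """Principal component analysis of a z-scored AH feature matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Feature table with group labels; normalization happens inside fit().
    n_components : int
        Components to retain for scores/loadings (default 3 — the smallest
        number explaining more than half the variance in the motivating
        dataset). Explained-variance ratios are always reported for *all*
        components so they sum to 1.
    """

    def __init__(self, matrix: FeatureMatrix, n_components: int = 3) -> None:
        self.matrix = matrix
        self.n_components = int(n_components)

    def fit(self) -> "PCAResults":
        z, means, sds, dropped = zscore(self.matrix.data)
        max_rank = min(len(z) - 1, z.shape[1])
        if self.n_components > max_rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the maximum rank "
                f"{max_rank} of the normalized matrix"
            )
        sk = _SkPCA(n_components=None, svd_solver="full")
        scores_full = sk.fit_transform(z.to_numpy())
        loadings_full = sk.components_.T  # features x components
        # Deterministic sign: largest-|loading| entry positive per component.
        for j in range(loadings_full.shape[1]):
            col = loadings_full[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                loadings_full[:, j] = -col
                scores_full[:, j] = -scores_full[:, j]
        k = self.n_components
        comp_names = [f"PC{j + 1}" for j in range(loadings_full.shape[1])]
        return PCAResults(
            model=self,
            loadings=pd.DataFrame(
                loadings_full[:, :k], index=z.columns, columns=comp_names[:k]
            ),
            explained_variance=pd.Series(
                sk.explained_variance_, index=comp_names, name="eigenvalue"
            ),
            explained_variance_ratio=pd.Series(
                sk.explained_variance_ratio_, index=comp_names, name="evr"
            ),
            scores=pd.DataFrame(
                scores_full[:, :k], index=z.index, columns=comp_names[:k]
            ),
            means=means,
            sds=sds,
            dropped_columns=dropped,
        )


@dataclass
class PCAResults:
    """Fitted PCA: loadings, eigenvalues, variance ratios, scores.

    ``explained_variance_ratio`` covers *all* components (sums to 1);
    ``loadings`` and ``scores`` are truncated to the retained components.
    ``means``/``sds`` are the normalization constants, needed to project
    new data into the same space.
    """

    model: AmphipathicPCA
    loadings: pd.DataFrame
    explained_variance: pd.Series
    explained_variance_ratio: pd.Series
    scores: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def cumulative_variance_pct(self, k: int | None = None) -> float:
        """Percent of total variance explained by the first k components."""
        k = self.n_components if k is None else k
        return float(self.explained_variance_ratio.iloc[:k].sum() * 100.0)

    def project(self, new_data: pd.DataFrame) -> pd.DataFrame:
        """Scores of new rows: z-score with the stored means/SDs, then × W."""
        missing = [c for c in self.means.index if c not in new_data.columns]
        if missing:
            raise ValueError(f"new data is missing feature columns: {missing}")
        z = (new_data[self.means.index] - self.means) / self.sds
        return pd.DataFrame(
            z.to_numpy() @ self.loadings.to_numpy(),
            index=new_data.index,
            columns=self.loadings.columns,
        )

    def loading_report(self, top_m: int = 5) -> dict[str, pd.Series]:
        """Top-``top_m`` features per component, ranked by |loading|.

        Ties in |loading| break alphabetically by feature name; returned
        values keep their sign.
        """
        n_feat = self.loadings.shape[0]
        if top_m > n_feat:
            warnings.warn(
                f"top_m={top_m} exceeds the {n_feat} features; clamping",
                UserWarning,
                stacklevel=2,
            )
            top_m = n_feat
        report: dict[str, pd.Series] = {}
        for comp in self.loadings.columns:
            col = self.loadings[comp]
            order = sorted(col.index, key=lambda f: (-abs(col[f]), f))
            report[comp] = col.loc[order[:top_m]]
        return report

    def summary(self) -> str:
        """Plain-text summary table of variance ratios and top loadings."""
        lines = ["Amphipathic-helix feature PCA", "=" * 46]
        lines.append(
            f"rows: {len(self.scores)}   features: {self.loadings.shape[0]}"
            f"   components retained: {self.n_components}"
        )
        if self.dropped_columns:
            lines.append(f"dropped zero-variance columns: {self.dropped_columns}")
        lines.append("-" * 46)
        lines.append(f"{'component':<10}{'eigenvalue':>12}{'% variance':>12}{'cum %':>12}")
        cum = 0.0
        for comp in self.loadings.columns:
            evr = self.explained_variance_ratio[comp] * 100.0
            cum += evr
            lines.append(
                f"{comp:<10}{self.explained_variance[comp]:>12.4f}"
                f"{evr:>12.2f}{cum:>12.2f}"
            )
        lines.append("-" * 46)
        for comp, top in self.loading_report(top_m=3).items():
            desc = ", ".join(f"{f} ({v:+.2f})" for f, v in top.items())
            lines.append(f"{comp} top loadings: {desc}")
        return "\n".join(lines)


def group_summary(
    matrix: FeatureMatrix, feature: str, by: str = "family"
) -> pd.DataFrame:
    """Per-group order statistics of one feature: median, quartiles, mean.

    Quartiles use linear interpolation, the convention of the violin plots
    these summaries back. ``by`` is 'family' or 'phylum' (or both joined).
    """
    if feature not in matrix.data.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if by not in matrix.labels.columns:
        raise KeyError(f"unknown grouping {by!r}")
    rows = []
    for name, idx in matrix.labels.groupby(by, sort=True).groups.items():
        vals = matrix.data.loc[idx, feature].to_numpy()
        if vals.size == 0:
            raise ValueError(f"group {name!r} is empty")
        rows.append(
            {
                "group": name,
                "n": vals.size,
                "mean": float(np.mean(vals)),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.median(vals)),
                "q3": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
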