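"""Covariate matrix construction and PCA projection.

Genomic signal tracks (chromatin marks, replication timing, expression,
methylation, GC content ...) are averaged over the training bins into an
``n x m`` covariate matrix X.  Because such tracks are strongly
correlated across features and tissues, X is centered, scaled and
rotated to principal components before regression; the full-rank score
matrix X' is the regression design.  Principal components can be ranked
by their mean absolute Pearson correlation with per-bin mutation counts
to support reduced (top-k) regressions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


def average_signal_over_bins(track: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Per-bin mean of per-base track values, uncovered bases counting 0.

    This is the "mean0" convention: the sum of value x covered-length
    over the bin, divided by the full bin length.  ``track`` needs
    columns chrom/start/end/value with non-overlapping intervals per
    chromosome (bedGraph semantics).
    """
    required = {"chrom", "start", "end", "value"}
    if not required <= set(track.columns):
        raise ValueError(f"track lacks columns {sorted(required - set(track.columns))}")
    track_chroms = set(track["chrom"].unique())
    bin_chroms = set(bins["chrom"].unique())
    orphan = track_chroms - bin_chroms
    covered = bin_chroms & track_chroms
    if len(track) and not covered and orphan:
        raise ValueError(f"track chromosomes not found in bins: {sorted(orphan)}")

    out = np.zeros(len(bins), dtype=float)
    for chrom, tgrp in track.groupby("chrom"):
        mask = (bins["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tgrp = tgrp.sort_values("start")
        ts = tgrp["start"].to_numpy(dtype=np.int64)
        te = tgrp["end"].to_numpy(dtype=np.int64)
        tv = tgrp["value"].to_numpy(dtype=float)
        b_starts = bins.loc[mask, "start"].to_numpy(dtype=np.int64)
        b_ends = bins.loc[mask, "end"].to_numpy(dtype=np.int64)
        sums = np.zeros(len(b_starts))
        for k, (bs, be) in enumerate(zip(b_starts, b_ends)):
            i0 = np.searchsorted(te, bs, side="right")
            i1 = np.searchsorted(ts, be, side="left")
            if i1 > i0:
                ov = np.minimum(te[i0:i1], be) - np.maximum(ts[i0:i1], bs)
                sums[k] = float(np.dot(tv[i0:i1], np.maximum(ov, 0)))
        out[mask] = sums / (b_ends - b_starts)
    return out


def gc_fraction(fasta, bins: pd.DataFrame) -> np.ndarray:
    """(G+C) / (A+C+G+T) per bin, case-insensitive.

    Ns and other ambiguity codes are excluded from the denominator; a
    bin with no unambiguous base yields NaN so the caller can drop it
    from training.  ``fasta`` is a mapping chrom -> sequence (e.g. a
    ``pyfaidx.Fasta``).
    """
    out = np.empty(len(bins), dtype=float)
    for k, row in enumerate(bins.itertuples(index=False)):
        seq = fasta[row.chrom][row.start : row.end]
        seq = str(seq).upper()
        if len(seq) < row.end - row.start:
            raise ValueError(
                f"sequence for {row.chrom} shorter than bin [{row.start}, {row.end})"
            )
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        denom = gc + at
        out[k] = gc / denom if denom else np.nan
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.warning("gc_fraction: %d bins with no unambiguous bases", n_missing)
    return out


def build_covariate_matrix(
    tracks: dict[str, pd.DataFrame], bins: pd.DataFrame
) -> pd.DataFrame:
    """Average each named track over the bins; rows indexed by bin index."""
    data = {name: average_signal_over_bins(tr, bins) for name, tr in tracks.items()}
    return pd.DataFrame(data, index=bins["index"].to_numpy())


@dataclass
class PCAModel:
    """Standardisation plus orthonormal rotation mapping X to scores X'."""

    column_means: np.ndarray
    column_scales: np.ndarray
    rotation: np.ndarray  # m x m; columns are loading vectors
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # n x m training scores
    feature_names: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new covariate rows into PC space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.column_means) / self.column_scales @ self.rotation

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Map scores back to the standardised covariate space."""
        return np.atleast_2d(scores) @ self.rotation.T

    def save(self, path) -> None:
        payload = {
            "column_means": self.column_means.tolist(),
            "column_scales": self.column_scales.tolist(),
            "rotation": self.rotation.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "feature_names": self.feature_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PCAModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            column_means=np.array(payload["column_means"]),
            column_scales=np.array(payload["column_scales"]),
            rotation=np.array(payload["rotation"]),
            explained_variance_ratio=np.array(payload["explained_variance_ratio"]),
            scores=np.empty((0, len(payload["column_means"]))),
            feature_names=payload["feature_names"],
        )


def fit_pca(X: pd.DataFrame | np.ndarray) -> PCAModel:
    """Center, scale (sample SD) and rotate the covariate matrix.

    All principal components are retained (full rank).  Constant columns
    cannot be scaled and are dropped with a warning.  Loading signs are
    fixed so each column's largest-magnitude element is positive, making
    the rotation reproducible across linear-algebra backends.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.atleast_2d(np.asarray(X, dtype=float))
        names = [f"f{j}" for j in range(values.shape[1])]
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite covariate at bin row {i}, feature {names[j]!r}")

    means = values.mean(axis=0)
    scales = values.std(axis=0, ddof=1)
    keep = scales > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant covariate columns: {dropped}")
        values = values[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        means, scales = means[keep], scales[keep]

    Z = (values - means) / scales
    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    scores = pca.fit_transform(Z)
    rotation = pca.components_.T  # m x m
    # deterministic sign convention
    for j in range(rotation.shape[1]):
        pivot = np.argmax(np.abs(rotation[:, j]))
        if rotation[pivot, j] < 0:
            rotation[:, j] *= -1
            scores[:, j] *= -1
    return PCAModel(
        column_means=means,
        column_scales=scales,
        rotation=rotation,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        feature_names=names,
    )


@dataclass
class PCRanking:
    """PCs ordered by mean |Pearson correlation| with mutation counts."""

    correlations: pd.DataFrame  # diseases x PCs
    mean_abs: np.ndarray
    order: np.ndarray  # PC indices, best first

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def rank_pcs(scores: np.ndarray, counts) -> PCRanking:
    """Pearson correlation of each PC with per-bin counts, per disease.

    ``counts`` is a :class:`~nbburden.grid.CountsMatrix` or a DataFrame
    of shape diseases x bins aligned with the score rows.
    """
    values = counts.values if hasattr(counts, "values") and not isinstance(counts, pd.DataFrame) else counts
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.atleast_2d(values))
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if values.shape[1] != scores.shape[0]:
        raise ValueError("counts columns must align with score rows")
    rows = {}
    for d in values.index:
        y = values.loc[d].to_numpy(dtype=float)
        if y.std() == 0:
            raise ValueError(f"zero-variance count vector for disease {d!r}")
        yc = y - y.mean()
        sc = scores - scores.mean(axis=0)
        denom = np.sqrt((sc**2).sum(axis=0) * (yc**2).sum())
        rows[d] = sc.T @ yc / denom
    corr = pd.DataFrame(rows).T
    mean_abs = corr.abs().mean(axis=0).to_numpy()
    order = np.argsort(-mean_abs, kind="stable")
    return PCRanking(correlations=corr, mean_abs=mean_abs, order=order)
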