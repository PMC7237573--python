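"""Reference-cohort correlation model and single-sample PCC perturbation.

The single-sample Pearson correlation coefficient (sPCC) of a taxon pair
(i, j) for a query sample s is the change in their Pearson correlation when
s is appended to the reference cohort::

    sPCC(i, j; s) = PCC_{ref + s}(i, j) - PCC_ref(i, j)

Being a difference of two correlations it is bounded in [-2, 2]. A healthy
(reference-like) sample barely moves any correlation, so its sPCC matrix is
near zero; a perturbed sample shifts the correlations of the taxa whose
dependence structure its state has rewired.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import ReferenceSizeError


def _as_frame(X) -> pd.DataFrame:
    """Coerce samples-by-taxa input to a DataFrame with string columns."""
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


class ReferenceNetwork(BaseEstimator):
    """Reference means, standard deviations and pairwise Pearson correlations.

    The estimator is fitted on the reference (healthy) samples only; every
    single-sample score is a perturbation of this baseline. Taxa with zero
    variance across the reference carry no correlation information and are
    excluded (listed in ``excluded_taxa_``).

    Parameters
    ----------
    min_samples : int
        Minimum number of reference samples (correlations over fewer than
        three points are unstable or undefined).

    Attributes
    ----------
    taxa_ : list of retained taxon ids
    excluded_taxa_ : list of zero-variance taxon ids
    mean_, std_ : per-taxon reference mean and SD (ddof=1), retained taxa
    correlation_ : (p, p) reference Pearson correlation matrix
    reference_ : (n_ref, p) retained reference abundance matrix
    """

    def __init__(self, min_samples: int = 3):
        self.min_samples = min_samples

    def fit(self, X, y=None) -> "ReferenceNetwork":
        frame = _as_frame(X)
        if frame.shape[0] < self.min_samples:
            raise ReferenceSizeError(
                f"need >= {self.min_samples} reference samples, got {frame.shape[0]}"
            )
        values = frame.to_numpy(dtype=float)
        variances = values.var(axis=0)
        keep = variances > 0
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        self.taxa_ = list(frame.columns[keep])
        self.excluded_taxa_ = list(frame.columns[~keep])
        retained = values[:, keep]
        self.reference_ = retained
        self.sample_ids_ = list(frame.index)
        self.mean_ = retained.mean(axis=0)
        self.std_ = retained.std(axis=0, ddof=1)
        self.correlation_ = np.corrcoef(retained, rowvar=False)
        np.fill_diagonal(self.correlation_, 1.0)
        return self

    # -- single-sample scores ---------------------------------------------

    def _index_of(self, taxon) -> int:
        try:
            return self.taxa_.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not retained in the reference model")

    def _sample_vector(self, sample) -> np.ndarray:
        if isinstance(sample, pd.Series):
            return sample.reindex(self.taxa_).to_numpy(dtype=float)
        sample = np.asarray(sample, dtype=float)
        if sample.shape[0] == self.n_features_in_ and len(self.excluded_taxa_):
            keep = np.isin(self.feature_names_in_, self.taxa_)
            sample = sample[keep]
        if sample.shape[0] != len(self.taxa_):
            raise ValueError("sample vector length does not match retained taxa")
        return sample

    def augmented_correlation(self, sample) -> np.ndarray:
        """Pearson correlation matrix over reference samples plus ``sample``."""
        check_is_fitted(self, "correlation_")
        vec = self._sample_vector(sample)
        stacked = np.vstack([self.reference_, vec])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(stacked, rowvar=False)
        # a taxon can only become zero-variance if it already was in the
        # reference (excluded); guard anyway: treat the perturbed PCC as 0.
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        return corr

    def spcc_matrix(self, sample) -> pd.DataFrame:
        """Full (p, p) sPCC matrix for one sample (zero diagonal)."""
        delta = self.augmented_correlation(sample) - self.correlation_
        np.fill_diagonal(delta, 0.0)
        return pd.DataFrame(delta, index=self.taxa_, columns=self.taxa_)

    def spcc(self, sample, i, j) -> float:
        """sPCC of the taxon pair (i, j) for one sample; symmetric in (i, j)."""
        a, b = self._index_of(i), self._index_of(j)
        return float(self.spcc_matrix(sample).iloc[a, b])

    def zscores(self, X) -> np.ndarray:
        """Reference-standardized values (x - mu) / sd, samples by taxa."""
        check_is_fitted(self, "mean_")
        frame = _as_frame(X)
        values = frame[self.taxa_].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else self._stack(X)
        return (values - self.mean_) / self.std_

    def _stack(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.vstack([self._sample_vector(row) for row in X])

    def deviation(self, sample) -> np.ndarray:
        """Absolute deviation |x - mu| per retained taxon for one sample."""
        return np.abs(self._sample_vector(sample) - self.mean_)


def fit_reference(table, design) -> ReferenceNetwork:
    """Fit a :class:`ReferenceNetwork` on the design's reference group.

    ``table`` is an :class:`~ienet.abundance.AbundanceTable`; only samples
    labelled with the design's reference group are used.
    """
    ref_samples = design.samples_in(design.reference)
    X = table.to_samples_matrix().loc[ref_samples]
    return ReferenceNetwork().fit(X)
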