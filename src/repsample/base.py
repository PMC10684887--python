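"""Common estimator surface for all sample weighters.

Every weighter follows the same contract: ``fit(X, X_reference)`` learns a
nonnegative weight per row of the non-representative sample ``X`` using a
representative reference sample, and exposes it as ``weights_``.  The
reference sample is never altered.  Estimators are scikit-learn
``BaseEstimator`` subclasses, so ``get_params``/``set_params``, cloning
and pipeline composition work as usual.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted


class BaseWeighter(BaseEstimator):
    """Base class: fit sample weights for a biased cohort against a reference."""

    def _validate_pair(self, X, X_reference):
        X = check_array(X, dtype=float, ensure_min_samples=1)
        R = check_array(X_reference, dtype=float, ensure_min_samples=1)
        if X.shape[1] != R.shape[1]:
            raise ValueError(
                f"feature-count mismatch: X has {X.shape[1]}, reference has {R.shape[1]}"
            )
        return X, R

    def fit(self, X, X_reference):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit_weights(self, X, X_reference) -> np.ndarray:
        """Convenience: fit and return the learned weight vector."""
        self.fit(X, X_reference)
        return self.weights_

    @property
    def n_samples_(self) -> int:
        check_is_fitted(self, "weights_")
        return len(self.weights_)
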