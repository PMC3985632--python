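"""scikit-learn-style estimators over the reconstruction pipeline.

Three estimators compose with sklearn pipelines and model selection:

* :class:`HiCNormalizer` — stateless transformer applying observed/expected
  normalization to a square contact matrix.
* :class:`ChromosomeReconstructor` — fit takes a normalized matrix, builds
  the constraint set, optimizes an ensemble and selects the representative
  model; fitted attributes expose the ensemble, scores and similarity.
* :class:`CompartmentCaller` — clusterer assigning each bin to one of the
  two chromatin compartments from the sign of PC1.

The functional module surface (:mod:`chromo3d.normalize`,
:mod:`chromo3d.optimize`, ...) stays the primary vocabulary; these classes
wrap it for users who want estimator semantics.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from . import compartments as _compartments
from . import evaluate as _evaluate
from . import normalize as _normalize
from . import optimize as _optimize
from .io import ContactMatrix
from .model import ModelParameters

__all__ = ["HiCNormalizer", "ChromosomeReconstructor", "CompartmentCaller"]


def _as_contact_matrix(X, normalized: bool) -> ContactMatrix:
    if isinstance(X, ContactMatrix):
        return X
    return ContactMatrix(values=np.asarray(X, dtype=float), normalized=normalized)


class HiCNormalizer(TransformerMixin, BaseEstimator):
    """Observed/expected (likelihood-ratio) normalization of a contact map.

    Stateless: ``fit`` only validates, ``transform`` divides each entry by
    its marginal-product expectation.  Accepts and returns square arrays;
    :func:`chromo3d.normalize.normalize_matrix` is the ContactMatrix-level
    equivalent.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("expected a square contact matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        M = _as_contact_matrix(X, normalized=False)
        return _normalize.normalize_matrix(M).values

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class ChromosomeReconstructor(BaseEstimator):
    """Reconstruct an ensemble of 3D chromosome models from a contact map.

    Parameters
    ----------
    cutoff : float
        Likelihood-ratio threshold separating contacts from non-contacts.
    n_models : int
        Ensemble size (independent optimizations from random starts).
    parameters : ModelParameters or None
        Distance thresholds and term weights; defaults to the 1 MB
        calibration when None.
    max_iterations, tol : optimizer controls.
    random_state : int
        Base seed; ensemble member k runs from random_state + k.
    assume_normalized : bool
        When False (default) the input is raw counts and is normalized
        first; set True to feed an already-normalized matrix.

    Attributes (after fit)
    ----------------------
    constraint_set_ : ConstraintSet
    ensemble_ : Ensemble
    similarity_ : SimilarityMatrix (when n_models >= 2)
    representative_idx_ : int
    representative_ : Structure
    report_ : EvaluationReport for the representative model
    """

    def __init__(
        self,
        cutoff: float = 0.66,
        n_models: int = 300,
        parameters: ModelParameters | None = None,
        max_iterations: int = 10_000,
        tol: float = 1e-7,
        random_state: int = 0,
        assume_normalized: bool = False,
    ):
        self.cutoff = cutoff
        self.n_models = n_models
        self.parameters = parameters
        self.max_iterations = max_iterations
        self.tol = tol
        self.random_state = random_state
        self.assume_normalized = assume_normalized

    def fit(self, X, y=None):
        M = _as_contact_matrix(X, normalized=self.assume_normalized)
        if not M.normalized:
            M = _normalize.normalize_matrix(M)
        P = self.parameters or ModelParameters()
        CS = _normalize.apply_cutoff(M, self.cutoff)
        opts = _optimize.OptimizerOptions(
            max_iterations=self.max_iterations,
            tol=self.tol,
            seed=self.random_state,
        )
        E = _optimize.build_ensemble(
            CS, P, opts, m=self.n_models, chrom=M.chrom, resolution=M.resolution
        )
        self.n_features_in_ = M.n
        self.constraint_set_ = CS
        self.ensemble_ = E
        if len(E) >= 2:
            self.similarity_ = _evaluate.pairwise_similarity(E)
            self.representative_idx_ = _evaluate.select_representative(
                E, self.similarity_
            )
        else:
            self.similarity_ = None
            self.representative_idx_ = 0
        self.representative_ = E.structures[self.representative_idx_]
        self.report_ = _evaluate.score_structure(self.representative_, CS, P)
        return self

    def score(self, X=None, y=None) -> float:
        """Contact score of the representative model (fraction satisfied)."""
        self._check_fitted()
        return self.report_.contact_score

    def _check_fitted(self):
        if not hasattr(self, "ensemble_"):
            raise AttributeError("ChromosomeReconstructor is not fitted yet")


class CompartmentCaller(ClusterMixin, BaseEstimator):
    """Two-compartment assignment from the contact map via PCA.

    fit sets ``labels_`` (values in {1, 2}), ``pc1_`` and
    ``variance_explained_``; fit_predict returns the labels, so the class
    slots into sklearn clustering APIs.
    """

    def __init__(self, use_correlation: bool = True, assume_normalized: bool = True):
        self.use_correlation = use_correlation
        self.assume_normalized = assume_normalized

    def fit(self, X, y=None):
        M = _as_contact_matrix(X, normalized=self.assume_normalized)
        if not M.normalized:
            M = _normalize.normalize_matrix(M)
        A = _compartments.assign_compartments(M, use_correlation=self.use_correlation)
        self.n_features_in_ = M.n
        self.assignment_ = A
        self.labels_ = A.labels
        self.pc1_ = A.pc1
        self.variance_explained_ = A.variance_explained
        self.degenerate_ = A.degenerate
        return self
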