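"""Phonological vector spaces: one-hot feature encoding plus truncated SVD.

Each sign is encoded as a binary vector with one block of indicator columns
per annotation slot in the chosen parameter scope (handshape, location,
movement, or all twelve slots together).  The sparse indicator matrix is then
densified with a truncated singular value decomposition; phonological
similarity between two signs is the cosine of their rows in the reduced space.
At full rank the reduced-space cosines equal the raw one-hot cosines, so
results that should not depend on the rank can be computed in that limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyFeatureSpaceError, ParameterError
from .lexicon import SCHEMA_SLOTS, Lexicon

logger = logging.getLogger(__name__)

#: Default cap on the retained SVD rank.
DEFAULT_SVD_RANK = 50


@dataclass(frozen=True)
class ParameterScope:
    """A named subset of annotation slots (one phonological parameter)."""

    name: str
    slots: tuple[str, ...]


SCOPES: dict[str, ParameterScope] = {
    "handshape": ParameterScope("handshape", SCHEMA_SLOTS[0:4]),
    "location": ParameterScope("location", SCHEMA_SLOTS[4:8]),
    "movement": ParameterScope("movement", SCHEMA_SLOTS[8:12]),
    "entire": ParameterScope("entire", SCHEMA_SLOTS),
}

_ALIASES = {"hs": "handshape", "loc": "location", "mov": "movement"}


def get_scope(scope: str | ParameterScope) -> ParameterScope:
    """Resolve a scope name (``handshape``/``HS``/... ) to a ParameterScope."""
    if isinstance(scope, ParameterScope):
        return scope
    key = str(scope).strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return SCOPES[key]
    except KeyError:
        raise ParameterError(f"unknown parameter scope {scope!r}") from None


@dataclass
class PhonoSpace:
    """Sign-by-feature binary matrix for one scope, plus its SVD reduction."""

    sign_index: list[str]
    feature_vocab: list[tuple[str, str]]
    onehot: np.ndarray
    scope: ParameterScope
    reduced: np.ndarray | None = None
    svd_rank: int | None = None
    singular_values: np.ndarray | None = None

    @property
    def n_signs(self) -> int:
        return len(self.sign_index)

    @property
    def n_features(self) -> int:
        return len(self.feature_vocab)


def _onehot_matrix(
    lex: Lexicon, scope: ParameterScope
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    vocab = sorted(
        {
            (slot, e.annotations[slot])
            for e in lex.entries
            for slot in scope.slots
            if slot in e.annotations
        }
    )
    if not vocab:
        raise EmptyFeatureSpaceError(
            f"scope {scope.name!r}: no annotation labels observed in any slot"
        )
    col = {pair: j for j, pair in enumerate(vocab)}
    X = np.zeros((len(lex.entries), len(vocab)), dtype=np.float64)
    for i, e in enumerate(lex.entries):
        for slot in scope.slots:
            if slot in e.annotations:
                X[i, col[(slot, e.annotations[slot])]] = 1.0
    return X, vocab


def build_onehot(lex: Lexicon, scope: str | ParameterScope) -> PhonoSpace:
    """Encode a (deduplicated) lexicon as a binary sign-by-feature matrix.

    The feature vocabulary is the sorted union of observed (slot, label)
    pairs over the scope's slots; row *i* has a 1 in column (s, l) iff entry
    *i* carries label *l* at slot *s*.  Missing slots contribute an all-zero
    block rather than an explicit "absent" feature level.
    """
    scope = get_scope(scope)
    X, vocab = _onehot_matrix(lex, scope)
    return PhonoSpace(sign_index=lex.glosses, feature_vocab=vocab, onehot=X, scope=scope)


def _truncated_svd(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic rank-k SVD scores: rows of U_k @ diag(S_k).

    The sign of each singular vector is fixed so that the largest-magnitude
    component of the corresponding right singular vector is positive, making
    the output reproducible across runs and platforms.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(Vt.shape[0]):
        m = np.argmax(np.abs(Vt[j]))
        if Vt[j, m] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U[:, :k] * S[:k], S[:k]


def reduce_svd(space: PhonoSpace, k: int | str | None = None) -> PhonoSpace:
    """Attach the rank-*k* SVD reduction to a phonological space.

    ``k=None`` retains ``min(DEFAULT_SVD_RANK, min(n_signs, n_features))``
    components.  ``k="full"`` (equivalently ``min(n_signs, n_features)``) is
    the full-rank limit in which pairwise cosines equal the raw one-hot
    cosines, useful wherever results should not depend on the rank.
    """
    limit = min(space.n_signs, space.n_features)
    if k is None:
        k = min(DEFAULT_SVD_RANK, limit)
    elif k == "full":
        k = limit
    if not 1 <= k <= limit:
        raise ParameterError(f"svd rank k={k} outside [1, {limit}]")
    reduced, sv = _truncated_svd(space.onehot, k)
    return replace(space, reduced=reduced, svd_rank=k, singular_values=sv)


def normalize_rows(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize rows; returns (normalized matrix, valid-row mask).

    Zero-norm rows (signs without any annotation in the scope) are flagged
    invalid and left as zero rows, so downstream cosines involving them are
    excluded rather than silently treated as 0.
    """
    norms = np.linalg.norm(M, axis=1)
    valid = norms > 0
    out = np.zeros_like(M, dtype=np.float64)
    out[valid] = M[valid] / norms[valid, None]
    return out, valid


def cosine_matrix(M: np.ndarray) -> np.ndarray:
    """Full pairwise cosine matrix; rows with zero norm yield NaN entries."""
    Mn, valid = normalize_rows(M)
    S = Mn @ Mn.T
    if not valid.all():
        S[~valid, :] = np.nan
        S[:, ~valid] = np.nan
    return S


def phono_similarity(space: PhonoSpace, i: int, j: int) -> float:
    """Cosine similarity between signs *i* and *j* in the reduced space.

    Returns NaN (the pair is "undefined") when either sign has no annotation
    in the scope; such pairs are excluded from downstream correlations.
    """
    if space.reduced is None:
        raise ParameterError("reduce_svd must be applied before phono_similarity")
    a, b = space.reduced[i], space.reduced[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("phono_similarity: zero-norm row for pair (%d, %d)", i, j)
        return float("nan")
    return float(a @ b / (na * nb))


class PhonologicalVectorizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from sign annotations to dense phonological coordinates.

    ``fit`` learns the feature vocabulary and the truncated-SVD basis from a
    :class:`~formsem.lexicon.Lexicon`; ``transform`` maps a lexicon onto that
    basis (for the training lexicon this equals the rows of ``U_k S_k``).

    Parameters
    ----------
    scope : str, default "entire"
        Parameter scope: "handshape", "location", "movement" or "entire".
    n_components : int or None, default None
        Retained SVD rank; ``None`` means ``min(50, matrix rank limit)``.
    """

    def __init__(self, scope: str = "entire", n_components: int | None = None):
        self.scope = scope
        self.n_components = n_components

    def fit(self, X: Lexicon, y=None):
        scope = get_scope(self.scope)
        M, vocab = _onehot_matrix(X, scope)
        limit = min(M.shape)
        k = min(DEFAULT_SVD_RANK, limit) if self.n_components is None else self.n_components
        if not 1 <= k <= limit:
            raise ParameterError(f"n_components={k} outside [1, {limit}]")
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        for j in range(Vt.shape[0]):
            m = np.argmax(np.abs(Vt[j]))
            if Vt[j, m] < 0:
                Vt[j] *= -1.0
        self.scope_ = scope
        self.feature_vocab_ = vocab
        self.components_ = Vt[:k]
        self.singular_values_ = S[:k]
        self.n_features_in_ = M.shape[1]
        return self

    def transform(self, X: Lexicon) -> np.ndarray:
        col = {pair: j for j, pair in enumerate(self.feature_vocab_)}
        M = np.zeros((len(X.entries), len(col)), dtype=np.float64)
        for i, e in enumerate(X.entries):
            for slot in self.scope_.slots:
                if slot in e.annotations and (slot, e.annotations[slot]) in col:
                    M[i, col[(slot, e.annotations[slot])]] = 1.0
        return M @ self.components_.T

    def to_phono_space(self, X: Lexicon) -> PhonoSpace:
        """Bundle the fitted encoding of *X* as a :class:`PhonoSpace`."""
        col = {pair: j for j, pair in enumerate(self.feature_vocab_)}
        M = np.zeros((len(X.entries), len(col)), dtype=np.float64)
        for i, e in enumerate(X.entries):
            for slot in self.scope_.slots:
                if slot in e.annotations and (slot, e.annotations[slot]) in col:
                    M[i, col[(slot, e.annotations[slot])]] = 1.0
        return PhonoSpace(
            sign_index=X.glosses,
            feature_vocab=list(self.feature_vocab_),
            onehot=M,
            scope=self.scope_,
            reduced=M @ self.components_.T,
            svd_rank=self.components_.shape[0],
            singular_values=self.singular_values_.copy(),
        )


def export_onehot_mtx(space: PhonoSpace, mtx_path, vocab_csv_path) -> None:
    """Export the one-hot matrix as Matrix Market plus a feature-vocab CSV."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(space.onehot))
    import pandas as pd

    pd.DataFrame(space.feature_vocab, columns=["slot", "label"]).to_csv(
        vocab_csv_path, index=False
    )
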