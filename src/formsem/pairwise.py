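"""Lexicon-wide pairwise analysis.

All unordered sign pairs are enumerated, each pair receives a semantic cosine
similarity and one phonological cosine similarity per parameter scope, and
the lexicon-wide association is summarized by a Pearson correlation with a
two-sided t-test.  For a lexicon of n signs there are n(n-1)/2 pairs (about
1.9 million at n ~ 1950), so the correlation can also be accumulated in
streaming row blocks without materializing the full pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .phonology import normalize_rows
from .semantics import AlignedLexicon

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001


@dataclass
class PairTable:
    """Unordered sign pairs with per-pair similarities."""

    pairs: np.ndarray  # (m, 2) int array, i < j, lexicographic
    n_signs: int
    sem_sim: np.ndarray | None = None
    phono_sim: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self):
        import pandas as pd

        data = {"pair_i": self.pairs[:, 0], "pair_j": self.pairs[:, 1]}
        if self.sem_sim is not None:
            data["sem_sim"] = self.sem_sim
        for scope, vals in self.phono_sim.items():
            data[f"phono_sim_{scope}"] = vals
        return pd.DataFrame(data)


@dataclass
class CorrelationResult:
    """Pearson correlation between semantic and phonological similarity."""

    scope: str
    r: float
    df: int
    p: float
    n_pairs: int
    significant: bool
    alpha: float = DEFAULT_ALPHA
    degenerate: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.degenerate:
            return f"{self.scope}: degenerate (zero variance, n={self.n_pairs})"
        return (
            f"{self.scope}: r({self.df}) = {self.r:.4f}, p = {self.p:.3g}"
            f" ({'significant' if self.significant else 'NS'} at alpha={self.alpha})"
        )


def enumerate_pairs(al: AlignedLexicon | int) -> PairTable:
    """All n(n-1)/2 unordered sign pairs in lexicographic order (i < j)."""
    n = al if isinstance(al, (int, np.integer)) else al.n
    if n < 2:
        raise ParameterError(f"need at least 2 signs to form pairs, got {n}")
    iu = np.triu_indices(n, k=1)
    return PairTable(pairs=np.column_stack(iu), n_signs=int(n))


def _pair_cosines(M: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    Mn, valid = normalize_rows(M)
    sims = np.einsum("ij,ij->i", Mn[pairs[:, 0]], Mn[pairs[:, 1]])
    bad = ~(valid[pairs[:, 0]] & valid[pairs[:, 1]])
    if bad.any():
        sims[bad] = np.nan
    return sims


def fill_similarities(
    pt: PairTable,
    al: AlignedLexicon,
    scopes: Sequence[str] | None = None,
) -> PairTable:
    """Populate semantic and per-scope phonological similarities for all pairs.

    Pairs involving a zero-norm vector in some scope get NaN in that scope
    and are excluded listwise from that scope's correlation (logged count).
    """
    scopes = list(scopes) if scopes is not None else list(al.phono_spaces)
    pt.sem_sim = _pair_cosines(al.sem_vectors, pt.pairs)
    for scope in scopes:
        space = al.phono_spaces[scope]
        M = space.reduced if space.reduced is not None else space.onehot
        sims = _pair_cosines(M, pt.pairs)
        n_undef = int(np.isnan(sims).sum())
        if n_undef:
            logger.info("fill_similarities: %d undefined pairs in scope %r", n_undef, scope)
        pt.phono_sim[scope] = sims
    return pt


def pearson(x, y, alpha: float = DEFAULT_ALPHA, scope: str = "") -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-test.

    The p-value uses the exact t transform t = r sqrt(df / (1 - r^2)) with
    df = n - 2 (scipy's pearsonr).  Zero variance in either argument yields a
    degenerate result that is excluded from reports rather than an exception.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ParameterError(f"need at least 3 observations, got {x.size}")
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pearson: zero variance, result degenerate (n=%d)", n)
        return CorrelationResult(
            scope=scope, r=float("nan"), df=n - 2, p=float("nan"),
            n_pairs=n, significant=False, alpha=alpha, degenerate=True,
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        scope=scope, r=float(r), df=n - 2, p=float(p),
        n_pairs=n, significant=bool(p < alpha), alpha=alpha,
    )


class _StreamingPearson:
    """Combine Pearson sufficient statistics over blocks of pairs.

    Accumulates centered sums around a pilot mean taken from the first block,
    which keeps the final cancellation numerically harmless even for millions
    of similarity values.
    """

    def __init__(self) -> None:
        self.n = 0
        self.cx = self.cy = None  # pilot centers
        self.sx = self.sy = self.sxx = self.syy = self.sxy = 0.0

    def update(self, x: np.ndarray, y: np.ndarray) -> None:
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size == 0:
            return
        if self.cx is None:
            self.cx, self.cy = float(x.mean()), float(y.mean())
        dx, dy = x - self.cx, y - self.cy
        self.n += x.size
        self.sx += dx.sum()
        self.sy += dy.sum()
        self.sxx += (dx * dx).sum()
        self.syy += (dy * dy).sum()
        self.sxy += (dx * dy).sum()

    def result(self, alpha: float, scope: str) -> CorrelationResult:
        n = self.n
        if n < 3:
            return CorrelationResult(
                scope=scope, r=float("nan"), df=max(n - 2, 0), p=float("nan"),
                n_pairs=n, significant=False, alpha=alpha, degenerate=True,
            )
        varx = self.sxx - self.sx ** 2 / n
        vary = self.syy - self.sy ** 2 / n
        if varx <= 0 or vary <= 0:
            return CorrelationResult(
                scope=scope, r=float("nan"), df=n - 2, p=float("nan"),
                n_pairs=n, significant=False, alpha=alpha, degenerate=True,
            )
        r = (self.sxy - self.sx * self.sy / n) / np.sqrt(varx * vary)
        r = float(np.clip(r, -1.0, 1.0))
        df = n - 2
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df))
        return CorrelationResult(
            scope=scope, r=r, df=df, p=p, n_pairs=n,
            significant=bool(p < alpha), alpha=alpha,
        )


def run_pairwise(
    al: AlignedLexicon,
    scopes: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    block_size: int = 512,
) -> dict[str, CorrelationResult]:
    """Lexicon-wide Pearson correlation per scope, streaming over row blocks.

    Equivalent to running :func:`pearson` on a fully materialized pair table,
    but only ``block_size`` rows of the cosine matrices are held at a time, so
    the n-squared pair set never has to exist in memory at once.
    """
    scopes = list(scopes) if scopes is not None else list(al.phono_spaces)
    n = al.n
    if n < 2:
        raise ParameterError("need at least 2 aligned signs")
    sem_n, sem_valid = normalize_rows(al.sem_vectors)
    phono = {}
    for scope in scopes:
        space = al.phono_spaces[scope]
        M = space.reduced if space.reduced is not None else space.onehot
        phono[scope] = normalize_rows(M)
    acc = {scope: _StreamingPearson() for scope in scopes}
    for start in range(0, n - 1, block_size):
        stop = min(start + block_size, n - 1)
        rows = np.arange(start, stop)
        sem_block = sem_n[rows] @ sem_n.T  # (B, n)
        mask = np.zeros_like(sem_block, dtype=bool)
        for bi, i in enumerate(rows):
            mask[bi, i + 1:] = True
        mask &= sem_valid[None, :]
        mask &= sem_valid[rows][:, None]
        for scope in scopes:
            Pn, pvalid = phono[scope]
            ph_block = Pn[rows] @ Pn.T
            m = mask & pvalid[None, :] & pvalid[rows][:, None]
            acc[scope].update(sem_block[m], ph_block[m])
    out = {}
    for scope in scopes:
        res = acc[scope].result(alpha, scope)
        logger.info("run_pairwise: %s", res)
        out[scope] = res
    return out
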