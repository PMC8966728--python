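"""Shared fixtures: tiny hand-built lexicons, toy embedding files, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from formsem import Lexicon, SignEntry, SyntheticConfig, align, generate


def make_entry(gloss, **slots):
    return SignEntry(gloss=gloss, annotations={k: v for k, v in slots.items() if v})


@pytest.fixture
def toy_lexicon():
    """Three fully annotated signs."""
    entries = [
        make_entry(
            "tree",
            hs_dom_begin="5", hs_dom_end="5", hs_nondom_begin="B", hs_nondom_end="B",
            loc_dom_begin="neutral", loc_dom_end="neutral",
            loc_nondom_begin="arm", loc_nondom_end="arm",
            mov_local="twist", mov_path="none", mov_axis="vertical",
            mov_nondom_behavior="base",
        ),
        make_entry(
            "mother",
            hs_dom_begin="5", hs_dom_end="5",
            loc_dom_begin="chin", loc_dom_end="chin",
            mov_local="tap", mov_path="none", mov_axis="none",
        ),
        make_entry(
            "think",
            hs_dom_begin="1", hs_dom_end="1",
            loc_dom_begin="head", loc_dom_end="head",
            mov_local="none", mov_path="straight", mov_axis="midsagittal",
        ),
    ]
    return Lexicon(entries=entries, language="ASL")


@pytest.fixture
def toy_embeddings_text(tmp_path):
    """GloVe-format file covering the toy lexicon, d=4."""
    path = tmp_path / "emb.txt"
    path.write_text(
        "tree 1.0 0.0 0.0 0.0\n"
        "mother 0.0 1.0 0.0 0.0\n"
        "think 0.5 0.5 0.0 0.5\n"
        "extra -1.0 0.0 0.0 0.0\n"
    )
    return path


@pytest.fixture
def small_synthetic():
    """A small planted-cluster lexicon aligned through the real pipeline."""
    cfg = SyntheticConfig(n_clusters=4, cluster_sizes=[8, 8, 8, 8], seed=11)
    syn = generate(cfg)
    al = align(syn.lexicon, syn.embedding)
    return cfg, syn, al


# ---------------------------------------------------------------------------
# Independent oracles (used by unit and acceptance tests; deliberately naive).


def naive_ward_heights(X: np.ndarray) -> np.ndarray:
    """O(n^3) Ward agglomeration via the Lance-Williams update.

    Independent of scipy's nearest-neighbor-chain implementation: keeps a full
    distance matrix and greedily merges the globally cheapest pair, recording
    the merge heights in order.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    D2 = D ** 2
    heights = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                if best is None or D2[a, b] < best[0]:
                    best = (D2[a, b], a, b)
        d2, a, b = best
        heights.append(np.sqrt(d2))
        na, nb = sizes[a], sizes[b]
        for k in active:
            if k in (a, b):
                continue
            nk = sizes[k]
            new = ((na + nk) * D2[a, k] + (nb + nk) * D2[b, k] - nk * d2) / (na + nb + nk)
            D2[a, k] = D2[k, a] = new
        sizes[a] = na + nb
        active.remove(b)
    return np.asarray(heights)


def direct_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Per-point silhouette by the textbook formula; singletons contribute 0."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            scores[i] = 0.0
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def direct_pearson(x, y) -> float:
    """Library-free Pearson coefficient by the definitional formula."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
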