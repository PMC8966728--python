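"""Seeded synthetic lexicons with planted semantic clusters and a tunable
form-meaning coupling.

The generator emulates the statistical structure the analysis is designed to
detect: a lexicon of glosses whose semantic vectors fall into well-separated
Gaussian clusters, and whose categorical phonological annotations share their
cluster's canonical labels to a controllable degree.

Coupling model
--------------
Each cluster draws one canonical label per annotation slot.  A sign's
semantic vector is ``center + sem_within_sd * eps`` with ``eps ~ N(0, I_d)``;
its prototypicality percentile is ``t = chi2.cdf(||eps||^2, d)`` (uniform on
[0, 1] by construction).  In each coupled slot the sign adopts the canonical
label with probability ``rho ** (4 t)`` and otherwise draws uniformly from
the slot's inventory; uncoupled scopes always draw uniformly.  Tying label
adoption to semantic prototypicality makes semantically central cluster
members also phonologically canonical, which plants a *within-cluster*
form-meaning correlation that is zero at ``rho = 0``, grows monotonically
through moderate ``rho``, and degenerates to identical forms at ``rho = 1``
(every sign adopts every canonical label).  A flat adoption probability
would make within-cluster semantic and phonological fluctuations independent
and leave nothing for the within-cluster analysis to recover.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .lexicon import Lexicon, SignEntry, write_lexicon
from .phonology import SCOPES
from .semantics import EmbeddingTable, write_embeddings

logger = logging.getLogger(__name__)

#: Exponent linking semantic prototypicality to canonical-label adoption.
PROTOTYPICALITY_EXPONENT = 4.0

#: Realistic per-slot inventory sizes: handshape systems distinguish dozens of
#: configurations, location systems a few major zones with minor distinctions,
#: movement categories fewer contrastive values.
DEFAULT_SLOT_INVENTORIES: dict[str, int] = {
    "hs_dom_begin": 30,
    "hs_dom_end": 30,
    "hs_nondom_begin": 30,
    "hs_nondom_end": 30,
    "loc_dom_begin": 20,
    "loc_dom_end": 20,
    "loc_nondom_begin": 20,
    "loc_nondom_end": 20,
    "mov_local": 12,
    "mov_path": 10,
    "mov_axis": 6,
    "mov_nondom_behavior": 6,
}

_PARAM_OF_SLOT = {
    slot: name
    for name, scope in SCOPES.items()
    if name != "entire"
    for slot in scope.slots
}


@dataclass
class SyntheticConfig:
    """Generative conditions for a synthetic lexicon."""

    n_clusters: int = 10
    cluster_sizes: Sequence[int] | None = None  # default: 30 signs per cluster
    sem_dim: int = 100
    sem_within_sd: float = 0.5
    sem_between_sd: float = 2.0
    coupling: float = 0.5
    slot_inventories: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SLOT_INVENTORIES)
    )
    coupled_scopes: tuple[str, ...] = ("handshape", "location", "movement")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            self.cluster_sizes = [30] * self.n_clusters
        self.cluster_sizes = list(self.cluster_sizes)
        if self.n_clusters < 1 or len(self.cluster_sizes) != self.n_clusters:
            raise ParameterError("cluster_sizes must list one size per cluster")
        if any(s < 1 for s in self.cluster_sizes):
            raise ParameterError("cluster sizes must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ParameterError("coupling must lie in [0, 1]")
        if any(v < 2 for v in self.slot_inventories.values()):
            raise ParameterError("every slot inventory needs at least 2 labels")
        unknown = set(self.coupled_scopes) - {"handshape", "location", "movement"}
        if unknown:
            raise ParameterError(f"unknown coupled scopes {sorted(unknown)}")

    @property
    def n(self) -> int:
        return int(sum(self.cluster_sizes))


@dataclass
class SyntheticLexicon:
    """Generated lexicon, its embedding table, and the generative ground truth."""

    lexicon: Lexicon
    embedding: EmbeddingTable
    truth: dict


def generate(cfg: SyntheticConfig) -> SyntheticLexicon:
    """Draw a synthetic lexicon; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n, K, d = cfg.n, cfg.n_clusters, cfg.sem_dim
    centers = rng.normal(0.0, cfg.sem_between_sd, size=(K, d))
    cluster_of = np.repeat(np.arange(K), cfg.cluster_sizes)
    eps = rng.normal(0.0, 1.0, size=(n, d))
    sem_vectors = centers[cluster_of] + cfg.sem_within_sd * eps
    proto = stats.chi2.cdf((eps ** 2).sum(axis=1), df=d)
    p_adopt = cfg.coupling ** (PROTOTYPICALITY_EXPONENT * proto)

    canonical: dict[int, dict[str, str]] = {c: {} for c in range(K)}
    ann_codes: dict[str, np.ndarray] = {}
    for slot, inv in cfg.slot_inventories.items():
        canon = rng.integers(0, inv, size=K)
        uniform = rng.integers(0, inv, size=n)
        if _PARAM_OF_SLOT[slot] in cfg.coupled_scopes:
            adopt = rng.random(n) < p_adopt
            codes = np.where(adopt, canon[cluster_of], uniform)
        else:
            codes = uniform
        ann_codes[slot] = codes
        for c in range(K):
            canonical[c][slot] = f"l{canon[c]:02d}"

    width = max(4, len(str(n)))
    glosses = [f"s{i:0{width}d}" for i in range(n)]
    entries = [
        SignEntry(
            gloss=glosses[i],
            language="synthetic",
            variant_index=1,
            annotations={slot: f"l{ann_codes[slot][i]:02d}" for slot in cfg.slot_inventories},
        )
        for i in range(n)
    ]
    lexicon = Lexicon(entries=entries, language="synthetic", provenance="formsem synthetic generator")
    embedding = EmbeddingTable(tokens=list(glosses), vectors=sem_vectors, dimension=d)
    truth = {
        "cluster_of": cluster_of.tolist(),
        "canonical_labels": {str(c): canonical[c] for c in range(K)},
        "prototypicality": proto.tolist(),
        "config": _config_dict(cfg),
    }
    return SyntheticLexicon(lexicon=lexicon, embedding=embedding, truth=truth)


def _config_dict(cfg: SyntheticConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["cluster_sizes"] = list(map(int, out["cluster_sizes"]))
    out["coupled_scopes"] = list(out["coupled_scopes"])
    return out


def planted_effect(
    cfg: SyntheticConfig,
    scope: str = "entire",
    n_reps: int = 40,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the within-cluster Pearson r implied by *cfg*.

    Replicates the generative draw ``n_reps`` times, pools the within-cluster
    pairs using the *true* cluster labels, correlates raw one-hot phonological
    cosines (the encoding-independent full-rank limit) against semantic
    cosines, and returns (mean r, standard error of the mean).  This is the
    recovery target for the estimation pipeline, which instead has to find
    the clusters itself.
    """
    from .phonology import build_onehot, cosine_matrix

    base_seed = cfg.seed if seed is None else seed
    rs = []
    for rep in range(n_reps):
        rep_cfg = dataclasses.replace(cfg, seed=base_seed + 100_003 * rep)
        syn = generate(rep_cfg)
        S_sem = cosine_matrix(syn.embedding.vectors)
        S_ph = cosine_matrix(build_onehot(syn.lexicon, scope).onehot)
        labels = np.asarray(syn.truth["cluster_of"])
        xs, ys = [], []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if idx.size < 2:
                continue
            iu = np.triu_indices(idx.size, k=1)
            xs.append(S_sem[np.ix_(idx, idx)][iu])
            ys.append(S_ph[np.ix_(idx, idx)][iu])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # degenerate draw (e.g. coupling 1: all forms canonical)
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    if not rs:
        return float("nan"), float("nan")
    rs = np.asarray(rs)
    return float(rs.mean()), float(rs.std(ddof=1) / np.sqrt(len(rs)))


def analysis_scale_fixture(seed: int = 0) -> SyntheticLexicon:
    """A lexicon at realistic analysis scale for smoke and contrast checks.

    About 1,950 signs in 60 semantic clusters, all twelve annotation slots,
    coupling 0.5 confined to the movement parameter (one language-specific
    systematic scope, the other parameters arbitrary).
    """
    K, n = 60, 1950
    sizes = np.full(K, n // K)
    sizes[: n - sizes.sum()] += 1
    cfg = SyntheticConfig(
        n_clusters=K,
        cluster_sizes=sizes.tolist(),
        coupling=0.5,
        coupled_scopes=("movement",),
        seed=seed,
    )
    return generate(cfg)


def write_synthetic(syn: SyntheticLexicon, out_dir: str | Path) -> dict[str, Path]:
    """Write lexicon.tsv, embeddings.txt (GloVe format) and truth.json."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lexicon": out / "lexicon.tsv",
        "embeddings": out / "embeddings.txt",
        "truth": out / "truth.json",
    }
    write_lexicon(syn.lexicon, paths["lexicon"])
    write_embeddings(syn.embedding, paths["embeddings"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(syn.truth, fh, indent=1)
        fh.write("\n")
    logger.info("write_synthetic: wrote %d signs to %s", len(syn.lexicon), out)
    return paths
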