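"""Semantic vector spaces: embedding loading and lexicon alignment.

Sign meanings are represented by pre-trained word embeddings (GloVe plain-text
format: one token followed by *d* floats per line).  Only signs whose
normalized gloss has an embedding vector enter the analysis; the aligned
lexicon keeps the semantic vectors and per-scope phonological spaces
index-aligned over the retained entries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmbeddingFormatError, EmptyFeatureSpaceError, NoOverlapError
from .lexicon import Lexicon
from .phonology import PhonoSpace, build_onehot, get_scope, reduce_svd

logger = logging.getLogger(__name__)

DEFAULT_SCOPES: tuple[str, ...] = ("handshape", "location", "movement", "entire")


@dataclass
class EmbeddingTable:
    """Token -> dense semantic vector mapping of fixed dimension."""

    tokens: list[str]
    vectors: np.ndarray
    dimension: int

    def __post_init__(self) -> None:
        self.token_index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self.token_index

    def __len__(self) -> int:
        return len(self.tokens)

    def get(self, token: str) -> np.ndarray:
        return self.vectors[self.token_index[token]]


def load_embeddings(path: str | Path, dimension: int | None = None) -> EmbeddingTable:
    """Parse a GloVe-format text file (optionally gzipped).

    Malformed lines (wrong float count, unparseable floats) are skipped with
    a logged count; duplicate tokens keep their first occurrence.  The
    declared ``dimension`` is verified against the first parseable line.

    Raises
    ------
    EmbeddingFormatError
        On an empty file or a dimension mismatch.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    tokens: list[str] = []
    rows: list[np.ndarray] = []
    index: dict[str, int] = {}
    d: int | None = None
    skipped = 0
    duplicates = 0
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                skipped += 1
                continue
            token = parts[0]
            try:
                vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
            except ValueError:
                skipped += 1
                continue
            if d is None:
                d = vec.size
                if dimension is not None and d != dimension:
                    raise EmbeddingFormatError(
                        f"{path}: declared dimension {dimension} but first line has {d}"
                    )
            if vec.size != d:
                skipped += 1
                continue
            if token in index:
                duplicates += 1
                continue
            index[token] = len(tokens)
            tokens.append(token)
            rows.append(vec)
    if not tokens:
        raise EmbeddingFormatError(f"{path}: no parseable embedding lines")
    if skipped:
        logger.warning("%s: skipped %d malformed lines", path, skipped)
    if duplicates:
        logger.warning("%s: ignored %d duplicate tokens (first kept)", path, duplicates)
    logger.info("%s: loaded %d vectors of dimension %d", path, len(tokens), d)
    return EmbeddingTable(tokens=tokens, vectors=np.vstack(rows), dimension=int(d))


def write_embeddings(table: EmbeddingTable, path: str | Path, fmt: str = "%.6f") -> None:
    """Write an embedding table in GloVe plain-text format."""
    with open(path, "w", encoding="utf-8") as fh:
        for token, row in zip(table.tokens, table.vectors):
            fh.write(token + " " + " ".join(fmt % x for x in row) + "\n")


@dataclass
class AlignedLexicon:
    """Lexicon subset with embeddings, index-aligned to per-scope phonological spaces."""

    entries: Lexicon
    sem_vectors: np.ndarray
    phono_spaces: dict[str, PhonoSpace]
    n: int

    @property
    def glosses(self) -> list[str]:
        return self.entries.glosses


def align(
    lex: Lexicon,
    emb: EmbeddingTable,
    scopes: Sequence[str] = DEFAULT_SCOPES,
    svd_rank: int | None = None,
) -> AlignedLexicon:
    """Retain the entries whose gloss has an embedding; build phonological spaces.

    One :class:`PhonoSpace` per requested scope is built over the retained
    entries (so semantic rows and phonological rows stay index-aligned).  A
    scope in which no sign carries any annotation is dropped with a warning.

    Raises
    ------
    NoOverlapError
        If no gloss at all has an embedding vector.
    """
    keep = [e for e in lex.entries if e.gloss in emb]
    dropped = len(lex.entries) - len(keep)
    if not keep:
        raise NoOverlapError("no lexicon gloss has an embedding vector")
    logger.info("align: retained %d signs, dropped %d without embeddings", len(keep), dropped)
    sub = Lexicon(entries=keep, language=lex.language, provenance=lex.provenance)
    sem = np.vstack([emb.get(e.gloss) for e in keep])
    spaces: dict[str, PhonoSpace] = {}
    for scope in scopes:
        name = get_scope(scope).name
        try:
            spaces[name] = reduce_svd(build_onehot(sub, name), svd_rank)
        except EmptyFeatureSpaceError:
            logger.warning("align: scope %r dropped (empty feature space)", name)
    return AlignedLexicon(entries=sub, sem_vectors=sem, phono_spaces=spaces, n=len(keep))


def sem_similarity(al: AlignedLexicon, i: int, j: int) -> float:
    """Cosine similarity of the semantic vectors of signs *i* and *j*.

    NaN (undefined) if either vector is zero, matching the phonological
    similarity contract.
    """
    a, b = al.sem_vectors[i], al.sem_vectors[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("sem_similarity: zero vector for pair (%d, %d)", i, j)
        return float("nan")
    return float(a @ b / (na * nb))
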