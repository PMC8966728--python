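"""Reading, validating, deduplicating and writing sign annotation tables.

A lexicon is an ordered list of sign entries.  Each entry carries a gloss (the
written identifier of the sign), a language label, a variant index (1 = first
listed entry for that gloss) and a mapping from annotation slots to categorical
labels.  The twelve slots cover the three major phonological parameters:
handshape and location are each annotated for the dominant and non-dominant
hand at the beginning and end of the sign; movement is annotated for local
movement, path movement, axis and the behavior of the non-dominant hand.
One-handed signs simply lack the non-dominant slots.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import LexiconFormatError

logger = logging.getLogger(__name__)

#: The fixed annotation schema, in canonical order.
SCHEMA_SLOTS: tuple[str, ...] = (
    "hs_dom_begin",
    "hs_dom_end",
    "hs_nondom_begin",
    "hs_nondom_end",
    "loc_dom_begin",
    "loc_dom_end",
    "loc_nondom_begin",
    "loc_nondom_end",
    "mov_local",
    "mov_path",
    "mov_axis",
    "mov_nondom_behavior",
)

_WS = re.compile(r"\s+")


def normalize_gloss(gloss: str) -> str:
    """Lowercase, strip surrounding whitespace, hyphenate internal whitespace.

    Glosses have to match embedding tokens, which are lowercase single tokens,
    so ``"Roller Coaster "`` becomes ``"roller-coaster"``.
    """
    return _WS.sub("-", str(gloss).strip().lower())


@dataclass
class SignEntry:
    """One lexical sign: gloss, provenance and its categorical annotations."""

    gloss: str
    language: str = "synthetic"
    variant_index: int = 1
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gloss = normalize_gloss(self.gloss)
        if not self.gloss:
            raise LexiconFormatError("gloss is empty after normalization")
        if self.variant_index < 1:
            raise LexiconFormatError(
                f"variant_index must be >= 1, got {self.variant_index}"
            )
        for slot, label in self.annotations.items():
            if label is None or str(label) == "":
                raise LexiconFormatError(f"empty label for slot {slot!r}")


@dataclass
class Lexicon:
    """Ordered collection of sign entries for one language."""

    entries: list[SignEntry]
    language: str = "synthetic"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def glosses(self) -> list[str]:
        return [e.gloss for e in self.entries]

    def to_frame(self, schema: Sequence[str] = SCHEMA_SLOTS) -> pd.DataFrame:
        """Tabular view: gloss, variant, language plus one column per slot."""
        rows = []
        for e in self.entries:
            row = {"gloss": e.gloss, "variant": e.variant_index, "language": e.language}
            for slot in schema:
                row[slot] = e.annotations.get(slot, "")
            rows.append(row)
        return pd.DataFrame(rows)


def read_lexicon(
    path: str | Path,
    schema: Sequence[str] = SCHEMA_SLOTS,
    language: str | None = None,
) -> Lexicon:
    """Read a UTF-8 TSV/CSV annotation table into a :class:`Lexicon`.

    The header must name a ``gloss`` column; ``variant`` and ``language``
    columns are optional, as is any subset of the schema slots.  Unknown
    columns are ignored with a warning.  Empty cells become missing slots.
    Row order is preserved (it defines "first listed variant").

    Raises
    ------
    LexiconFormatError
        If the gloss column is missing or header names are duplicated.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None:
        raise LexiconFormatError(f"{path}: file is empty")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise LexiconFormatError(f"{path}: duplicate header column {name!r}")
        seen.add(name)
    if "gloss" not in seen:
        raise LexiconFormatError(f"{path}: no 'gloss' column in header {header}")

    known = {"gloss", "variant", "language", *schema}
    unknown = [c for c in header if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        ann = {
            slot: str(row[slot]).strip()
            for slot in schema
            if slot in df.columns and str(row[slot]).strip() != ""
        }
        variant = int(row["variant"]) if "variant" in df.columns and str(row["variant"]).strip() else 1
        lang = row["language"] if "language" in df.columns and str(row["language"]).strip() else (language or "synthetic")
        entries.append(
            SignEntry(gloss=row["gloss"], language=lang, variant_index=variant, annotations=ann)
        )
    lex = Lexicon(entries=entries, language=language or (entries[0].language if entries else "synthetic"), provenance=str(path))
    logger.info("%s: read %d entries", path, len(lex))
    return lex


def write_lexicon(lex: Lexicon, path: str | Path, schema: Sequence[str] = SCHEMA_SLOTS) -> None:
    """Write a lexicon as a TSV/CSV table that :func:`read_lexicon` round-trips."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    lex.to_frame(schema).to_csv(path, sep=sep, index=False)


def dedup_first_variant(lex: Lexicon) -> Lexicon:
    """Keep only the first-occurring entry per gloss, preserving order.

    Lexical databases list several variants for some signs (the BSL sign
    "mauve" has 15 entries); retaining all of them would overweight those
    glosses, so only the first listed variant is analyzed.
    """
    seen: set[str] = set()
    kept = []
    for entry in lex.entries:
        if entry.gloss not in seen:
            seen.add(entry.gloss)
            kept.append(entry)
    removed = len(lex.entries) - len(kept)
    if removed:
        logger.info("dedup_first_variant: removed %d duplicate entries", removed)
    return Lexicon(entries=kept, language=lex.language, provenance=lex.provenance)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if records is None:
        raise ValueError("records must not be None")
    return pd.DataFrame(records)


def write_table(records, path: str | Path, format: str | None = None) -> None:
    """Write a result table as CSV (RFC 4180) or JSON.

    Floats are written with 12 significant digits so a read-back reproduces
    string/integer fields exactly and floats to 12 significant digits.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    df = _as_frame(records)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        def _round12(v):
            if isinstance(v, float):
                return float(f"{v:.12g}")
            return v

        payload = [
            {k: _round12(v) for k, v in rec.items()}
            for rec in df.to_dict(orient="records")
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {fmt!r}")


def read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown table format {fmt!r}")
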