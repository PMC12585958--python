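"""Reading, cleaning and tokenizing protein sequence corpora, and PPI pair tables.

Sequences are restricted to the 20 standard amino acids; everything else
(ambiguity codes B/Z/X, selenocysteine U, pyrrolysine O, gaps, whitespace)
is filtered out.  Cleaned sequences are capped at a maximum length and joined
into a single token stream with a reserved separator token between proteins,
so that downstream n-gram graphs can mark protein boundaries.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("protgram")

#: The 20 standard amino acid one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Reserved boundary token inserted between concatenated sequences.
DEFAULT_SEPARATOR: str = "|"

#: Maximum retained residues per sequence.
MAX_SEQUENCE_LENGTH: int = 10_000


class FastaFormatError(ValueError):
    """Raised when a FASTA file has sequence data before any header line."""


class PairTableError(ValueError):
    """Raised for schema or consistency problems in a PPI pair table."""


@dataclass
class CleanCorpus:
    """An ordered collection of cleaned residue strings.

    Invariants: every character of every sequence is a standard amino acid,
    every sequence is non-empty and at most ``MAX_SEQUENCE_LENGTH`` long, and
    the separator token never occurs inside a sequence.
    """

    sequences: list[str]
    separator: str = DEFAULT_SEPARATOR
    source_path: str = ""
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.separator) != 1 or self.separator in _AA_SET:
            raise ValueError(
                "separator must be a single character outside the amino acid alphabet"
            )
        if self.ids and len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")

    def token_stream(self) -> str:
        """All sequences joined by single separator tokens."""
        return self.separator.join(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (possibly line-wrapped) FASTA file into ``{record_id: raw_sequence}``.

    Raises :class:`FastaFormatError` naming the offending line if sequence
    data appears before any ``>`` header.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno} contains sequence data before any '>' header"
                )
            break
    records: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records[rec.id] = str(rec.seq)
    return records


def clean_sequence(raw: str, max_len: int = MAX_SEQUENCE_LENGTH) -> str:
    """Uppercase, keep only the 20 standard residues, then cap the length.

    The cap is applied after filtering so that exactly the first ``max_len``
    retained residues survive.  An empty result is permitted.
    """
    kept = [c for c in raw.upper() if c in _AA_SET]
    return "".join(kept[:max_len])


def build_corpus(
    records: Mapping[str, str] | Iterable[str],
    separator: str = DEFAULT_SEPARATOR,
    max_len: int = MAX_SEQUENCE_LENGTH,
    source_path: str = "",
) -> CleanCorpus:
    """Clean every raw record and assemble a :class:`CleanCorpus`.

    Records cleaning to the empty string are dropped with a logged warning.
    Input order is preserved, so the corpus (and every graph built from it)
    is deterministic in the input.
    """
    if isinstance(records, Mapping):
        items = list(records.items())
    else:
        items = [(str(i), seq) for i, seq in enumerate(records)]
    ids: list[str] = []
    seqs: list[str] = []
    n_dropped = 0
    for rid, raw in items:
        cleaned = clean_sequence(raw, max_len=max_len)
        if not cleaned:
            n_dropped += 1
            continue
        ids.append(rid)
        seqs.append(cleaned)
    if n_dropped:
        logger.warning("dropped %d sequence(s) that cleaned to empty", n_dropped)
    return CleanCorpus(sequences=seqs, separator=separator, source_path=source_path, ids=ids)


# ---------------------------------------------------------------------------
# PPI pair tables
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ("id_a", "id_b", "label")


@dataclass
class PairTable:
    """Labeled protein pairs: columns id_a, id_b and a binary label."""

    pairs: pd.DataFrame
    id_space: str = "UniProtKB"

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise PairTableError(f"pair table missing column(s): {missing}")
        df = self.pairs.loc[:, list(PAIR_COLUMNS)].copy()
        if not set(df["label"].unique()) <= {0, 1}:
            raise PairTableError("labels must be binary (0/1)")
        df["label"] = df["label"].astype(int)
        key = df.apply(lambda r: tuple(sorted((r["id_a"], r["id_b"]))), axis=1)
        nlab = df.groupby(key)["label"].nunique()
        conflicts = list(nlab.index[nlab > 1])
        if conflicts:
            raise PairTableError(f"conflicting labels for unordered pair(s): {conflicts}")
        self.pairs = df.reset_index(drop=True)

    def class_counts(self) -> tuple[int, int]:
        """(positives, negatives)."""
        pos = int((self.pairs["label"] == 1).sum())
        return pos, len(self.pairs) - pos

    def __len__(self) -> int:
        return len(self.pairs)


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "parquet" if ext in {".parquet", ".pq"} else "tsv"


def read_pairs(path: str | os.PathLike, fmt: str | None = None) -> PairTable:
    """Read a pair table from TSV (header id_a, id_b, label) or Parquet."""
    fmt = _infer_format(path, fmt)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown pair table format: {fmt!r}")
    return PairTable(pairs=df)


def write_pairs(table: PairTable, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a pair table; ``read_pairs(write_pairs(t)) == t`` in both formats."""
    fmt = _infer_format(path, fmt)
    if fmt == "parquet":
        table.pairs.to_parquet(path, index=False)
    elif fmt == "tsv":
        table.pairs.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown pair table format: {fmt!r}")
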