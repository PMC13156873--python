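"""Labeled citation corpora: the screening universe with oracle labels.

A corpus is an ordered collection of records, each a title + abstract pair
with a binary relevance label (1 = included in the source review,
0 = excluded).  The labels are the ground truth against which simulated
screening runs are scored; they are never shown to the ranker before a
record is "screened".

Two on-disk dialects are supported: delimited text following the SYNERGY
repository layout (one row per record, columns mapped by name) and the RIS
tag format (TI/AB plus a configurable label tag).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._util import round_half_up

#: label spellings accepted by default; anything else is a hard error.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "0": 0,
    "1": 1,
    "included": 1,
    "excluded": 0,
    "include": 1,
    "exclude": 0,
    "relevant": 1,
    "irrelevant": 0,
}

#: default column names for the delimited dialect (SYNERGY-style exports).
DEFAULT_COLUMNS: dict[str, str] = {
    "id": "record_id",
    "title": "title",
    "abstract": "abstract",
    "label": "label_included",
}


@dataclass(frozen=True)
class LabeledRecord:
    """One citation: identifier, title, abstract, oracle relevance label."""

    record_id: str
    title: str
    abstract: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def text(self) -> str:
        """Screening text: title and abstract concatenated."""
        return f"{self.title} {self.abstract}".strip()

    @property
    def is_empty(self) -> bool:
        """True when both title and abstract are blank after stripping."""
        return not self.text


@dataclass
class Corpus:
    """Ordered collection of labeled records.

    Records whose title and abstract are both empty are retained (dropping
    them would change N and every percentage statistic) but flagged; the
    screener always ranks them last.
    """

    records: list[LabeledRecord]
    name: str = "corpus"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, rec in enumerate(self.records):
            if rec.record_id in self._index:
                raise ValueError(f"duplicate record_id: {rec.record_id!r}")
            self._index[rec.record_id] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> LabeledRecord:
        return self.records[self._index[record_id]]

    def row_of(self, record_id: str) -> int:
        """Corpus row index of a record (the deterministic tie-break key)."""
        return self._index[record_id]

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def R(self) -> int:
        return sum(r.label for r in self.records)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    @property
    def flagged_empty(self) -> list[str]:
        return [r.record_id for r in self.records if r.is_empty]

    def validate_for_screening(self) -> None:
        """A screening simulation needs N >= 2 and 1 <= R < N."""
        if self.N < 2:
            raise ValueError(f"corpus has {self.N} records; need at least 2")
        if self.R < 1:
            raise ValueError("corpus has no relevant records")
        if self.R >= self.N:
            raise ValueError("corpus has no irrelevant records")


def corpus_summary(corpus: Corpus) -> tuple[int, int, float]:
    """(N, R, prevalence %) with the prevalence half-up rounded to 1 decimal."""
    if corpus.N == 0:
        raise ValueError("empty corpus")
    prevalence = round_half_up(corpus.R / corpus.N * 100, 1)
    return corpus.N, corpus.R, prevalence


def _parse_label(raw: object, label_map: Mapping[str, int], row: int) -> int:
    key = str(raw).strip().lower()
    if key.endswith(".0"):  # pandas may render integer labels as floats
        key = key[:-2]
    if key not in label_map:
        raise ValueError(f"unparseable label {raw!r} in data row {row}")
    return label_map[key]


def read_labeled_corpus(
    path: str | Path,
    dialect: str = "synergy-delimited",
    *,
    columns: Mapping[str, str] | None = None,
    label_map: Mapping[str, int] | None = None,
    sep: str = ",",
    label_tag: str = "C1",
    name: str | None = None,
) -> Corpus:
    """Read a labeled corpus from delimited text or RIS.

    Parameters
    ----------
    dialect
        ``"synergy-delimited"`` (columns mapped by name via *columns*, UTF-8,
        separator stated explicitly — never autodetected) or ``"ris"``.
    columns
        Mapping with keys ``id``, ``title``, ``abstract``, ``label`` naming
        the file's columns; defaults to the SYNERGY export layout.
    label_map
        Accepted label spellings -> {0,1}.  Unknown values are hard errors;
        labels are never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    name = name if name is not None else path.stem

    if dialect == "synergy-delimited":
        cols = dict(DEFAULT_COLUMNS)
        if columns:
            cols.update(columns)
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
        if cols["label"] not in df.columns:
            raise ValueError(
                f"missing label column {cols['label']!r} in {path} "
                f"(columns: {list(df.columns)})"
            )
        have_id = cols["id"] in df.columns
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            row_d = dict(zip(df.columns, row))
            rid = str(row_d[cols["id"]]) if have_id else f"row-{i}"
            records.append(
                LabeledRecord(
                    record_id=rid,
                    title=str(row_d.get(cols["title"], "")),
                    abstract=str(row_d.get(cols["abstract"], "")),
                    label=_parse_label(row_d[cols["label"]], label_map, i),
                )
            )
        return Corpus(records, name=name)

    if dialect == "ris":
        return _read_ris(path, label_tag=label_tag, label_map=label_map, name=name)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    dialect: str = "synergy-delimited",
    *,
    sep: str = ",",
    label_tag: str = "C1",
) -> Path:
    """Write a corpus so that reading it back reproduces records exactly.

    Delimited output uses minimal quoting, so embedded separators and
    newlines in abstracts survive the round trip; empty fields are written
    as empty strings, not as missing values.
    """
    path = Path(path)
    if dialect == "synergy-delimited":
        df = pd.DataFrame(
            {
                DEFAULT_COLUMNS["id"]: [r.record_id for r in corpus],
                DEFAULT_COLUMNS["title"]: [r.title for r in corpus],
                DEFAULT_COLUMNS["abstract"]: [r.abstract for r in corpus],
                DEFAULT_COLUMNS["label"]: [r.label for r in corpus],
            }
        )
        df.to_csv(path, sep=sep, index=False, encoding="utf-8", quoting=csv.QUOTE_MINIMAL)
    elif dialect == "ris":
        _write_ris(corpus, path, label_tag=label_tag)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# --- minimal RIS tag format -------------------------------------------------
# Tag lines look like "TI  - some title"; a record ends with "ER  - ".
# Continuation lines (no tag) extend the previous tag's value.

_RIS_TAGS = {"TY", "ID", "TI", "AB", "ER"}


def _read_ris(
    path: Path, *, label_tag: str, label_map: Mapping[str, int], name: str
) -> Corpus:
    records: list[LabeledRecord] = []
    fields: dict[str, str] = {}
    last_tag: str | None = None
    n_seen = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            tag, sep_, value = line[:2], line[2:6], line[6:]
            if len(line) >= 6 and sep_ == "  - " and (tag in _RIS_TAGS or tag == label_tag):
                if tag == "ER":
                    if label_tag not in fields:
                        raise ValueError(
                            f"record {n_seen} lacks label tag {label_tag!r} in {path}"
                        )
                    records.append(
                        LabeledRecord(
                            record_id=fields.get("ID", f"ris-{n_seen}"),
                            title=fields.get("TI", ""),
                            abstract=fields.get("AB", ""),
                            label=_parse_label(fields[label_tag], label_map, n_seen),
                        )
                    )
                    n_seen += 1
                    fields, last_tag = {}, None
                else:
                    fields[tag] = value
                    last_tag = tag
            elif line.strip() and last_tag is not None:
                fields[last_tag] += " " + line.strip()
    return Corpus(records, name=name)


def _write_ris(corpus: Corpus, path: Path, *, label_tag: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write("TY  - JOUR\n")
            fh.write(f"ID  - {rec.record_id}\n")
            # RIS is line-oriented; embedded newlines are folded to spaces.
            fh.write(f"TI  - {' '.join(rec.title.splitlines())}\n")
            fh.write(f"AB  - {' '.join(rec.abstract.splitlines())}\n")
            fh.write(f"{label_tag}  - {rec.label}\n")
            fh.write("ER  - \n")


def corpus_from_frame(df: pd.DataFrame, name: str = "corpus") -> Corpus:
    """Build a Corpus from a DataFrame with record_id/title/abstract/label."""
    records = [
        LabeledRecord(str(r.record_id), str(r.title), str(r.abstract), int(r.label))
        for r in df.itertuples(index=False)
    ]
    return Corpus(records, name=name)


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in corpus],
            "title": [r.title for r in corpus],
            "abstract": [r.abstract for r in corpus],
            "label": [r.label for r in corpus],
        }
    )
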