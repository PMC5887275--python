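"""Readers and writers for corpora, queries, qrels and run files.

The canonical corpus dialect is line-delimited JSON, one record per
line with keys ``docno``/``title``/``repository``/``text``/``metadata``.
A second reader accepts TREC-style tagged text (``<DOC>`` blocks with
``<DOCNO>`` etc.), which is how dataset-description corpora such as the
bioCADDIE challenge snapshot are conventionally distributed. Qrels and
run files use the standard TREC formats.

Readers are streaming generators: a corpus is never held in memory in
full, only the set of docnos seen so far (for duplicate detection).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator
import json

logger = logging.getLogger(__name__)

DIALECTS = ("lines", "trec")


class CorpusFormatError(ValueError):
    """Malformed corpus / qrels / run input; message names the offending record."""


@dataclass
class DatasetRecord:
    """One indexable dataset description with fielded text.

    ``metadata`` holds the repository-level description appended by
    :func:`augment_metadata`; it is empty until augmentation.
    """

    docno: str
    title: str
    repository: str
    text: str
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.docno:
            raise CorpusFormatError("record with empty docno")
        if not self.repository:
            raise CorpusFormatError(f"record {self.docno!r} has empty repository")


@dataclass
class Query:
    qid: str
    raw_text: str

    def __post_init__(self) -> None:
        if not self.qid or not self.raw_text:
            raise CorpusFormatError("query must have non-empty qid and text")


@dataclass
class RepositoryDescription:
    """Curated free-text description of a source repository ('About' page)."""

    repository: str
    about_text: str

    def __post_init__(self) -> None:
        if not self.repository:
            raise CorpusFormatError("repository description with empty label")


class QrelsTable:
    """Graded relevance judgments: (qid, docno) -> grade in {0, 1, 2}."""

    GRADES = (0, 1, 2)

    def __init__(self, entries: dict[tuple[str, str], int] | None = None) -> None:
        self.entries: dict[tuple[str, str], int] = {}
        for (qid, docno), grade in (entries or {}).items():
            self.add(qid, docno, grade)

    def add(self, qid: str, docno: str, grade: int) -> None:
        if grade not in self.GRADES:
            raise CorpusFormatError(f"grade {grade} for ({qid}, {docno}) not in 0..2")
        self.entries[(qid, docno)] = grade

    def grade(self, qid: str, docno: str) -> int:
        """Judged grade, with unjudged documents counting as 0."""
        return self.entries.get((qid, docno), 0)

    def judged(self, qid: str) -> dict[str, int]:
        return {d: g for (q, d), g in self.entries.items() if q == qid}

    @property
    def qids(self) -> list[str]:
        return sorted({q for q, _ in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, QrelsTable) and self.entries == other.entries


# -- corpus ---------------------------------------------------------------

_REC_KEYS = ("docno", "title", "repository", "text", "metadata")


def read_corpus(path: str | Path, dialect: str = "lines") -> Iterator[DatasetRecord]:
    """Stream :class:`DatasetRecord` objects from ``path`` in file order.

    ``dialect`` is ``"lines"`` (JSON lines, canonical) or ``"trec"``
    (tagged text). A missing METADATA tag yields an empty metadata
    field; a missing or empty DOCNO, or a duplicate docno, is an error
    naming the record.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    seen: set[str] = set()
    reader = _read_lines if dialect == "lines" else _read_trec
    with open(path, encoding="utf-8") as handle:
        for rec in reader(handle):
            if rec.docno in seen:
                raise CorpusFormatError(f"duplicate docno {rec.docno!r}")
            seen.add(rec.docno)
            yield rec


def _read_lines(handle: IO[str]) -> Iterator[DatasetRecord]:
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"line {lineno}: invalid record ({exc.msg})") from exc
        if not isinstance(obj, dict) or not obj.get("docno"):
            raise CorpusFormatError(f"line {lineno}: record missing docno")
        unknown = set(obj) - set(_REC_KEYS)
        if unknown:
            raise CorpusFormatError(f"line {lineno}: unknown keys {sorted(unknown)}")
        try:
            yield DatasetRecord(
                docno=obj["docno"],
                title=obj.get("title", ""),
                repository=obj.get("repository", ""),
                text=obj.get("text", ""),
                metadata=obj.get("metadata", ""),
            )
        except CorpusFormatError as exc:
            raise CorpusFormatError(f"line {lineno}: {exc}") from exc


_TAG_RE = re.compile(r"<(DOCNO|TITLE|REPOSITORY|TEXT|METADATA)>(.*?)</\1>", re.S)


def _read_trec(handle: IO[str]) -> Iterator[DatasetRecord]:
    buf: list[str] = []
    in_doc = False
    rec_index = 0
    for line in handle:
        if "<DOC>" in line:
            in_doc = True
            buf = []
            continue
        if "</DOC>" in line:
            rec_index += 1
            fields = {k.lower(): v.strip() for k, v in _TAG_RE.findall("".join(buf))}
            if not fields.get("docno"):
                raise CorpusFormatError(f"record {rec_index}: missing DOCNO")
            try:
                yield DatasetRecord(
                    docno=fields["docno"],
                    title=fields.get("title", ""),
                    repository=fields.get("repository", ""),
                    text=fields.get("text", ""),
                    metadata=fields.get("metadata", ""),
                )
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"record {rec_index}: {exc}") from exc
            in_doc = False
            continue
        if in_doc:
            buf.append(line)


def write_corpus(records: Iterable[DatasetRecord], path: str | Path,
                 dialect: str = "lines") -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            if dialect == "lines":
                obj = {k: getattr(rec, k) for k in _REC_KEYS}
                out.write(json.dumps(obj, sort_keys=False) + "\n")
            else:
                out.write("<DOC>\n")
                for key in _REC_KEYS:
                    value = getattr(rec, key)
                    if key == "metadata" and not value:
                        continue
                    out.write(f"<{key.upper()}>{value}</{key.upper()}>\n")
                out.write("</DOC>\n")


def augment_metadata(
    records: Iterable[DatasetRecord],
    descriptions: Iterable[RepositoryDescription],
) -> Iterator[DatasetRecord]:
    """Append each repository's About-text to its records' METADATA field.

    Matching is case-insensitive exact match on the repository label.
    Records from repositories without a description pass through
    unchanged (logged, not fatal). No other field is modified. Apply
    once per corpus: re-application would append the text again.
    """
    by_repo = {d.repository.lower(): d.about_text for d in descriptions}
    unmatched: set[str] = set()
    for rec in records:
        about = by_repo.get(rec.repository.lower())
        if about is None:
            if rec.repository not in unmatched:
                unmatched.add(rec.repository)
                logger.info("no repository description for %r", rec.repository)
            yield rec
        else:
            merged = f"{rec.metadata} {about}".strip() if rec.metadata else about
            yield DatasetRecord(rec.docno, rec.title, rec.repository, rec.text, merged)


def read_repository_descriptions(path: str | Path) -> list[RepositoryDescription]:
    """Read repository descriptions from a JSON-lines file
    (keys ``repository`` and ``about_text``)."""
    out = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            try:
                out.append(RepositoryDescription(obj["repository"], obj.get("about_text", "")))
            except (KeyError, CorpusFormatError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    return out


# -- queries --------------------------------------------------------------

def read_queries(path: str | Path) -> list[Query]:
    """Read tab-separated ``qid<TAB>text`` query files."""
    queries = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise CorpusFormatError(f"line {lineno}: expected 'qid<TAB>text'")
            queries.append(Query(parts[0].strip(), parts[1].strip()))
    return queries


def write_queries(queries: Iterable[Query], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for q in queries:
            out.write(f"{q.qid}\t{q.raw_text}\n")


# -- qrels ----------------------------------------------------------------

def read_qrels(path: str | Path) -> QrelsTable:
    """Read TREC qrels: ``qid 0 docno grade`` with grades in 0..2."""
    table = QrelsTable()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CorpusFormatError(f"line {lineno}: expected 'qid 0 docno grade'")
            qid, _, docno, grade_s = parts
            try:
                grade = int(grade_s)
            except ValueError:
                raise CorpusFormatError(f"line {lineno}: non-integer grade {grade_s!r}")
            try:
                table.add(qid, docno, grade)
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    return table


def write_qrels(table: QrelsTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for (qid, docno), grade in sorted(table.entries.items()):
            out.write(f"{qid} 0 {docno} {grade}\n")


# -- run files ------------------------------------------------------------

def write_run(ranked_lists: Iterable, tag: str, path: str | Path) -> None:
    """Write TREC run lines ``qid Q0 docno rank score tag``.

    Ranks are 1-based in list order; scores are printed with 6 decimal
    places for evaluator compatibility.
    """
    with open(path, "w", encoding="utf-8") as out:
        for rl in ranked_lists:
            for rank, (docno, score) in enumerate(rl.items, start=1):
                out.write(f"{rl.qid} Q0 {docno} {rank} {score:.6f} {tag}\n")


def read_run(path: str | Path) -> list:
    """Read a TREC run file back into ranked lists (ordered by rank)."""
    from .retrieval import RankedList  # local import to avoid a cycle

    per_qid: dict[str, list[tuple[int, str, float]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise CorpusFormatError(f"line {lineno}: expected 6 run-file columns")
            qid, _, docno, rank_s, score_s, _tag = parts
            if qid not in per_qid:
                per_qid[qid] = []
                order.append(qid)
            per_qid[qid].append((int(rank_s), docno, float(score_s)))
    lists = []
    for qid in order:
        rows = sorted(per_qid[qid])
        lists.append(RankedList(qid, [(docno, score) for _, docno, score in rows]))
    return lists
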