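"""Parse, merge, filter and write curated protein-protein interaction tables.

Supports three tab-delimited dialects commonly used for physical-interaction
dumps: a BioGRID TAB-style table (official gene symbol columns), a
HIPPIE-style table (symbol columns plus a confidence score in [0, 1]) and a
plain two/three-column edge list. Parsing produces an
:class:`InteractionCorpus` of :class:`InteractionRecord` objects keyed by a
canonical (lexicographically ordered) unordered symbol pair; merging unions
corpora over canonical pairs, accumulating evidence counts and retaining the
maximum confidence seen for a pair.

Gene symbols are upper-cased and whitespace-stripped; no alias resolution is
attempted. Malformed rows are skipped and counted, never fatal.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .exceptions import DialectError

logger = logging.getLogger(__name__)

#: Column layout per named dialect. ``None`` for ``conf`` means the dialect
#: carries no confidence score.
_DIALECTS = {
    "biogrid": {
        "col_a": "official symbol interactor a",
        "col_b": "official symbol interactor b",
        "conf": None,
    },
    "hippie": {
        "col_a": "gene name interactor a",
        "col_b": "gene name interactor b",
        "conf": "confidence value",
    },
}

CANONICAL_HEADER = ("symbol_a", "symbol_b", "evidence_count", "confidence")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in lexicographic order."""
    return (a, b) if a <= b else (b, a)


def _normalize_symbol(raw: str) -> str:
    return raw.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One curated physical interaction with provenance and evidence weight.

    ``evidence_count`` is the number of distinct publications/techniques
    supporting the pair; ``confidence`` is an optional HIPPIE-style score in
    [0, 1].
    """

    protein_a: str
    protein_b: str
    source: str = "custom"
    evidence_count: int = 1
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        a = _normalize_symbol(self.protein_a)
        b = _normalize_symbol(self.protein_b)
        if not a or not b:
            raise ValueError("protein symbols must be non-empty after normalization")
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if self.evidence_count < 0:
            raise ValueError("evidence_count must be >= 0")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical unordered symbol pair."""
        return canonical_pair(self.protein_a, self.protein_b)

    @property
    def is_self_pair(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass
class InteractionCorpus:
    """An ordered collection of interaction records with bookkeeping.

    ``n_skipped`` counts malformed input rows that were dropped during
    parsing (they are reported, never fatal).
    """

    records: list[InteractionRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        """Distinct canonical unordered pairs in the corpus."""
        return {r.pair for r in self.records}

    def symbols(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.add(r.protein_a)
            out.add(r.protein_b)
        return out

    def self_pairs(self) -> set[str]:
        """Symbols with a retained self-interaction (flagged, never dropped)."""
        return {r.protein_a for r in self.records if r.is_self_pair}


def _require_columns(header: list[str], needed: Iterable[str], dialect: str) -> dict[str, int]:
    lowered = [h.strip().lstrip("#").strip().lower() for h in header]
    index = {}
    for col in needed:
        if col not in lowered:
            raise DialectError(f"dialect {dialect!r}: required column {col!r} missing from header")
        index[col] = lowered.index(col)
    return index


def _parse_confidence(raw: str) -> Optional[float]:
    raw = raw.strip()
    if not raw or raw in {"-", "NA", "na", "nan"}:
        return None
    value = float(raw)  # ValueError propagates to the malformed-row handler
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"confidence {value} outside [0, 1]")
    return value


def parse_interactions(path: str | Path, dialect: str) -> InteractionCorpus:
    """Parse a tab-delimited interaction table into a corpus.

    Parameters
    ----------
    path:
        Input file. Must exist and be tab-delimited.
    dialect:
        ``"biogrid"`` (official-symbol columns), ``"hippie"`` (symbol columns
        plus confidence), or ``"tsv2col"`` (two symbol columns with an
        optional third confidence column; an optional header line must start
        with ``#``).

    One record is produced per data row, in row order. Malformed rows (empty
    symbol, out-of-range or unparseable confidence, wrong column count) are
    skipped and counted in ``corpus.n_skipped``.
    """
    path = Path(path)
    if dialect not in (*_DIALECTS, "tsv2col"):
        raise DialectError(f"unknown dialect {dialect!r}")
    corpus = InteractionCorpus()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        if dialect == "tsv2col":
            _parse_tsv2col(reader, corpus)
        else:
            _parse_named_dialect(reader, corpus, dialect)
    if corpus.n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, corpus.n_skipped)
    return corpus


def _parse_named_dialect(reader, corpus: InteractionCorpus, dialect: str) -> None:
    spec = _DIALECTS[dialect]
    try:
        header = next(reader)
    except StopIteration:
        raise DialectError(f"dialect {dialect!r}: file is empty (no header)") from None
    needed = [spec["col_a"], spec["col_b"]] + ([spec["conf"]] if spec["conf"] else [])
    idx = _require_columns(header, needed, dialect)
    for row in reader:
        try:
            a = row[idx[spec["col_a"]]]
            b = row[idx[spec["col_b"]]]
            conf = _parse_confidence(row[idx[spec["conf"]]]) if spec["conf"] else None
            corpus.records.append(
                InteractionRecord(protein_a=a, protein_b=b, source=dialect, confidence=conf)
            )
        except (IndexError, ValueError):
            corpus.n_skipped += 1


def _parse_tsv2col(reader, corpus: InteractionCorpus) -> None:
    for row in reader:
        if row and row[0].startswith("#"):  # optional header line
            continue
        if len(row) not in (2, 3):
            corpus.n_skipped += 1
            continue
        try:
            conf = _parse_confidence(row[2]) if len(row) == 3 else None
            corpus.records.append(
                InteractionRecord(protein_a=row[0], protein_b=row[1], source="custom", confidence=conf)
            )
        except ValueError:
            corpus.n_skipped += 1


def merge_corpora(corpora: list[InteractionCorpus]) -> InteractionCorpus:
    """Union corpora over canonical unordered pairs.

    Per pair, ``evidence_count`` is the total evidence carried by all
    contributing records (each raw parsed record carries count 1, so on raw
    corpora this equals the number of contributing records) and the maximum
    confidence seen is retained. Output records are sorted by canonical pair,
    so merging is deterministic, commutative and associative.
    """
    if not corpora:
        raise ValueError("merge_corpora requires at least one corpus")
    evidence: dict[tuple[str, str], int] = {}
    confidence: dict[tuple[str, str], Optional[float]] = {}
    sources: dict[tuple[str, str], set[str]] = {}
    for corpus in corpora:
        for rec in corpus.records:
            key = rec.pair
            evidence[key] = evidence.get(key, 0) + rec.evidence_count
            prev = confidence.get(key)
            if rec.confidence is not None and (prev is None or rec.confidence > prev):
                confidence[key] = rec.confidence
            else:
                confidence.setdefault(key, prev)
            sources.setdefault(key, set()).add(rec.source)
    merged = InteractionCorpus(n_skipped=sum(c.n_skipped for c in corpora))
    for key in sorted(evidence):
        src = sources[key]
        merged.records.append(
            InteractionRecord(
                protein_a=key[0],
                protein_b=key[1],
                source=next(iter(src)) if len(src) == 1 else "merged",
                evidence_count=evidence[key],
                confidence=confidence[key],
            )
        )
    return merged


def confidence_report(corpus: InteractionCorpus, threshold: float) -> dict:
    """Count records whose confidence falls below ``threshold``.

    Records lacking a confidence score are reported separately and never
    counted as "below". ``fraction_below`` is relative to the scored records.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    scored = [r.confidence for r in corpus.records if r.confidence is not None]
    n_below = sum(1 for c in scored if c < threshold)
    return {
        "n_total": len(corpus.records),
        "n_with_confidence": len(scored),
        "n_missing_confidence": len(corpus.records) - len(scored),
        "n_below": n_below,
        "threshold": threshold,
        "fraction_below": (n_below / len(scored)) if scored else 0.0,
    }


def filter_by_confidence(corpus: InteractionCorpus, min_confidence: float) -> InteractionCorpus:
    """Opt-in confidence filter: keep records without a score or with score >= cutoff."""
    kept = [r for r in corpus.records if r.confidence is None or r.confidence >= min_confidence]
    return InteractionCorpus(records=kept, n_skipped=corpus.n_skipped)


def write_corpus(corpus: InteractionCorpus, path: str | Path) -> None:
    """Write the canonical edge-list TSV (symbol_a, symbol_b, evidence_count, confidence)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_HEADER)
        for rec in corpus.records:
            a, b = rec.pair
            writer.writerow(
                [a, b, rec.evidence_count, "" if rec.confidence is None else repr(rec.confidence)]
            )


def read_corpus(path: str | Path) -> InteractionCorpus:
    """Read back a canonical edge-list TSV written by :func:`write_corpus`."""
    corpus = InteractionCorpus()
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if tuple(h.strip().lower() for h in header) != CANONICAL_HEADER:
            raise DialectError(f"not a canonical edge list: header {header!r}")
        for row in reader:
            try:
                corpus.records.append(
                    InteractionRecord(
                        protein_a=row[0],
                        protein_b=row[1],
                        source="custom",
                        evidence_count=int(row[2]),
                        confidence=_parse_confidence(row[3]) if len(row) > 3 else None,
                    )
                )
            except (IndexError, ValueError):
                corpus.n_skipped += 1
    return corpus


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a summary report (e.g. from confidence_report) as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def parse_gmt(path: str | Path, background: Optional[int] = None):
    """Parse a GMT gene-set file into a :class:`brdnet.enrichment.GeneSetCollection`.

    GMT layout: one set per line — name, description, then member symbols,
    tab-separated. ``background`` sets the declared universe size; when
    omitted it defaults to the number of distinct symbols in the file.
    """
    from .enrichment import GeneSetCollection  # local import avoids a cycle at import time

    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DialectError(f"GMT line has fewer than 3 fields: {line[:80]!r}")
        name = fields[0].strip()
        if name in sets:
            raise DialectError(f"duplicate gene-set name {name!r}")
        members = frozenset(_normalize_symbol(s) for s in fields[2:] if s.strip())
        if not members:
            raise DialectError(f"gene set {name!r} is empty")
        sets[name] = members
        descriptions[name] = fields[1].strip()
    if background is None:
        background = len({m for s in sets.values() for m in s})
    return GeneSetCollection(sets=sets, descriptions=descriptions, background=background)
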