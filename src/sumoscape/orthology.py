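"""Strict ortholog calling from pairwise BLASTP tabular output.

A protein pair is accepted as orthologous when the best HSP between the
two sequences has an e-value below ``evalue_max`` (default 1e-10) and the
aligned span covers more than ``min_coverage`` (default 80%) of the
residues of *both* sequences.  Inequalities are strict by default
("smaller than", "over 80%"); a non-strict variant exists for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .proteome import Proteome

logger = logging.getLogger(__name__)

#: Standard 12-column BLAST tabular layout (-outfmt 6).
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

#: Extended layout carrying full sequence lengths.
BLAST6_EXT_COLUMNS = BLAST6_COLUMNS + ["qlen", "slen"]


class BlastParseError(ValueError):
    """Raised for malformed homology-search tabular input."""


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP row of pairwise homology search output (1-based inclusive)."""

    query_id: str
    subject_id: str
    evalue: float
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int
    identity_pct: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise BlastParseError(
                f"{self.query_id}/{self.subject_id}: bad query coordinates "
                f"{self.qstart}..{self.qend} (qlen {self.qlen})"
            )
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise BlastParseError(
                f"{self.query_id}/{self.subject_id}: bad subject coordinates "
                f"{self.sstart}..{self.send} (slen {self.slen})"
            )
        if self.evalue < 0:
            raise BlastParseError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class OrthologyCriteria:
    """Acceptance thresholds for the strict ortholog definition."""

    evalue_max: float = 1e-10
    min_coverage: float = 0.80
    strict: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")

    def accepts(self, evalue: float, coverage_q: float, coverage_s: float) -> bool:
        if self.strict:
            return (
                evalue < self.evalue_max
                and coverage_q > self.min_coverage
                and coverage_s > self.min_coverage
            )
        return (
            evalue <= self.evalue_max
            and coverage_q >= self.min_coverage
            and coverage_s >= self.min_coverage
        )


@dataclass(frozen=True)
class OrthologPair:
    query_id: str
    subject_id: str
    best_evalue: float
    coverage_q: float
    coverage_s: float


@dataclass
class OrthologMap:
    """Accepted ortholog pairs between a query and a subject species."""

    query_species: str
    subject_species: str
    pairs: list[OrthologPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.by_query: dict[str, list[OrthologPair]] = defaultdict(list)
        self.by_subject: dict[str, list[OrthologPair]] = defaultdict(list)
        seen: set[tuple[str, str]] = set()
        for pair in self.pairs:
            key = (pair.query_id, pair.subject_id)
            if key in seen:
                raise ValueError(f"duplicate ortholog pair {key}")
            seen.add(key)
            self.by_query[pair.query_id].append(pair)
            self.by_subject[pair.subject_id].append(pair)

    def __len__(self) -> int:
        return len(self.pairs)

    def subject_ids(self) -> set[str]:
        return set(self.by_subject)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                (p.query_id, p.subject_id, p.best_evalue, p.coverage_q, p.coverage_s)
                for p in self.pairs
            ],
            columns=["query_id", "subject_id", "evalue", "coverage_q", "coverage_s"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, query_species: str, subject_species: str
    ) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t")
        pairs = [
            OrthologPair(
                str(r.query_id), str(r.subject_id),
                float(r.evalue), float(r.coverage_q), float(r.coverage_s),
            )
            for r in df.itertuples()
        ]
        return cls(query_species, subject_species, pairs)


def parse_blast_tabular(
    path: str | Path,
    columns: Sequence[str] | None = None,
    query_proteome: Proteome | None = None,
    subject_proteome: Proteome | None = None,
) -> list[AlignmentHit]:
    """Parse BLAST tabular output into :class:`AlignmentHit` rows.

    ``columns`` names the tab-separated columns (default: the 12-column
    outfmt-6 dialect).  When ``qlen``/``slen`` are not among the columns
    they are filled from the supplied proteomes; with neither available a
    hard error is raised.  Rows whose identifiers are absent from supplied
    proteomes are rejected with a logged count.
    """
    path = Path(path)
    columns = list(columns) if columns is not None else list(BLAST6_COLUMNS)
    required = {"qseqid", "sseqid", "qstart", "qend", "sstart", "send", "evalue"}
    missing = required - set(columns)
    if missing:
        raise BlastParseError(f"dialect lacks required columns: {sorted(missing)}")
    has_lengths = "qlen" in columns and "slen" in columns
    if not has_lengths and (query_proteome is None or subject_proteome is None):
        raise BlastParseError(
            "dialect lacks qlen/slen and no proteomes supplied for length lookup"
        )

    try:
        df = pd.read_csv(
            path, sep="\t", names=columns, header=None, comment="#", dtype=str
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(columns):
        raise BlastParseError(
            f"{path}: expected {len(columns)} columns, found {df.shape[1]}"
        )

    hits: list[AlignmentHit] = []
    rejected = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(columns, row))
        qid, sid = rec["qseqid"], rec["sseqid"]
        if query_proteome is not None and qid not in query_proteome:
            rejected += 1
            continue
        if subject_proteome is not None and sid not in subject_proteome:
            rejected += 1
            continue
        try:
            qlen = int(rec["qlen"]) if has_lengths else query_proteome[qid].length
            slen = int(rec["slen"]) if has_lengths else subject_proteome[sid].length
            hit = AlignmentHit(
                query_id=qid,
                subject_id=sid,
                evalue=float(rec["evalue"]),
                qstart=int(rec["qstart"]),
                qend=int(rec["qend"]),
                sstart=int(rec["sstart"]),
                send=int(rec["send"]),
                qlen=qlen,
                slen=slen,
                identity_pct=float(rec.get("pident", 0.0) or 0.0),
            )
        except (ValueError, BlastParseError) as exc:
            raise BlastParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
        hits.append(hit)
    if rejected:
        logger.warning("%s: rejected %d rows with identifiers absent from proteomes",
                       path, rejected)
    return hits


def coverage(hit: AlignmentHit) -> tuple[float, float]:
    """Fraction of each sequence's residues spanned by the aligned region.

    Span coverage ``(end - start + 1) / length`` per sequence; gap columns
    are not subtracted (the measure computable from the tabular dialect).
    """
    cov_q = (hit.qend - hit.qstart + 1) / hit.qlen
    cov_s = (hit.send - hit.sstart + 1) / hit.slen
    return cov_q, cov_s


def best_hits(hits: Iterable[AlignmentHit]) -> dict[tuple[str, str], AlignmentHit]:
    """Single best HSP per (query, subject) pair.

    Lowest e-value wins; ties broken by larger summed coverage, then by
    first encountered.  No HSP chaining across the pair.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = hit
            continue
        if hit.evalue < incumbent.evalue:
            best[key] = hit
        elif hit.evalue == incumbent.evalue:
            if sum(coverage(hit)) > sum(coverage(incumbent)):
                best[key] = hit
    return best


def call_orthologs(
    hits: Iterable[AlignmentHit],
    criteria: OrthologyCriteria = OrthologyCriteria(),
    query_species: str = "query",
    subject_species: str = "subject",
) -> OrthologMap:
    """Apply the strict ortholog criterion to the best HSP of each pair."""
    hits = list(hits)
    if not hits:
        logger.info("call_orthologs: empty hit collection, returning empty map")
    pairs: list[OrthologPair] = []
    for (qid, sid), hit in best_hits(hits).items():
        cov_q, cov_s = coverage(hit)
        if criteria.accepts(hit.evalue, cov_q, cov_s):
            pairs.append(OrthologPair(qid, sid, hit.evalue, cov_q, cov_s))
    return OrthologMap(query_species, subject_species, pairs)


def count_conserved(ids: Iterable[str], ortholog_map: OrthologMap) -> int:
    """Number of query identifiers with at least one accepted ortholog."""
    return sum(1 for protein_id in set(ids) if ortholog_map.by_query.get(protein_id))
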