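"""Cross-species SUMOylation prediction by strict-orthology transfer.

A query protein is ``experimental`` when it appears in the query
species' own evidence set, ``predicted`` when any accepted ortholog pair
lands on an experimentally known target of a donor species, and ``none``
otherwise.  Provenance records every supporting (donor species, donor
target, e-value, coverage) tuple across all donors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .orthology import OrthologMap
from .proteome import Proteome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceSet:
    """Experimentally determined SUMO-target identifiers for one species."""

    species: str
    target_ids: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if any(not t for t in self.target_ids):
            raise ValueError("empty identifier in evidence set")

    @classmethod
    def from_file(cls, path: str | Path, species: str, source: str = "") -> "EvidenceSet":
        """Read one identifier per line, or a TSV with a protein_id column."""
        text = Path(path).read_text()
        first = text.splitlines()[0] if text.strip() else ""
        if "\t" in first:
            df = pd.read_csv(path, sep="\t")
            col = "protein_id" if "protein_id" in df.columns else df.columns[0]
            ids = {str(v) for v in df[col] if str(v).strip()}
        else:
            ids = {
                line.strip()
                for line in text.splitlines()
                if line.strip() and not line.startswith("#")
            }
        return cls(species=species, target_ids=frozenset(ids), source=source or str(path))


@dataclass(frozen=True)
class Provenance:
    donor_species: str
    donor_id: str
    evalue: float
    coverage_q: float
    coverage_s: float


@dataclass
class PredictionRecord:
    protein_id: str
    species: str
    status: str  # experimental | predicted | none
    provenance: list[Provenance] = field(default_factory=list)


@dataclass
class PredictionSummary:
    species: str
    proteome_size: int
    experimental: int
    predicted: int

    @property
    def total_sumoylatable(self) -> int:
        return self.experimental + self.predicted

    @property
    def proteome_fraction(self) -> float:
        return self.total_sumoylatable / self.proteome_size


def predict(
    query: Proteome,
    own_evidence: EvidenceSet | None,
    donors: Sequence[tuple[EvidenceSet, OrthologMap]],
) -> list[PredictionRecord]:
    """Assign experimental/predicted/none status to every query protein.

    Own-species experimental evidence takes precedence over transfer.
    Donor evidence identifiers absent from the corresponding ortholog
    map's subject universe are ignored with a logged warning (published
    lists and proteomes drift).
    """
    own_ids = own_evidence.target_ids if own_evidence is not None else frozenset()

    for evidence, ortho_map in donors:
        missing = evidence.target_ids - ortho_map.subject_ids()
        if missing:
            logger.warning(
                "%d donor target ids from %s absent from the ortholog map subject universe",
                len(missing), evidence.species,
            )

    records: list[PredictionRecord] = []
    for rec in query:
        if rec.id in own_ids:
            records.append(PredictionRecord(rec.id, query.species, "experimental"))
            continue
        provenance: list[Provenance] = []
        for evidence, ortho_map in donors:
            for pair in ortho_map.by_query.get(rec.id, ()):
                if pair.subject_id in evidence.target_ids:
                    provenance.append(
                        Provenance(
                            donor_species=evidence.species,
                            donor_id=pair.subject_id,
                            evalue=pair.best_evalue,
                            coverage_q=pair.coverage_q,
                            coverage_s=pair.coverage_s,
                        )
                    )
        status = "predicted" if provenance else "none"
        records.append(PredictionRecord(rec.id, query.species, status, provenance))
    return records


def summarize_prediction(
    records: Sequence[PredictionRecord], proteome: Proteome
) -> PredictionSummary:
    """Count statuses over a record set covering exactly the proteome."""
    record_ids = {r.protein_id for r in records}
    if record_ids != set(proteome.ids()):
        raise ValueError("prediction records do not cover exactly the proteome ids")
    experimental = sum(1 for r in records if r.status == "experimental")
    predicted = sum(1 for r in records if r.status == "predicted")
    return PredictionSummary(
        species=proteome.species,
        proteome_size=proteome.size,
        experimental=experimental,
        predicted=predicted,
    )


# ---------------------------------------------------------------------------
# "sumobase"-style export of known and predicted targets

_TSV_COLUMNS = ["protein_id", "species", "status", "provenance"]


def _provenance_str(provenance: Iterable[Provenance]) -> str:
    return ";".join(
        f"{p.donor_species}:{p.donor_id}:{p.evalue:g}:{p.coverage_q:.6g}:{p.coverage_s:.6g}"
        for p in provenance
    )


def _provenance_parse(text: str) -> list[Provenance]:
    out = []
    for chunk in text.split(";"):
        if not chunk:
            continue
        species, donor_id, evalue, cov_q, cov_s = chunk.split(":")
        out.append(Provenance(species, donor_id, float(evalue), float(cov_q), float(cov_s)))
    return out


def export_sumobase(
    records: Sequence[PredictionRecord], path: str | Path, format: str = "tsv"
) -> None:
    """Write the known/predicted target dump, one row per protein, ordered by id."""
    ordered = sorted(records, key=lambda r: r.protein_id)
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            [
                (r.protein_id, r.species, r.status, _provenance_str(r.provenance))
                for r in ordered
            ],
            columns=_TSV_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = [
            {
                "protein_id": r.protein_id,
                "species": r.species,
                "status": r.status,
                "provenance": [
                    {
                        "donor_species": p.donor_species,
                        "donor_id": p.donor_id,
                        "evalue": p.evalue,
                        "coverage_q": p.coverage_q,
                        "coverage_s": p.coverage_s,
                    }
                    for p in r.provenance
                ],
            }
            for r in ordered
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_sumobase(path: str | Path, format: str = "tsv") -> list[PredictionRecord]:
    """Re-read an exported dump (round-trips with :func:`export_sumobase`)."""
    path = Path(path)
    records: list[PredictionRecord] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for row in df.itertuples(index=False):
            records.append(
                PredictionRecord(
                    protein_id=row.protein_id,
                    species=row.species,
                    status=row.status,
                    provenance=_provenance_parse(row.provenance),
                )
            )
    elif format == "json":
        for obj in json.loads(path.read_text()):
            records.append(
                PredictionRecord(
                    protein_id=obj["protein_id"],
                    species=obj["species"],
                    status=obj["status"],
                    provenance=[Provenance(**p) for p in obj["provenance"]],
                )
            )
    else:
        raise ValueError(f"unknown export format {format!r}")
    return records
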