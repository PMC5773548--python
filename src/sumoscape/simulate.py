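"""Seeded synthetic fixtures with known ground truth.

Three generators emulate the data every other module consumes: a pair of
proteomes with planted ortholog relations and a homology-search hit
table; a replicate protein-group table with planted true SUMO targets
and IMAC contaminants; and a lysine-free proteome with planted consensus
motifs.  E-values are synthesised by a documented monotone map from
percent identity (100% -> 1e-180 down to 35% -> 1e-8) rather than by
running an aligner, so tests never depend on an external binary.  A
fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .motifs import MotifPattern
from .orthology import AlignmentHit
from .proteome import Proteome, ProteinRecord, write_fasta
from .target_calling import (
    ProteinGroupTable,
    RunObservation,
    RunSpec,
    write_design,
    write_protein_groups,
)

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_RESIDUES_NO_K = np.array([r for r in _RESIDUES if r != "K"])


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults emulate a three-condition, three-replicate purification
    design with wild-type controls, moderately diverged orthologs and a
    donor target list covering a fifth of the donor proteome.
    """

    seed: int = 0
    n_proteins: int = 200
    length_min: int = 80
    length_max: int = 400
    divergence: float = 0.1
    fraction_conserved: float = 0.5
    fraction_targets: float = 0.2
    motif_plant_rate: float = 0.4
    dropout: float = 0.0
    contaminant_count: int = 10
    control_leak_ratio: float = 100.0
    n_fdr_decoys: int = 5

    def __post_init__(self) -> None:
        for name in ("divergence", "fraction_conserved", "fraction_targets",
                     "motif_plant_rate", "dropout"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.divergence >= 1:
            raise ValueError("divergence must be < 1")
        if self.length_min > self.length_max or self.length_min < 10:
            raise ValueError("need 10 <= length_min <= length_max")


@dataclass
class SyntheticTruth:
    """Planted ground truth, serialised alongside the fixtures."""

    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    donor_target_ids: list[str] = field(default_factory=list)
    conserved_target_queries: list[str] = field(default_factory=list)
    motif_positions: dict[str, list] = field(default_factory=dict)
    ms_true_targets: list[str] = field(default_factory=list)
    ms_contaminants: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


def _random_sequence(rng: np.random.Generator, length: int,
                     alphabet: np.ndarray = _RESIDUES) -> str:
    return "".join(rng.choice(alphabet, size=length))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Per-site substitution to a different residue with the given probability."""
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < divergence:
            options = [r for r in _RESIDUES if r != chars[i]]
            chars[i] = options[rng.integers(len(options))]
    return "".join(chars)


def _identity_pct(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def evalue_from_identity(identity_pct: float) -> float:
    """Monotone map from percent identity to a synthetic e-value.

    Log-linear between 100% -> 1e-180 and 35% -> 1e-8; clamped outside.
    """
    identity_pct = min(100.0, max(35.0, identity_pct))
    log10_e = -180.0 + (100.0 - identity_pct) * (180.0 - 8.0) / (100.0 - 35.0)
    return 10.0 ** log10_e


def simulate_species_pair(
    params: SimulationParams,
    query_species: str = "query_sp",
    donor_species: str = "donor_sp",
) -> tuple[Proteome, Proteome, list[AlignmentHit], SyntheticTruth]:
    """Query/donor proteomes with planted orthologs and a synthetic hit table.

    Conserved query proteins are divergence-mutated copies of distinct
    donor proteins (full-length alignment rows whose e-value falls with
    identity); background spurious rows carry e-values >= 1e-5 and
    partial coverage, so they never survive the strict criterion.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins

    donor_records = []
    for i in range(n):
        length = int(rng.integers(params.length_min, params.length_max + 1))
        donor_records.append(
            ProteinRecord(f"d{i:04d}", donor_species, _random_sequence(rng, length))
        )
    donor = Proteome(donor_species, donor_records)

    n_conserved = round(params.fraction_conserved * n)
    conserved_idx = rng.choice(n, size=n_conserved, replace=False)
    partner = {int(q): int(d) for q, d in
               zip(conserved_idx, rng.permutation(n)[:n_conserved])}

    query_records = []
    truth = SyntheticTruth()
    hits: list[AlignmentHit] = []
    for i in range(n):
        qid = f"q{i:04d}"
        if i in partner:
            src = donor_records[partner[i]]
            seq = _mutate(rng, src.sequence, params.divergence)
            query_records.append(ProteinRecord(qid, query_species, seq))
            truth.ortholog_pairs.append((qid, src.id))
            ident = _identity_pct(seq, src.sequence)
            hits.append(
                AlignmentHit(
                    query_id=qid, subject_id=src.id,
                    evalue=evalue_from_identity(ident),
                    qstart=1, qend=len(seq), sstart=1, send=src.length,
                    qlen=len(seq), slen=src.length, identity_pct=ident,
                )
            )
        else:
            length = int(rng.integers(params.length_min, params.length_max + 1))
            query_records.append(
                ProteinRecord(qid, query_species, _random_sequence(rng, length))
            )
    query = Proteome(query_species, query_records)

    # spurious background rows: weak e-value, partial span
    n_spurious = n // 2
    for _ in range(n_spurious):
        q = query_records[int(rng.integers(n))]
        d = donor_records[int(rng.integers(n))]
        span_q = max(10, int(0.4 * q.length))
        span_s = max(10, int(0.4 * d.length))
        hits.append(
            AlignmentHit(
                query_id=q.id, subject_id=d.id,
                evalue=float(10.0 ** rng.uniform(-5, 1)),
                qstart=1, qend=span_q, sstart=1, send=span_s,
                qlen=q.length, slen=d.length,
                identity_pct=float(rng.uniform(15, 30)),
            )
        )

    n_targets = round(params.fraction_targets * n)
    target_idx = set(int(i) for i in rng.choice(n, size=n_targets, replace=False))
    truth.donor_target_ids = sorted(f"d{i:04d}" for i in target_idx)
    target_set = set(truth.donor_target_ids)
    truth.conserved_target_queries = sorted(
        q for q, d in truth.ortholog_pairs if d in target_set
    )
    return query, donor, hits, truth


def write_species_pair(params: SimulationParams, outdir: str | Path) -> dict[str, Path]:
    """Emit the species-pair fixture as FASTA/TSV/text/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    query, donor, hits, truth = simulate_species_pair(params)
    paths = {
        "query_fasta": outdir / "query.fasta",
        "donor_fasta": outdir / "donor.fasta",
        "hits_tsv": outdir / "hits.tsv",
        "donor_targets": outdir / "donor_targets.txt",
        "truth": outdir / "truth.json",
    }
    write_fasta(query, paths["query_fasta"])
    write_fasta(donor, paths["donor_fasta"])
    with open(paths["hits_tsv"], "w") as fh:
        for h in hits:
            aln_len = h.qend - h.qstart + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t{aln_len}"
                f"\t0\t0\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}"
                f"\t{h.evalue:.3g}\t0\t{h.qlen}\t{h.slen}\n"
            )
    paths["donor_targets"].write_text(
        "".join(f"{t}\n" for t in truth.donor_target_ids)
    )
    truth.to_json(paths["truth"])
    return paths


def default_run_design() -> list[RunSpec]:
    """Three stress conditions x three replicates, plus six wild-type controls.

    Each tagged purification is an independent experiment group; control
    purifications come from untreated and heat-shocked wild-type worms.
    """
    runs = []
    for cond in ("steady_state", "heat_shock", "uv"):
        for rep in range(1, 4):
            run_id = f"{cond}_r{rep}"
            runs.append(RunSpec(run_id, cond, experiment=run_id))
    for cond in ("control_N2", "control_N2_hs"):
        for rep in range(1, 4):
            run_id = f"{cond}_r{rep}"
            runs.append(RunSpec(run_id, cond, experiment=run_id, is_control=True))
    return runs


def simulate_protein_groups(
    params: SimulationParams,
) -> tuple[ProteinGroupTable, SyntheticTruth]:
    """Replicate protein-group table with planted targets and contaminants.

    True targets appear across the tagged runs (per-run dropout applied)
    with >= 2 peptides and intensities far above any control leak; a
    quarter of them leak into controls at 1/``control_leak_ratio`` of
    their typical intensity.  Contaminants bind the affinity column
    non-specifically and appear in control runs at full intensity, so
    the control rule excludes them.  FDR decoys carry an FDR above the
    1% threshold.
    """
    rng = np.random.default_rng(params.seed + 1)
    runs = default_run_design()
    sample_runs = [r for r in runs if not r.is_control]
    control_runs = [r for r in runs if r.is_control]

    n_true = round(params.fraction_targets * params.n_proteins)
    truth = SyntheticTruth(
        ms_true_targets=[f"t{i:04d}" for i in range(n_true)],
        ms_contaminants=[f"c{i:04d}" for i in range(params.contaminant_count)],
    )

    observations: dict[str, list[RunObservation]] = {}
    fdr: dict[str, float] = {}

    for k, protein_id in enumerate(truth.ms_true_targets):
        base = float(10.0 ** rng.uniform(6.5, 8.0))
        leaks = k % 4 == 0  # a quarter of true targets leak into controls
        obs = []
        detected_any = 0
        for run in sample_runs:
            if rng.random() < params.dropout:
                obs.append(RunObservation(run))
                continue
            detected_any += 1
            obs.append(
                RunObservation(
                    run,
                    raw_intensity=base * float(rng.uniform(0.8, 1.25)),
                    peptide_count=int(rng.integers(2, 9)),
                )
            )
        # dropout never erases a planted target entirely: keep >= min support
        if detected_any < 3:
            obs = []
            for run in sample_runs:
                obs.append(
                    RunObservation(
                        run,
                        raw_intensity=base * float(rng.uniform(0.8, 1.25)),
                        peptide_count=int(rng.integers(2, 9)),
                    )
                )
        for run in control_runs:
            if leaks:
                obs.append(
                    RunObservation(
                        run,
                        raw_intensity=base / params.control_leak_ratio,
                        peptide_count=1,
                    )
                )
            else:
                obs.append(RunObservation(run))
        observations[protein_id] = obs
        fdr[protein_id] = float(rng.uniform(0.0, 0.009))

    for protein_id in truth.ms_contaminants:
        base = float(10.0 ** rng.uniform(6.5, 8.0))
        obs = []
        for run in sample_runs + control_runs:
            obs.append(
                RunObservation(
                    run,
                    raw_intensity=base * float(rng.uniform(0.8, 1.25)),
                    peptide_count=int(rng.integers(2, 9)),
                )
            )
        observations[protein_id] = obs
        fdr[protein_id] = float(rng.uniform(0.0, 0.009))

    for i in range(params.n_fdr_decoys):
        protein_id = f"f{i:04d}"
        base = float(10.0 ** rng.uniform(6.5, 8.0))
        obs = [
            RunObservation(run, raw_intensity=base, peptide_count=2)
            for run in sample_runs
        ] + [RunObservation(run) for run in control_runs]
        observations[protein_id] = obs
        fdr[protein_id] = float(rng.uniform(0.02, 0.2))

    table = ProteinGroupTable(runs=runs, observations=observations, fdr=fdr)
    return table, truth


def write_ms_fixture(params: SimulationParams, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_protein_groups(params)
    paths = {
        "table": outdir / "protein_groups.tsv",
        "design": outdir / "design.yaml",
        "truth": outdir / "truth.json",
    }
    write_protein_groups(table, paths["table"])
    write_design(table.runs, paths["design"])
    truth.to_json(paths["truth"])
    return paths


def simulate_kfree_proteome(
    params: SimulationParams, species: str = "motif_sp"
) -> Proteome:
    """Uniform-composition proteome over a lysine-free alphabet.

    Without lysine no consensus pattern can match, so planted motifs are
    the only matches.
    """
    rng = np.random.default_rng(params.seed + 2)
    records = []
    for i in range(params.n_proteins):
        length = int(rng.integers(params.length_min, params.length_max + 1))
        records.append(
            ProteinRecord(f"m{i:04d}", species,
                          _random_sequence(rng, length, _RESIDUES_NO_K))
        )
    return Proteome(species, records)


def _realize_motif(rng: np.random.Generator, motif: MotifPattern) -> str:
    """A concrete shortest string matching the pattern."""
    if motif._window:
        cls, anchor = motif._tokens
        return rng.choice(sorted(cls)) + rng.choice(sorted(anchor))
    return "".join(rng.choice(sorted(tok)) for tok in motif._tokens)


def plant_motifs(
    proteome: Proteome,
    params: SimulationParams,
    motif: MotifPattern | None = None,
) -> tuple[Proteome, SyntheticTruth]:
    """Plant exactly one motif occurrence in a fraction of the sequences.

    The base proteome must use a lysine-free alphabet so that planted
    occurrences are the only matches; positions are recorded 1-based.
    """
    if motif is None:
        motif = MotifPattern("[IV]KE", "[IV]KE")
    rng = np.random.default_rng(params.seed + 3)
    n_plant = round(params.motif_plant_rate * proteome.size)
    chosen = set(int(i) for i in rng.choice(proteome.size, size=n_plant, replace=False))

    truth = SyntheticTruth()
    records = []
    for i, rec in enumerate(proteome):
        if i in chosen:
            realization = _realize_motif(rng, motif)
            pos = int(rng.integers(0, rec.length - len(realization) + 1))
            seq = rec.sequence[:pos] + realization + rec.sequence[pos + len(realization):]
            records.append(ProteinRecord(rec.id, rec.species, seq))
            truth.motif_positions[rec.id] = [motif.name, pos + 1]
        else:
            records.append(rec)
    return Proteome(proteome.species, records), truth
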