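"""SUMO-target calling from replicate affinity-purification MS tables.

A protein group is called a SUMO target when it is (i) detected in at
least ``min_experiments`` independent experiment groups, (ii) supported by
at least ``min_peptides`` peptides, (iii) identified below the FDR
threshold, and (iv) either absent from every wild-type control
purification or present at more than ``control_intensity_ratio`` times
the control raw intensity.  A qualitative condition-versus-condition
comparison lists proteins detected in at least 2 of 3 replicates of one
condition and in none of the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping

import pandas as pd
import yaml


class DesignError(ValueError):
    """Raised for inconsistent run design or table input."""


@dataclass(frozen=True)
class RunSpec:
    """One MS run: condition label, experiment group and control status."""

    run_id: str
    condition: str
    experiment: str
    is_control: bool = False


@dataclass(frozen=True)
class RunObservation:
    """Detection evidence for one protein in one run.

    ``raw_intensity`` of ``None`` (or 0) means the protein was not
    detected in the run.
    """

    run: RunSpec
    raw_intensity: float | None = None
    peptide_count: int = 0

    @property
    def detected(self) -> bool:
        return self.raw_intensity is not None and self.raw_intensity > 0


@dataclass
class ProteinGroupTable:
    """Per-run evidence for every protein group, plus the run design."""

    runs: list[RunSpec]
    observations: dict[str, list[RunObservation]]
    fdr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            raise DesignError("duplicate run_id in design")
        self._runs_by_id = {r.run_id: r for r in self.runs}
        for protein_id, obs in self.observations.items():
            for o in obs:
                if o.run.run_id not in self._runs_by_id:
                    raise DesignError(
                        f"protein {protein_id!r}: unknown run {o.run.run_id!r}"
                    )

    @property
    def control_runs(self) -> list[RunSpec]:
        return [r for r in self.runs if r.is_control]

    @property
    def experiment_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.runs:
            if not r.is_control:
                seen.setdefault(r.experiment)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.runs:
            seen.setdefault(r.condition)
        return list(seen)

    def protein_ids(self) -> list[str]:
        return list(self.observations)


@dataclass(frozen=True)
class CallConfig:
    min_experiments: int = 3
    min_peptides: int = 2
    fdr_max: float = 0.01
    control_intensity_ratio: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_experiments, self.min_peptides) < 1:
            raise ValueError("min_experiments and min_peptides must be >= 1")
        if self.fdr_max <= 0 or self.control_intensity_ratio <= 0:
            raise ValueError("fdr_max and control_intensity_ratio must be positive")


@dataclass(frozen=True)
class DifferentialRule:
    min_present: int = 2
    of_replicates: int = 3
    required_absent: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.required_absent < self.min_present <= self.of_replicates):
            raise ValueError("require 0 <= required_absent < min_present <= of_replicates")

    def scaled_min_present(self, n_replicates: int) -> int:
        # ceil(min_present/of_replicates * n); preserves 2-of-3 at n=3
        return math.ceil(self.min_present / self.of_replicates * n_replicates)


@dataclass
class TargetCall:
    """Verdict for one protein group with the rule trail that produced it."""

    protein_id: str
    called: bool
    rule_trail: dict[str, bool]
    supporting_experiments: int
    max_peptides: int
    control_status: str  # absent_in_controls | exceeds_ratio | fails


def call_targets(
    table: ProteinGroupTable, cfg: CallConfig = CallConfig()
) -> list[TargetCall]:
    """Evaluate the four target-calling rules for every protein group.

    Proteins absent from every run are excluded silently; a table without
    control runs is a hard error because the control rule is undecidable.
    """
    if not table.control_runs:
        raise DesignError("no control runs in design; control rule undecidable")

    calls: list[TargetCall] = []
    for protein_id in sorted(table.observations):
        obs = table.observations[protein_id]
        detecting = [o for o in obs if o.detected]
        if not detecting:
            continue

        fdr_ok = table.fdr.get(protein_id, 0.0) <= cfg.fdr_max

        experiments = {
            o.run.experiment for o in detecting if not o.run.is_control
        }
        experiments_ok = len(experiments) >= cfg.min_experiments

        max_pep = max((o.peptide_count for o in detecting), default=0)
        peptides_ok = max_pep >= cfg.min_peptides

        control_intensities = [
            o.raw_intensity for o in detecting if o.run.is_control
        ]
        sample_intensities = [
            o.raw_intensity for o in detecting if not o.run.is_control
        ]
        if not control_intensities:
            control_status = "absent_in_controls"
            control_ok = True
        elif sample_intensities and (
            median(sample_intensities)
            > cfg.control_intensity_ratio * max(control_intensities)
        ):
            control_status = "exceeds_ratio"
            control_ok = True
        else:
            control_status = "fails"
            control_ok = False

        trail = {
            "min_experiments": experiments_ok,
            "min_peptides": peptides_ok,
            "fdr": fdr_ok,
            "control": control_ok,
        }
        calls.append(
            TargetCall(
                protein_id=protein_id,
                called=all(trail.values()),
                rule_trail=trail,
                supporting_experiments=len(experiments),
                max_peptides=max_pep,
                control_status=control_status,
            )
        )
    return calls


def called_ids(calls: Iterable[TargetCall]) -> set[str]:
    return {c.protein_id for c in calls if c.called}


def differential_presence(
    table: ProteinGroupTable,
    cond_a: str,
    cond_b: str,
    rule: DifferentialRule = DifferentialRule(),
) -> tuple[list[str], list[str]]:
    """Condition-specific protein lists by qualitative presence/absence.

    A protein is ``cond_a``-specific when detected in at least the scaled
    ``min_present`` replicates of ``cond_a`` and in at most
    ``required_absent`` replicates of ``cond_b`` (default: none);
    symmetric for ``cond_b``.  The two lists are disjoint.
    """
    known = set(table.conditions())
    for cond in (cond_a, cond_b):
        if cond not in known:
            raise DesignError(f"unknown condition label {cond!r}")

    n_a = sum(1 for r in table.runs if r.condition == cond_a)
    n_b = sum(1 for r in table.runs if r.condition == cond_b)
    if min(n_a, n_b) < rule.of_replicates:
        raise DesignError(
            f"conditions need >= {rule.of_replicates} replicates "
            f"(got {cond_a}: {n_a}, {cond_b}: {n_b})"
        )
    need_a = rule.scaled_min_present(n_a)
    need_b = rule.scaled_min_present(n_b)

    a_specific: list[str] = []
    b_specific: list[str] = []
    for protein_id in sorted(table.observations):
        obs = table.observations[protein_id]
        in_a = sum(1 for o in obs if o.detected and o.run.condition == cond_a)
        in_b = sum(1 for o in obs if o.detected and o.run.condition == cond_b)
        if in_a >= need_a and in_b <= rule.required_absent:
            a_specific.append(protein_id)
        elif in_b >= need_b and in_a <= rule.required_absent:
            b_specific.append(protein_id)
    return a_specific, b_specific


def merge_condition_calls(
    per_condition: Mapping[str, Iterable[str]]
) -> tuple[list[str], pd.DataFrame]:
    """Union of per-condition called-protein lists with a presence matrix."""
    if not per_condition:
        raise DesignError("at least one condition required")
    conditions = list(per_condition)
    sets = {cond: set(ids) for cond, ids in per_condition.items()}
    union = sorted(set().union(*sets.values()))
    matrix = pd.DataFrame(
        {cond: [pid in sets[cond] for pid in union] for cond in conditions},
        index=union,
    )
    return union, matrix


# ---------------------------------------------------------------------------
# TSV + YAML design I/O


def read_design(path: str | Path) -> list[RunSpec]:
    """Read a run-design sidecar: run_id -> {condition, experiment, control}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise DesignError(f"{path}: design must map run ids to run attributes")
    runs = []
    for run_id, attrs in raw.items():
        runs.append(
            RunSpec(
                run_id=str(run_id),
                condition=str(attrs["condition"]),
                experiment=str(attrs.get("experiment", run_id)),
                is_control=bool(attrs.get("control", False)),
            )
        )
    return runs


def write_design(runs: Iterable[RunSpec], path: str | Path) -> None:
    doc = {
        r.run_id: {
            "condition": r.condition,
            "experiment": r.experiment,
            "control": r.is_control,
        }
        for r in runs
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_protein_groups(
    table_path: str | Path, design_path: str | Path
) -> ProteinGroupTable:
    """Read a protein-group TSV plus its design sidecar.

    Expected columns: ``protein_id``, ``fdr``, then per run
    ``<run_id>_peptides`` and ``<run_id>_intensity``.  An empty intensity
    cell means not detected.
    """
    runs = read_design(design_path)
    df = pd.read_csv(table_path, sep="\t")
    if "protein_id" not in df.columns:
        raise DesignError(f"{table_path}: missing protein_id column")
    observations: dict[str, list[RunObservation]] = {}
    fdr: dict[str, float] = {}
    for row in df.to_dict("records"):
        protein_id = str(row["protein_id"])
        fdr[protein_id] = float(row.get("fdr", 0.0) or 0.0)
        obs = []
        for run in runs:
            intensity = row.get(f"{run.run_id}_intensity")
            peptides = row.get(f"{run.run_id}_peptides", 0)
            if intensity is None or (isinstance(intensity, float) and math.isnan(intensity)):
                intensity = None
            else:
                intensity = float(intensity)
            if isinstance(peptides, float) and math.isnan(peptides):
                peptides = 0
            obs.append(
                RunObservation(
                    run=run,
                    raw_intensity=intensity,
                    peptide_count=int(peptides),
                )
            )
        observations[protein_id] = obs
    return ProteinGroupTable(runs=runs, observations=observations, fdr=fdr)


def write_protein_groups(table: ProteinGroupTable, path: str | Path) -> None:
    rows = []
    for protein_id in table.observations:
        row: dict[str, object] = {
            "protein_id": protein_id,
            "fdr": table.fdr.get(protein_id, 0.0),
        }
        for o in table.observations[protein_id]:
            row[f"{o.run.run_id}_peptides"] = o.peptide_count
            row[f"{o.run.run_id}_intensity"] = (
                "" if o.raw_intensity is None else repr(o.raw_intensity)
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: Iterable[TargetCall]) -> pd.DataFrame:
    """Tabular view of target calls for TSV export."""
    rows = []
    for c in calls:
        row = {
            "protein_id": c.protein_id,
            "called": c.called,
            "supporting_experiments": c.supporting_experiments,
            "max_peptides": c.max_peptides,
            "control_status": c.control_status,
        }
        row.update({f"rule_{k}": v for k, v in c.rule_trail.items()})
        rows.append(row)
    return pd.DataFrame(rows)
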