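import pytest

from sumoscape.target_calling import (
    ProteinGroupTable,
    RunObservation,
    RunSpec,
)


def make_runs(n_experiments=3, n_controls=2):
    """Minimal design: one run per experiment group plus controls."""
    runs = [
        RunSpec(f"exp{i}", condition="steady_state", experiment=f"E{i}")
        for i in range(1, n_experiments + 1)
    ]
    runs += [
        RunSpec(f"ctrl{i}", condition="control_N2", experiment=f"C{i}", is_control=True)
        for i in range(1, n_controls + 1)
    ]
    return runs


def make_table(runs, rows, fdr=None):
    """rows: protein_id -> {run_id: (intensity, peptides)}."""
    observations = {}
    for pid, per_run in rows.items():
        obs = []
        for run in runs:
            intensity, peptides = per_run.get(run.run_id, (None, 0))
            obs.append(RunObservation(run, raw_intensity=intensity,
                                      peptide_count=peptides))
        observations[pid] = obs
    return ProteinGroupTable(runs=runs, observations=observations, fdr=fdr or {})


@pytest.fixture
def basic_runs():
    return make_runs()
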