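import random
from statistics import median

import pytest

from conftest import make_runs, make_table
from sumoscape.target_calling import (
    CallConfig,
    DesignError,
    DifferentialRule,
    RunObservation,
    RunSpec,
    call_targets,
    called_ids,
    differential_presence,
    merge_condition_calls,
    read_protein_groups,
    write_design,
    write_protein_groups,
)


def detected(intensity=1e6, peptides=4):
    return (intensity, peptides)


# --- the four calling rules ----------------------------------------------

def test_three_experiments_absent_in_controls_is_called(basic_runs):
    table = make_table(basic_runs, {
        "p1": {"exp1": detected(), "exp2": detected(), "exp3": detected()},
    })
    [call] = call_targets(table)
    assert call.called
    assert call.control_status == "absent_in_controls"
    assert all(call.rule_trail.values())


def test_two_experiments_fails_support_rule(basic_runs):
    table = make_table(basic_runs, {
        "p1": {"exp1": detected(), "exp2": detected()},
    })
    [call] = call_targets(table)
    assert not call.called
    assert call.rule_trail["min_experiments"] is False


def test_single_peptide_fails_peptide_rule(basic_runs):
    table = make_table(basic_runs, {
        "p1": {f"exp{i}": detected(peptides=1) for i in (1, 2, 3)},
    })
    [call] = call_targets(table)
    assert not call.called
    assert call.rule_trail["min_peptides"] is False


def test_high_fdr_fails_fdr_rule(basic_runs):
    table = make_table(
        basic_runs,
        {"p1": {f"exp{i}": detected() for i in (1, 2, 3)}},
        fdr={"p1": 0.05},
    )
    [call] = call_targets(table)
    assert not call.called
    assert call.rule_trail["fdr"] is False


def test_control_ratio_five_fold_not_called(basic_runs):
    # control at 1e6, sample median 5e6: 5x is below the 10x requirement
    table = make_table(basic_runs, {
        "p1": {
            "exp1": detected(5e6), "exp2": detected(5e6), "exp3": detected(5e6),
            "ctrl1": detected(1e6, 1),
        },
    })
    [call] = call_targets(table)
    assert not call.called
    assert call.control_status == "fails"


def test_control_ratio_twenty_fold_called(basic_runs):
    # control at 1e5, sample median 2e6: 20x exceeds the 10x requirement
    table = make_table(basic_runs, {
        "p1": {
            "exp1": detected(2e6), "exp2": detected(2e6), "exp3": detected(2e6),
            "ctrl1": detected(1e5, 1),
        },
    })
    [call] = call_targets(table)
    assert call.called
    assert call.control_status == "exceeds_ratio"


def test_absent_everywhere_excluded_silently(basic_runs):
    table = make_table(basic_runs, {"p1": {}})
    assert call_targets(table) == []


def test_no_control_runs_is_hard_error():
    runs = [RunSpec("exp1", "steady_state", "E1")]
    table = make_table(runs, {"p1": {"exp1": detected()}})
    with pytest.raises(DesignError, match="control"):
        call_targets(table)


def test_calls_invariant_to_row_order(basic_runs):
    rows = {f"p{i}": {f"exp{j}": detected() for j in (1, 2, 3)} for i in range(5)}
    forward = call_targets(make_table(basic_runs, rows))
    backward = call_targets(make_table(basic_runs, dict(reversed(rows.items()))))
    assert [c.protein_id for c in forward] == [c.protein_id for c in backward]
    assert called_ids(forward) == called_ids(backward)


def test_monotonicity_in_config(basic_runs):
    rows = {
        "p1": {"exp1": detected(2e6), "exp2": detected(2e6), "exp3": detected(2e6),
               "ctrl1": detected(1e5, 1)},
        "p2": {"exp1": detected(), "exp2": detected()},
    }
    table = make_table(basic_runs, rows)
    base = called_ids(call_targets(table))
    # raising the control ratio never adds proteins
    stricter = called_ids(call_targets(table, CallConfig(control_intensity_ratio=50)))
    assert stricter <= base
    # lowering min_experiments never removes proteins
    looser = called_ids(call_targets(table, CallConfig(min_experiments=2)))
    assert base <= looser


# --- differential presence ------------------------------------------------

def diff_runs():
    runs = []
    for cond in ("heat_shock", "steady_state"):
        for rep in (1, 2, 3):
            runs.append(RunSpec(f"{cond}_r{rep}", cond, f"{cond}_r{rep}"))
    runs.append(RunSpec("ctrl1", "control_N2", "C1", is_control=True))
    return runs


@pytest.mark.parametrize(
    "hs_reps,ss_reps,expect_hs,expect_ss",
    [
        (3, 0, True, False),   # 3/3 in heat shock, none in steady state
        (2, 0, True, False),   # 2 of 3 suffices
        (2, 1, False, False),  # "in none" violated
        (2, 2, False, False),  # present in both
        (0, 2, False, True),   # symmetric case
    ],
)
def test_differential_presence_rule(hs_reps, ss_reps, expect_hs, expect_ss):
    runs = diff_runs()
    row = {}
    for rep in range(1, hs_reps + 1):
        row[f"heat_shock_r{rep}"] = detected()
    for rep in range(1, ss_reps + 1):
        row[f"steady_state_r{rep}"] = detected()
    table = make_table(runs, {"p1": row})
    hs, ss = differential_presence(table, "heat_shock", "steady_state")
    assert (["p1"] if expect_hs else []) == hs
    assert (["p1"] if expect_ss else []) == ss


def test_differential_unknown_condition_errors():
    table = make_table(diff_runs(), {"p1": {}})
    with pytest.raises(DesignError, match="unknown condition"):
        differential_presence(table, "heat_shock", "osmotic")


def test_differential_lists_disjoint_random():
    runs = diff_runs()
    rng = random.Random(11)
    rows = {}
    for i in range(50):
        row = {}
        for run in runs:
            if not run.is_control and rng.random() < 0.5:
                row[run.run_id] = detected()
        rows[f"p{i}"] = row
    a, b = differential_presence(make_table(runs, rows), "heat_shock", "steady_state")
    assert not set(a) & set(b)


def test_scaled_threshold_with_extra_replicates():
    # 6 replicates per condition: threshold scales to ceil(2/3*6) = 4
    runs = []
    for cond in ("a_cond", "b_cond"):
        for rep in range(1, 7):
            runs.append(RunSpec(f"{cond}_r{rep}", cond, f"{cond}_r{rep}"))
    runs.append(RunSpec("ctrl1", "control_N2", "C1", is_control=True))
    three = {f"a_cond_r{r}": detected() for r in (1, 2, 3)}
    four = {f"a_cond_r{r}": detected() for r in (1, 2, 3, 4)}
    table = make_table(runs, {"p3": three, "p4": four})
    a, b = differential_presence(table, "a_cond", "b_cond")
    assert a == ["p4"] and b == []


# --- merging --------------------------------------------------------------

def test_merge_condition_calls_union_and_matrix():
    union, matrix = merge_condition_calls({"A": {"p1", "p2"}, "B": {"p2", "p3"}})
    assert union == ["p1", "p2", "p3"]
    assert matrix.loc["p2", "A"] and matrix.loc["p2", "B"]
    assert not matrix.loc["p1", "B"]

    single, _ = merge_condition_calls({"A": {"p1"}})
    assert single == ["p1"]


# --- TSV/YAML round trip --------------------------------------------------

def test_table_io_round_trip(tmp_path, basic_runs):
    table = make_table(
        basic_runs,
        {
            "p1": {"exp1": detected(), "exp2": detected(), "exp3": detected()},
            "p2": {"exp1": detected(5e6), "ctrl1": detected(1e6, 1)},
        },
        fdr={"p1": 0.001, "p2": 0.002},
    )
    tsv = tmp_path / "groups.tsv"
    design = tmp_path / "design.yaml"
    write_protein_groups(table, tsv)
    write_design(table.runs, design)
    back = read_protein_groups(tsv, design)
    assert back.runs == table.runs
    assert called_ids(call_targets(back)) == called_ids(call_targets(table))


# --- independent oracle ---------------------------------------------------

def independent_rule_evaluation(table, cfg):
    """Rule-by-rule reimplementation used only as a comparator."""
    called = set()
    for pid, obs in table.observations.items():
        det = [o for o in obs if o.raw_intensity and o.raw_intensity > 0]
        if not det:
            continue
        if table.fdr.get(pid, 0.0) > cfg.fdr_max:
            continue
        groups = {o.run.experiment for o in det if not o.run.is_control}
        if len(groups) < cfg.min_experiments:
            continue
        if max(o.peptide_count for o in det) < cfg.min_peptides:
            continue
        ctrl = [o.raw_intensity for o in det if o.run.is_control]
        smp = [o.raw_intensity for o in det if not o.run.is_control]
        if ctrl:
            if not smp:
                continue
            if median(smp) <= cfg.control_intensity_ratio * max(ctrl):
                continue
        called.add(pid)
    return called


def test_oracle_equivalence_random_tables():
    rng = random.Random(99)
    runs = make_runs(n_experiments=8, n_controls=4)
    for trial in range(200):
        rows = {}
        for i in range(rng.randint(1, 20)):
            row = {}
            for run in runs:
                if rng.random() < 0.5:
                    row[run.run_id] = (10.0 ** rng.uniform(4, 8),
                                       rng.randint(1, 6))
            rows[f"p{i}"] = row
        fdr = {pid: rng.choice([0.001, 0.005, 0.02]) for pid in rows}
        table = make_table(runs, rows, fdr=fdr)
        cfg = CallConfig(
            min_experiments=rng.randint(2, 5),
            min_peptides=rng.randint(1, 4),
            fdr_max=0.01,
            control_intensity_ratio=rng.choice([2.0, 10.0, 100.0]),
        )
        assert called_ids(call_targets(table, cfg)) == \
            independent_rule_evaluation(table, cfg), f"trial {trial}"
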