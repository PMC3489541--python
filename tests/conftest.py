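import warnings

import pytest

import srmdesign as sd
from srmdesign import fixtures as fx
from srmdesign.digest import Peptide


def assert_solution_valid(solution, grid, targets, config):
    """Capacity and indicator-consistency assertions for any solver path."""
    for i, members in grid.membership.items():
        load = len(solution.selected & members)
        assert load <= config.capacity, f"slot {i} over capacity: {load}"
    for p, y in solution.peptide_uncovered.items():
        cov = sum(1 for tid in grid.per_peptide.get(p, []) if tid in solution.selected)
        if y == 0:
            assert cov >= config.tau, f"peptide {p}: y=0 but coverage {cov}"
        else:
            assert cov < config.tau, f"peptide {p}: y=1 but coverage {cov}"
    for (s, j), z in solution.protein_uncovered.items():
        covered = sum(
            1 for p in targets.proteins[s] if solution.peptide_uncovered[p] == 0
        )
        if z == 0:
            assert covered >= j + 1
        else:
            assert covered < j + 1


def sweep_instances(n_instances=200, max_transitions=12, gradient=20.0):
    """Seeded random scheduling instances spanning tau/rho/capacity grids."""
    taus, rhos, caps = (1, 2, 3), (1, 2), (1, 2, 3)
    for seed in range(1, n_instances + 1):
        n_t = 4 + seed % (max_transitions - 3)
        n_p = 1 + seed % 5
        n_s = 1 + seed % 3
        transitions, targets = fx.synthetic_schedule_instance(
            n_t, n_p, n_s, seed, gradient_length=gradient
        )
        config = sd.ScheduleConfig(
            delta=2.5,
            gradient_length=gradient,
            capacity=caps[seed % 3],
            tau=taus[seed % 3],
            rho=rhos[seed % 2],
        )
        yield seed, transitions, targets, config


@pytest.fixture(scope="session")
def small_proteome():
    return fx.synthetic_proteome(fx.FixtureSpec(seed=11, n_proteins=12))


@pytest.fixture(scope="session")
def trained_predictors(small_proteome):
    spec = fx.FixtureSpec(seed=11, n_proteins=12)
    table = fx.synthetic_rt_table(small_proteome, spec)
    records = sd.dedupe_by_tic(table)
    positives = sd.select_training_positives(records)
    negatives = sd.select_training_negatives(records, small_proteome)
    rt_model = sd.train_rt([(r.sequence, r.retention_time) for r in positives])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pt_model = sd.train_pt(
            [Peptide(sequence=r.sequence) for r in positives], negatives
        )
    return sd.PredictorSet(rt_model=rt_model, pt_model=pt_model)
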