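"""Virtual-twin sets: design counts, seeding, dose contract, summaries."""

import numpy as np
import pytest

import ppqtwin as pt
from ppqtwin.twins import twin_rng


@pytest.fixture(scope="module")
def record():
    return pt.SubjectRecord(
        subject_id="sudan_07", site="sudan", age=24.0, gestational_age=22.0,
        dose_salt_mg_per_kg=17.5, observed_body_weight=58.0, fed_state="fasted",
    )


@pytest.fixture(scope="module")
def short_schedule():
    return (1.0, 4.0, 8.0, 24.0, 48.0, 52.0, 72.0, 168.0)


def test_default_design_yields_100_profiles(record, compound, short_schedule):
    twins = pt.build_twin_set(
        record, compound, pt.TwinDesign(master_seed=3), output_times=short_schedule
    )
    assert len(twins.profiles) == 10 * 10
    assert sorted(set(twins.trial_index)) == list(range(10))
    assert sorted(set(twins.subject_index)) == list(range(10))


def test_degenerate_design_reduces_to_mean_physiology(record, compound, short_schedule):
    twins = pt.build_twin_set(
        record, compound, pt.TwinDesign(n_subjects=1, n_trials=1, master_seed=0),
        output_times=short_schedule, cv_scale=0.0,
    )
    mean = pt.mean_physiology(record.gestational_age, record.age)
    dose = compound.salt_to_base(record.dose_salt_mg_per_kg * mean.body_weight)
    direct = pt.simulate(
        mean, compound, pt.DoseRegimen.once_daily(dose, 3, short_schedule)
    )
    assert np.allclose(twins.profiles[0].concentrations, direct.concentrations,
                       rtol=1e-12)


def test_seeding_contract(record, compound, short_schedule):
    design = pt.TwinDesign(n_subjects=2, n_trials=2, master_seed=42)
    a = pt.build_twin_set(record, compound, design, output_times=short_schedule)
    b = pt.build_twin_set(record, compound, design, output_times=short_schedule)
    assert a.simulated_body_weights == b.simulated_body_weights
    for pa, pb in zip(a.profiles, b.profiles):
        assert np.array_equal(pa.concentrations, pb.concentrations)
    c = pt.build_twin_set(
        record, compound,
        pt.TwinDesign(n_subjects=2, n_trials=2, master_seed=43),
        output_times=short_schedule,
    )
    assert a.simulated_body_weights != c.simulated_body_weights


def test_substreams_are_independent_of_other_patients(record):
    """Per-(patient, trial, subject) streams do not depend on how many other
    patients are in the run."""
    r1 = twin_rng(5, "sudan_07", 3, 4).normal()
    r2 = twin_rng(5, "sudan_07", 3, 4).normal()
    other = twin_rng(5, "thailand_01", 3, 4).normal()
    assert r1 == r2
    assert r1 != other


def test_mg_per_kg_dose_contract(record, compound, short_schedule):
    twins = pt.build_twin_set(
        record, compound, pt.TwinDesign(n_subjects=3, n_trials=2, master_seed=9),
        output_times=short_schedule,
    )
    base_per_kg = compound.salt_to_base(record.dose_salt_mg_per_kg)
    for p, bw in zip(twins.profiles, twins.simulated_body_weights):
        assert p.body_weight == bw
        assert p.dose_total / (3 * bw) == pytest.approx(base_per_kg, rel=1e-9)
    assert twins.gestational_age == record.gestational_age
    assert twins.age == record.age


def test_pinned_body_weight_override(record, compound, short_schedule):
    twins = pt.build_twin_set(
        record, compound, pt.TwinDesign(n_subjects=2, n_trials=1, master_seed=1),
        output_times=short_schedule, pin_body_weight=True,
    )
    assert all(bw == record.observed_body_weight
               for bw in twins.simulated_body_weights)


def test_summary_of_identical_profiles_collapses(record, compound, short_schedule):
    twins = pt.build_twin_set(
        record, compound, pt.TwinDesign(n_subjects=3, n_trials=1, master_seed=0),
        output_times=short_schedule, cv_scale=0.0,
    )
    summary = pt.summarize_twin_set(twins)
    assert np.allclose(summary.center, twins.profiles[0].concentrations)
    assert np.allclose(summary.upper - summary.lower, 0.0, atol=1e-12)


def test_summary_mean_of_constant_profiles():
    times = np.array([1.0, 2.0, 3.0])
    mk = lambda v, sid: pt.ConcentrationProfile(sid, times, np.full(3, v),
                                                dose_total=1.0, body_weight=60.0)
    twins = pt.TwinSet(
        subject_id="x", profiles=(mk(10.0, "a"), mk(30.0, "b")),
        trial_index=(0, 0), subject_index=(0, 1), master_seed=0,
        simulated_body_weights=(60.0, 60.0), gestational_age=20.0, age=25.0,
    )
    summary = pt.summarize_twin_set(twins)
    assert np.allclose(summary.center, 20.0)
    median = pt.summarize_twin_set(twins, statistic="median")
    assert np.allclose(median.center, 20.0)


def test_summary_band_covers_noise_free_profile():
    """With multiplicative lognormal noise the 95% band should cover the
    noise-free (median) profile in essentially all replicates."""
    rng = np.random.default_rng(7)
    times = np.array([1.0, 24.0, 72.0])
    truth = np.array([100.0, 60.0, 20.0])
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        profiles = tuple(
            pt.ConcentrationProfile(f"s{i}", times,
                                    truth * rng.lognormal(0, 0.3, 3),
                                    dose_total=1.0, body_weight=60.0)
            for i in range(50)
        )
        twins = pt.TwinSet(
            subject_id="x", profiles=profiles,
            trial_index=tuple([0] * 50), subject_index=tuple(range(50)),
            master_seed=0, simulated_body_weights=tuple([60.0] * 50),
            gestational_age=20.0, age=25.0,
        )
        s = pt.summarize_twin_set(twins)
        if np.all((s.lower <= truth) & (truth <= s.upper)):
            hits += 1
    assert hits >= 90


def test_mismatched_grids_rejected():
    t1, t2 = np.array([1.0, 2.0]), np.array([1.0, 3.0])
    p1 = pt.ConcentrationProfile("a", t1, np.ones(2), dose_total=1.0, body_weight=60.0)
    p2 = pt.ConcentrationProfile("b", t2, np.ones(2), dose_total=1.0, body_weight=60.0)
    twins = pt.TwinSet(
        subject_id="x", profiles=(p1, p2), trial_index=(0, 0),
        subject_index=(0, 1), master_seed=0, simulated_body_weights=(60.0, 60.0),
        gestational_age=20.0, age=25.0,
    )
    with pytest.raises(ValueError):
        pt.summarize_twin_set(twins)


def test_record_validation():
    with pytest.raises(ValueError):
        pt.SubjectRecord("x", "sudan", 25.0, 22.0, dose_salt_mg_per_kg=30.0)
    with pytest.raises(ValueError):
        pt.SubjectRecord("x", "sudan", 25.0, 11.0, dose_salt_mg_per_kg=17.0)
    with pytest.raises(ValueError):
        pt.SubjectRecord("x", "mars", 25.0, 22.0, dose_salt_mg_per_kg=17.0)
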