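"""Synthetic trial cohort: generation, aggregation, round-tripping."""

import numpy as np
import pytest

from fpcea.cohort import (
    Cohort,
    CohortConfig,
    aggregate_services,
    calibrate_cohort_config,
    generate_cohort,
)
from fpcea.exceptions import ModelError, SchemaError


@pytest.fixture(scope="module")
def config():
    return calibrate_cohort_config()


@pytest.fixture(scope="module")
def cohort(config):
    return generate_cohort(config, seed=1)


class TestGeneration:
    def test_cohort_size_and_retention(self, cohort):
        assert len(cohort) == 1000
        for arm in ("intervention", "control"):
            retained = int(((cohort.arm == arm) & cohort.retained).sum())
            # binomial(500, 0.66): expect about 330
            assert 280 <= retained <= 380

    def test_empty_cohort(self, config):
        import dataclasses

        empty = generate_cohort(dataclasses.replace(config, n_per_arm=0), seed=1)
        assert len(empty) == 0

    def test_full_retention_boundary(self, config):
        import dataclasses

        c = generate_cohort(dataclasses.replace(config, retention=1.0), seed=1)
        assert c.retained.all()

    def test_reproducible_under_seed(self, config):
        a = generate_cohort(config, seed=9)
        b = generate_cohort(config, seed=9)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.abortion_month, b.abortion_month)

    def test_long_acting_states_persist(self, cohort):
        # once an implant/IUD appears it runs to month 12 (no switching configured)
        for code in (3, 4):
            rows = np.flatnonzero((cohort.states == code).any(axis=1))
            for i in rows[:50]:
                j = int(np.argmax(cohort.states[i] == code))
                assert (cohort.states[i, j:] == code).all()

    def test_non_retained_contribute_no_services(self, cohort):
        dropped = ~cohort.retained
        assert (cohort.states[dropped] == 0).all()
        assert (cohort.abortion_month[dropped] == 0).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(SchemaError):
            CohortConfig(retention=1.5)
        with pytest.raises(SchemaError):
            CohortConfig(initiation={"intervention": {"ocp": 0.8, "injectable": 0.5}})
        with pytest.raises(SchemaError):
            CohortConfig(switching={"ocp": {"injectable": 0.7, "implant": 0.5}})


class TestAggregation:
    def test_forced_arithmetic_single_pill_user(self):
        states = np.full((1, 12), 1, dtype=np.int8)  # pill all 12 months
        c = Cohort(np.array(["intervention"], dtype=object), np.array([True]), states, np.array([0]))
        agg = aggregate_services(c)["intervention"]
        assert agg.ocp_cycles == 12_000.0  # 12 cycles scaled to per-1000

    def test_injectable_doses_per_started_quarter(self):
        states = np.zeros((1, 12), dtype=np.int8)
        states[0, :8] = 2  # 8 months of continuous use -> doses at months 1,4,7
        c = Cohort(np.array(["control"], dtype=object), np.array([True]), states, np.array([0]))
        assert aggregate_services(c)["control"].injectable_doses == 3000.0

    def test_all_idle_cohort_aggregates_to_zero(self):
        states = np.zeros((4, 12), dtype=np.int8)
        c = Cohort(
            np.array(["control"] * 4, dtype=object),
            np.array([True] * 4),
            states,
            np.zeros(4, dtype=np.int16),
        )
        assert all(v == 0 for v in aggregate_services(c)["control"].as_dict().values())

    def test_no_retained_participants_is_error(self):
        c = Cohort(
            np.array(["control"], dtype=object),
            np.array([False]),
            np.zeros((1, 12), dtype=np.int8),
            np.zeros(1, dtype=np.int16),
        )
        with pytest.raises(ModelError):
            aggregate_services(c)

    def test_additivity_under_pooling(self, config):
        a = generate_cohort(config, seed=11)
        b = generate_cohort(config, seed=12)
        pooled = aggregate_services(Cohort.concat([a, b]))
        for arm in ("intervention", "control"):
            ra = int(((a.arm == arm) & a.retained).sum())
            rb = int(((b.arm == arm) & b.retained).sum())
            agg_a = aggregate_services(a)[arm].as_dict()
            agg_b = aggregate_services(b)[arm].as_dict()
            for k, v in pooled[arm].as_dict().items():
                weighted = (agg_a[k] * ra + agg_b[k] * rb) / (ra + rb)
                assert v == pytest.approx(weighted, rel=1e-12)

    def test_switching_generates_multiple_episodes(self):
        cfg = CohortConfig(
            n_per_arm=200,
            retention=1.0,
            initiation={"intervention": {"ocp": 1.0}, "control": {"ocp": 1.0}},
            duration_q={"intervention": {"ocp": 0.1}, "control": {"ocp": 0.1}},
            switching={"ocp": {"implant": 1.0}},
            seed=5,
        )
        agg = aggregate_services(generate_cohort(cfg))
        # everyone discontinuing the pill before month 12 switches to an implant
        assert agg["intervention"].implant_insertions > 500


class TestRoundTrip:
    def test_csv_round_trip_preserves_aggregates(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        again = Cohort.from_csv(path)
        before = aggregate_services(cohort)
        after = aggregate_services(again)
        for arm in before:
            assert before[arm].as_dict() == after[arm].as_dict()

    def test_participant_records_view(self, cohort):
        records = cohort.records
        assert len(records) == len(cohort)
        r = records[0]
        assert r.arm in ("intervention", "control")
        assert len(r.states) == 12


class TestCalibration:
    def test_expected_rates_recovered_on_average(self, config):
        # average aggregate over seeds should sit near the targets
        sums = {arm: {} for arm in ("intervention", "control")}
        n = 40
        for s in range(n):
            for arm, mix in aggregate_services(generate_cohort(config, seed=s)).items():
                for k, v in mix.as_dict().items():
                    sums[arm][k] = sums[arm].get(k, 0.0) + v / n
        targets = {
            "intervention": dict(zip(sums["intervention"], (2172, 558, 172, 112, 47))),
            "control": dict(zip(sums["control"], (3308, 325, 75, 63, 69))),
        }
        for arm in sums:
            for k in sums[arm]:
                assert sums[arm][k] == pytest.approx(targets[arm][k], rel=0.06), (arm, k)

    def test_unreachable_target_rejected(self):
        bad = {
            "intervention": {"ocp": 9000.0, "injectable": 558.0, "implant": 172.0, "iud": 112.0, "repeat_abortion": 47.0},
            "control": {"ocp": 3308.0, "injectable": 325.0, "implant": 75.0, "iud": 63.0, "repeat_abortion": 69.0},
        }
        with pytest.raises(ModelError):
            calibrate_cohort_config(targets=bad)
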