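from __future__ import annotations

import math

import numpy as np
import pytest

from profilepoll.polling import (
    InsufficientSupportError,
    JointMass,
    Profile,
    UndefinedProfileError,
    conditional_frequency,
    joint_distribution,
    poll,
    poll_dataset,
)

from conftest import make_dataset, random_dataset
from polling_oracle import oracle_joint, oracle_poll


def jm_from_cells(cells, counts=None, subset=("v0",)):
    counts = counts or {k: 100 for k in cells}
    return JointMass(
        subset=tuple(subset),
        cells=dict(cells),
        counts=counts,
        total_mass=sum(cells.values()),
        n_records=sum(counts.values()),
    )


class TestJointDistribution:
    def test_singleton_cell_mass_is_the_weight(self):
        ds = make_dataset([{"haz": -2.6, "weight": 2.5, "residence": "rural"}])
        jm = joint_distribution(ds, ["residence"])
        assert jm.cells == {(1, ("rural",)): 2.5}
        assert jm.counts[(1, ("rural",))] == 1

    def test_duplicated_record_doubles_mass(self):
        row = {"haz": -2.6, "weight": 2.5, "residence": "rural"}
        jm1 = joint_distribution(make_dataset([row]), ["residence"])
        jm2 = joint_distribution(make_dataset([row, dict(row)]), ["residence"])
        assert jm2.cells[(1, ("rural",))] == 2 * jm1.cells[(1, ("rural",))]

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n_max=100)
        subset = [v.name for v in ds.codebook][:2]
        jm = joint_distribution(ds, subset)
        cells, counts = oracle_joint(ds.df.to_dict("records"), subset)
        assert set(jm.cells) == set(cells)
        for key, mass in cells.items():
            assert jm.cells[key] == pytest.approx(mass, rel=1e-14)
            assert jm.counts[key] == counts[key]

    def test_missing_values_excluded_per_analysis(self):
        ds = make_dataset([
            {"haz": -2.5, "weight": 1.0, "a": "x", "b": "y"},
            {"haz": -2.5, "weight": 1.0, "a": np.nan, "b": "y"},
        ])
        assert joint_distribution(ds, ["a"]).n_records == 1
        assert joint_distribution(ds, ["b"]).n_records == 2

    def test_empty_subset_rejected(self, four_children):
        with pytest.raises(ValueError):
            joint_distribution(four_children, [])

    def test_severe_outcome_coding(self):
        ds = make_dataset([
            {"haz": -3.5, "weight": 1.0, "a": "x"},
            {"haz": -2.5, "weight": 1.0, "a": "x"},
        ])
        jm = joint_distribution(ds, ["a"], outcome="stunted_severe")
        assert jm.cells[(1, ("x",))] == 1.0
        assert jm.cells[(0, ("x",))] == 1.0


class TestConditionalFrequency:
    def test_hand_arithmetic(self):
        jm = jm_from_cells({(1, ("a",)): 3.0, (0, ("a",)): 1.0})
        assert conditional_frequency(jm, 1, ("a",)) == pytest.approx(0.75)

    def test_degenerate_single_outcome(self):
        jm = jm_from_cells({(1, ("a",)): 2.0})
        assert conditional_frequency(jm, 1, ("a",)) == 1.0
        assert conditional_frequency(jm, 0, ("a",)) == 0.0

    def test_normalisation_identity(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, n_max=300)
        jm = joint_distribution(ds, [v.name for v in ds.codebook][:3])
        for c in jm.profiles():
            total = conditional_frequency(jm, 0, c) + conditional_frequency(jm, 1, c)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_absent_profile_signals(self):
        jm = jm_from_cells({(1, ("a",)): 2.0})
        with pytest.raises(UndefinedProfileError):
            conditional_frequency(jm, 1, ("zzz",))

    def test_accepts_profile_object(self):
        jm = jm_from_cells({(1, ("a",)): 2.0})
        assert conditional_frequency(jm, 1, Profile(("v0",), ("a",))) == 1.0


class TestPoll:
    def test_two_profile_hand_case_coverage_rank(self):
        jm = jm_from_cells({(1, ("a",)): 6.0, (1, ("b",)): 2.0})
        r = poll(jm, convention="coverage-rank", min_cell=1)
        assert r.winner.values == ("a",)
        assert r.coverage == pytest.approx(0.75)
        assert r.edge == pytest.approx(3.0)
        assert not r.tied

    def test_symmetric_masses_tie(self):
        jm = jm_from_cells({(1, ("a",)): 4.0, (1, ("b",)): 4.0})
        r = poll(jm, min_cell=1)
        assert r.edge == 1.0
        assert r.tied
        assert r.winner.values == ("a",)  # lexicographic tie-break

    def test_conventions_can_disagree(self):
        # "a" has the larger stunted mass; "b" the higher conditional risk
        cells = {(1, ("a",)): 6.0, (0, ("a",)): 6.0,
                 (1, ("b",)): 4.0, (0, ("b",)): 1.0}
        jm = jm_from_cells(cells)
        assert poll(jm, convention="coverage-rank", min_cell=1).winner.values == ("a",)
        assert poll(jm, convention="conditional-rank", min_cell=1).winner.values == ("b",)

    def test_min_cell_filters_thin_profiles(self):
        jm = JointMass(
            subset=("v0",),
            cells={(1, ("a",)): 5.0, (1, ("b",)): 4.0, (1, ("c",)): 99.0},
            counts={(1, ("a",)): 30, (1, ("b",)): 30, (1, ("c",)): 1},
            total_mass=108.0,
            n_records=61,
        )
        r = poll(jm, min_cell=25)
        assert r.winner.values == ("a",)  # "c" is massive but unsupported
        # coverage denominator still includes every observed profile
        assert r.coverage == pytest.approx(5.0 / 108.0)

    def test_insufficient_support_signals(self):
        jm = jm_from_cells({(1, ("a",)): 5.0}, counts={(1, ("a",)): 50})
        with pytest.raises(InsufficientSupportError):
            poll(jm, min_cell=25)

    def test_global_mass_normalisation_is_irrelevant(self):
        # dividing every cell mass by one shared constant (the complete-case
        # count) changes no reported ratio
        rng = np.random.default_rng(8)
        ds = random_dataset(rng, n_max=500)
        jm = joint_distribution(ds, [v.name for v in ds.codebook][:3])
        scaled = JointMass(
            subset=jm.subset,
            cells={k: m / jm.n_records for k, m in jm.cells.items()},
            counts=jm.counts,
            total_mass=jm.total_mass / jm.n_records,
            n_records=jm.n_records,
        )
        for convention in ("coverage-rank", "conditional-rank"):
            a = poll(jm, convention=convention, min_cell=1)
            b = poll(scaled, convention=convention, min_cell=1)
            assert a.winner == b.winner and a.runner_up == b.runner_up
            assert a.coverage == pytest.approx(b.coverage, rel=1e-12)
            assert a.edge == pytest.approx(b.edge, rel=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("convention", ["coverage-rank", "conditional-rank"])
    def test_matches_bruteforce_enumeration(self, convention):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(12):
            ds = random_dataset(rng, n_max=500)
            subset = [v.name for v in ds.codebook]
            jm = joint_distribution(ds, subset)
            cells, counts = oracle_joint(ds.df.to_dict("records"), subset)
            expected = oracle_poll(cells, counts, convention=convention, min_cell=5)
            if expected is None:
                with pytest.raises(InsufficientSupportError):
                    poll(jm, convention=convention, min_cell=5)
                continue
            r = poll(jm, convention=convention, min_cell=5)
            assert r.winner.values == expected["winner"]
            assert r.runner_up.values == expected["runner_up"]
            assert r.coverage == pytest.approx(expected["coverage"], rel=1e-12)
            assert r.edge == pytest.approx(expected["edge"], rel=1e-12)
            checked += 1
        assert checked >= 5


class TestInvariances:
    def test_record_order_invariance(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(rng, n_max=400)
        subset = [v.name for v in ds.codebook][:3]
        r1 = poll_dataset(ds, subset, min_cell=1)
        shuffled = make_dataset(
            ds.df.sample(frac=1.0, random_state=99).reset_index(drop=True).to_dict("records"),
            codebook=ds.codebook,
        )
        r2 = poll_dataset(shuffled, subset, min_cell=1)
        assert r1.winner == r2.winner and r1.runner_up == r2.runner_up
        assert r1.coverage == pytest.approx(r2.coverage, rel=1e-12)
        assert r1.edge == pytest.approx(r2.edge, rel=1e-12)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(17)
        ds = random_dataset(rng, n_max=400)
        subset = [v.name for v in ds.codebook][:3]
        r1 = poll_dataset(ds, subset, min_cell=1)
        ds.df["weight"] = ds.df["weight"] * 1234.5
        r2 = poll_dataset(ds, subset, min_cell=1)
        assert r1.winner == r2.winner
        assert r1.coverage == pytest.approx(r2.coverage, rel=1e-12)
        assert r1.edge == pytest.approx(r2.edge, rel=1e-12)

    def test_edge_at_least_one_and_coverage_partitions(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            ds = random_dataset(rng, n_max=300)
            subset = [v.name for v in ds.codebook][:2]
            jm = joint_distribution(ds, subset)
            for g in (0, 1):
                masses = [m for (gg, _), m in jm.cells.items() if gg == g]
                if len(masses) >= 2:
                    m_g = sum(masses)
                    assert sum(m / m_g for m in masses) == pytest.approx(1.0, abs=1e-12)
                    r = poll(jm, g=g, min_cell=1)
                    assert r.edge >= 1.0
                    assert r.tied == (r.edge == 1.0)
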