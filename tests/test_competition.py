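"""Interface-competition counts and partner overlap."""

import networkx as nx
import numpy as np
import pytest

from hubcycle import (
    SmoothedMatrix,
    activity_mask,
    competition_profile,
    flag_staggered,
    make_staggered_partners,
    partner_overlap,
    SimulationConfig,
    smooth_matrix,
)


def mask_from(values, genes, times=None):
    values = np.asarray(values, float)
    sm = SmoothedMatrix(
        experiment_id="e",
        genes=genes,
        times=np.arange(values.shape[1], dtype=float) * 10 if times is None else times,
        values=values,
        missing=np.zeros_like(values, dtype=bool),
    )
    return activity_mask(sm)


def star(hub, partners):
    g = nx.Graph()
    for p in partners:
        g.add_edge(hub, p)
    return g


class TestCompetitionProfile:
    def test_excess_arithmetic(self):
        # 3 partners all active with one interface: count 3, excess 2
        mask = mask_from([[1.0], [1.0], [1.0], [1.0]], ["H", "P1", "P2", "P3"])
        prof = competition_profile("H", star("H", ["P1", "P2", "P3"]), mask, 1)
        assert prof.active_partner_count.tolist() == [3]
        assert prof.excess.tolist() == [2]
        assert prof.fraction_time_competitive == 1.0

    def test_disjoint_partners_no_competition(self):
        # partners active at mutually exclusive times: the staggered scenario
        values = [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
        mask = mask_from(values, ["H", "P1", "P2", "P3"])
        prof = competition_profile("H", star("H", ["P1", "P2", "P3"]), mask, 1)
        assert prof.max_simultaneous == 1
        assert not prof.excess.any()

    def test_zero_partner_hub(self):
        mask = mask_from([[1.0, 1.0]], ["H"])
        g = nx.Graph()
        g.add_node("H")
        prof = competition_profile("H", g, mask, 1)
        assert prof.active_partner_count.tolist() == [0, 0]

    def test_counts_match_bruteforce(self, rng):
        partners = [f"P{i}" for i in range(8)]
        values = rng.normal(scale=0.3, size=(9, 12))
        mask = mask_from(values, ["H"] + partners)
        prof = competition_profile("H", star("H", partners), mask, 2)
        for j, t in enumerate(mask.times):
            expected = sum(mask.is_active(p, t) for p in partners)
            assert prof.active_partner_count[j] == expected

    def test_double_counting_identity(self, rng):
        partners = [f"P{i}" for i in range(6)]
        mask = mask_from(rng.normal(scale=0.3, size=(7, 10)), ["H"] + partners)
        prof = competition_profile("H", star("H", partners), mask, 1)
        total = sum(len(mask.active_times(p)) for p in partners)
        assert prof.active_partner_count.sum() == total

    def test_excess_monotone_in_interfaces(self, rng):
        partners = [f"P{i}" for i in range(6)]
        mask = mask_from(rng.normal(scale=0.3, size=(7, 10)), ["H"] + partners)
        g = star("H", partners)
        e1 = competition_profile("H", g, mask, 1).excess
        e2 = competition_profile("H", g, mask, 2).excess
        assert (e2 <= e1).all()


class TestPartnerOverlap:
    def test_identical_vectors(self):
        mask = mask_from([[1.0, -1.0, 1.0]] * 2, ["A", "B"])
        ov = partner_overlap(mask, ["A", "B"])
        assert ov.pair("A", "B") == 1.0

    def test_disjoint_vectors(self):
        mask = mask_from([[1.0, -1.0], [-1.0, 1.0]], ["A", "B"])
        ov = partner_overlap(mask, ["A", "B"])
        assert ov.pair("A", "B") == 0.0

    def test_both_empty_flagged(self):
        mask = mask_from([[-1.0], [-1.0]], ["A", "B"])
        ov = partner_overlap(mask, ["A", "B"])
        assert ov.pair("A", "B") == 0.0
        assert ("A", "B") in ov.both_empty_pairs

    def test_matches_bruteforce_sets(self, rng):
        genes = [f"P{i}" for i in range(5)]
        mask = mask_from(rng.normal(scale=0.3, size=(5, 14)), genes)
        ov = partner_overlap(mask, genes)
        for i, a in enumerate(ov.partners):
            for j, b in enumerate(ov.partners):
                if i == j:
                    continue
                sa, sb = mask.active_times(a), mask.active_times(b)
                expected = len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
                assert ov.jaccard[i, j] == pytest.approx(expected)
        assert np.allclose(ov.jaccard, ov.jaccard.T)

    def test_time_relabelling_invariance(self, rng):
        values = rng.normal(scale=0.3, size=(3, 10))
        perm = rng.permutation(10)
        genes = ["A", "B", "C"]
        j1 = partner_overlap(mask_from(values, genes), genes).jaccard
        j2 = partner_overlap(mask_from(values[:, perm], genes), genes).jaccard
        np.testing.assert_allclose(j1, j2)


class TestStaggered:
    def test_all_zero_overlap_is_staggered(self):
        mask = mask_from([[1.0, -1.0], [-1.0, 1.0]], ["A", "B"])
        assert flag_staggered(partner_overlap(mask, ["A", "B"]))

    def test_full_overlap_not_staggered(self):
        mask = mask_from([[1.0, 1.0]] * 2, ["A", "B"])
        assert not flag_staggered(partner_overlap(mask, ["A", "B"]))

    def test_phase_shifted_trio_staggered(self):
        # three partners with troughs spaced T/3 apart, smoothed as in the
        # pipeline: active-time overlap is low under the default threshold
        m = make_staggered_partners(3, SimulationConfig(seed=1), noise_sd=0.0)
        mask = activity_mask(smooth_matrix(m))
        ov = partner_overlap(mask, m.genes)
        assert ov.staggered_score < 0.5
        assert flag_staggered(ov)

    def test_antiphase_pair_zero_overlap(self):
        # baseline below the display threshold: each partner is visible only
        # around its peak, and antiphase peaks never co-occur
        m = make_staggered_partners(
            2, SimulationConfig(seed=1), amplitude=1.5, baseline=-0.25, noise_sd=0.0
        )
        mask = activity_mask(smooth_matrix(m))
        ov = partner_overlap(mask, m.genes)
        assert ov.pair(*m.genes) == 0.0
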