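"""EdU S-phase gating and sister-pair G2 exclusion."""

import itertools

import numpy as np
import pytest

from cinquant.cellcycle import (
    CellCycleParams,
    count_sister_pairs,
    edu_filter,
    g2_filter,
    segment_mean_edu,
)
from cinquant.segmentation import segment_nuclei
from cinquant.synth import SynthConfig, generate_field


def brute_force_max_pairs(positions, cutoff):
    """Exhaustive maximum-cardinality matching over sub-cutoff edges."""
    n = len(positions)
    edges = [
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if np.linalg.norm(positions[i] - positions[j]) < cutoff
    ]

    def best(remaining_edges, used):
        top = 0
        for k, (i, j) in enumerate(remaining_edges):
            if i in used or j in used:
                continue
            top = max(top, 1 + best(remaining_edges[k + 1:], used | {i, j}))
        return top

    return best(edges, frozenset())


class TestSisterPairs:
    def test_threshold_straddle(self):
        two = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.5]])
        assert count_sister_pairs(two, 0.8) == 1
        two_far = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.9]])
        assert count_sister_pairs(two_far, 0.8) == 0

    def test_wide_spread_has_no_pairs(self, rng):
        pos = rng.uniform(0, 30, size=(46, 3))  # huge volume: all far apart
        from scipy.spatial.distance import pdist

        assume_far = (pdist(pos) > 0.8).all()
        if assume_far:
            assert count_sister_pairs(pos, 0.8) == 0

    def test_nan_coordinates_rejected(self):
        pos = np.array([[0.0, np.nan, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            count_sister_pairs(pos, 0.8)

    def test_greedy_matches_exhaustive_on_random_configs(self):
        # nucleus-scale random point sets; exhaustive matching as oracle
        rng = np.random.default_rng(99)
        mismatches = 0
        for _ in range(200):
            n = int(rng.integers(2, 11))
            pos = rng.uniform(0, 1, size=(n, 3)) * np.array([3.0, 8.0, 8.0])
            greedy = count_sister_pairs(pos, 0.8)
            exact = brute_force_max_pairs(pos, 0.8)
            if greedy != exact:
                mismatches += 1
        assert mismatches == 0

    def test_pair_count_invariances(self, rng):
        pos = rng.uniform(0, 1, size=(12, 3)) * np.array([2.0, 5.0, 5.0])
        base = count_sister_pairs(pos, 0.8)
        assert base <= len(pos) // 2
        # rigid translation
        assert count_sister_pairs(pos + np.array([1.0, -2.0, 3.0]), 0.8) == base
        # rotation about z
        th = 0.7
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        assert count_sister_pairs(pos @ rot.T, 0.8) == base
        # shrinking the cutoff cannot increase the count
        assert count_sister_pairs(pos, 0.5) <= base


class TestG2Filter:
    def _pairs_positions(self, n_pairs, extra_singles=0):
        """n_pairs tight pairs on a coarse grid plus isolated singles."""
        pos = []
        for k in range(n_pairs):
            base = np.array([0.0, 3.0 * (k % 8), 3.0 * (k // 8)])
            pos.append(base)
            pos.append(base + np.array([0.0, 0.0, 0.4]))
        for s in range(extra_singles):
            pos.append(np.array([0.0, 3.0 * (s % 8) + 1.5, 3.0 * (s // 8) + 24.0]))
        return np.array(pos)

    def test_boundary_strict_at_more_than_20_pairs(self):
        params = CellCycleParams()
        assert g2_filter(self._pairs_positions(21), params) is True
        assert g2_filter(self._pairs_positions(20), params) is False

    def test_no_spots_retained(self):
        assert g2_filter(np.empty((0, 3)), CellCycleParams()) is False

    def test_synthetic_g2_nuclei_excluded_g1_retained(self):
        from cinquant.spots import count_centromeres

        params = CellCycleParams()
        outcomes = {True: [], False: []}
        cfg = SynthConfig(
            n_nuclei=2, g2_fraction=0.5, s_phase_fraction=0.0, mn_rate=0.0, seed=0
        )
        for ss in np.random.SeedSequence(17).spawn(6):
            field, truth = generate_field(cfg, rng=np.random.default_rng(ss))
            mask = segment_nuclei(field)
            for nuc in truth.nuclei:
                tm = truth.nucleus_mask == nuc.label
                lab = np.bincount(mask[tm].ravel()).argmax()
                if lab == 0:
                    continue
                res = count_centromeres(field.cenpa, mask == lab, field.spacing)
                pos = np.array([s.position_um for s in res.spots])
                outcomes[nuc.g2].append(g2_filter(pos, params))
        assert np.mean(outcomes[True]) >= 0.9  # true G2 excluded
        assert np.mean(outcomes[False]) <= 0.05  # true G1 kept


class TestEduFilter:
    def test_infinite_thresholds(self, small_field):
        field, _ = small_field
        mask = segment_nuclei(field)
        assert not edu_filter(mask, field.edu, np.inf).any()
        assert edu_filter(mask, field.edu, -np.inf).all()

    def test_empty_segment_raises(self, small_field):
        field, _ = small_field
        mask = segment_nuclei(field)
        with pytest.raises(ValueError):
            segment_mean_edu(mask, field.edu, 999)

    def test_s_phase_nuclei_flagged(self):
        cfg = SynthConfig(
            n_nuclei=3, s_phase_fraction=0.5, g2_fraction=0.0, mn_rate=0.0, seed=4
        )
        means = {True: [], False: []}
        for ss in np.random.SeedSequence(8).spawn(8):
            field, truth = generate_field(cfg, rng=np.random.default_rng(ss))
            mask = segment_nuclei(field)
            for nuc in truth.nuclei:
                tm = truth.nucleus_mask == nuc.label
                lab = np.bincount(mask[tm].ravel()).argmax()
                if lab == 0:
                    continue
                means[nuc.s_phase].append(segment_mean_edu(mask, field.edu, lab))
        thr = 0.5 * (np.mean(means[True]) + np.mean(means[False]))
        flagged = np.asarray(means[True]) > thr
        spared = np.asarray(means[False]) > thr
        assert flagged.mean() >= 0.99
        assert spared.mean() <= 0.01

    def test_filters_commute(self, small_field):
        # EdU flags and G2 flags are computed independently per nucleus, so
        # applying the filters in either order retains the same set
        field, _ = small_field
        mask = segment_nuclei(field)
        from cinquant.spots import count_centromeres

        params = CellCycleParams(edu_threshold=300.0)
        labels = [int(v) for v in np.unique(mask)[1:]]
        edu_flags = {
            lab: segment_mean_edu(mask, field.edu, lab) > params.edu_threshold
            for lab in labels
        }
        g2_flags = {}
        for lab in labels:
            res = count_centromeres(field.cenpa, mask == lab, field.spacing)
            pos = np.array([s.position_um for s in res.spots])
            g2_flags[lab] = g2_filter(pos, params)
        keep_edu_then_g2 = [
            lab for lab in labels if not edu_flags[lab] and not g2_flags[lab]
        ]
        keep_g2_then_edu = [
            lab for lab in labels if not g2_flags[lab] and not edu_flags[lab]
        ]
        assert keep_edu_then_g2 == keep_g2_then_edu
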