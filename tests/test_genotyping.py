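import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelcaller.bands import Band, BandProfile
from gelcaller.config import GenotypeConfig
from gelcaller.genotype import (
    NOVEL,
    BandCluster,
    ClusterModel,
    ModelSchemaError,
    ReferenceSpec,
    align_lanes,
    band_offsets,
    call_genotypes,
    classify_band,
    cluster_bands,
    interlane_correlation,
    load_model,
    save_model,
)


def make_band(pos, lane=0):
    return Band(lane_index=lane, position=int(pos), intensity=100.0, prominence=50.0,
                position_sub=float(pos))


def profile_with_peaks(H, peaks, height=100.0):
    v = np.zeros(H)
    for p in peaks:
        v[max(0, p - 1) : p + 2] += height / 2
        v[p] += height / 2
    return BandProfile(v)


class TestAlignment:
    def test_identical_lanes_zero_shift(self):
        prof = profile_with_peaks(100, [30, 60])
        bands = [make_band(30), make_band(60)]
        als = align_lanes([prof, prof, prof], [bands] * 3, ReferenceSpec(30, 5))
        assert all(a.global_shift == 0 and a.local_shift == 0 for a in als)
        assert all(a.reference_found for a in als)

    def test_shifted_lane_compensated(self):
        p0 = profile_with_peaks(120, [40, 80])
        s = 6
        pj = profile_with_peaks(120, [40 + s, 80 + s])
        bands0 = [make_band(40), make_band(80)]
        bandsj = [make_band(40 + s), make_band(80 + s)]
        als = align_lanes([p0, pj], [bands0, bandsj], ReferenceSpec(40, 8))
        assert als[1].total_shift == -s
        assert als[1].reference_found and abs(als[1].reference_position - (40 + s)) <= 1

    def test_lane_missing_reference_flagged(self):
        p0 = profile_with_peaks(100, [30, 60])
        pj = profile_with_peaks(100, [70])
        als = align_lanes(
            [p0, p0, pj],
            [[make_band(30), make_band(60)], [make_band(30), make_band(60)], [make_band(70)]],
            ReferenceSpec(30, 5),
        )
        assert not als[2].reference_found

    def test_fewer_than_two_reference_lanes_aborts(self):
        pj = profile_with_peaks(100, [70])
        with pytest.raises(RuntimeError, match="reference"):
            align_lanes([pj, pj], [[make_band(70)], [make_band(70)]], ReferenceSpec(20, 3))

    def test_interlane_correlation_examples(self):
        b = profile_with_peaks(50, [20])
        assert interlane_correlation(b, b, 0) > interlane_correlation(b, b, 5)
        zero = BandProfile(np.zeros(50))
        assert interlane_correlation(b, zero, 0) == 0


class TestOffsets:
    def test_reference_band_offset_exactly_zero(self):
        prof = profile_with_peaks(100, [30, 60])
        bands = [make_band(30), make_band(60)]
        als = align_lanes([prof, prof], [bands, bands], ReferenceSpec(30, 5))
        offs = band_offsets([bands, bands], als)
        assert (0, 0.0) in offs and (1, 0.0) in offs

    def test_band_below_reference_positive_offset(self):
        prof = profile_with_peaks(100, [30, 55])
        bands = [make_band(30), make_band(55)]
        als = align_lanes([prof, prof], [bands, bands], ReferenceSpec(30, 5))
        offs = [o for lane, o in band_offsets([bands, bands], als) if lane == 0]
        assert 25.0 in offs

    def test_missing_reference_lane_omitted(self):
        p0 = profile_with_peaks(100, [30, 60])
        pj = profile_with_peaks(100, [75])
        als = align_lanes(
            [p0, p0, pj],
            [[make_band(30)], [make_band(30)], [make_band(75)]],
            ReferenceSpec(30, 5),
        )
        offs = band_offsets([[make_band(30)], [make_band(30)], [make_band(75)]], als)
        assert all(lane != 2 for lane, _ in offs)


def dbscan_oracle(xs, eps, minpts):
    """Classic neighbourhood-expansion DBSCAN, 1-D, written from the definition.

    Returns labels with -1 for noise; clusters numbered in order of first
    core point encountered (matching scikit-learn's documented behaviour).
    """
    n = len(xs)
    labels = [None] * n
    neighbors = [
        [j for j in range(n) if abs(xs[j] - xs[i]) <= eps] for i in range(n)
    ]
    core = [len(nb) >= minpts for nb in neighbors]
    cid = 0
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        labels[i] = cid
        queue = list(neighbors[i])
        while queue:
            j = queue.pop(0)
            if labels[j] == -1:
                labels[j] = cid  # border point reclaimed
            if labels[j] is not None:
                continue
            labels[j] = cid
            if core[j]:
                queue.extend(neighbors[j])
        cid += 1
    return [l if l is not None else -1 for l in labels]


def canon(labels):
    """Relabel clusters by first appearance so labelings compare."""
    mapping, out = {}, []
    for l in labels:
        if l == -1:
            out.append(-1)
            continue
        if l not in mapping:
            mapping[l] = len(mapping)
        out.append(mapping[l])
    return out


class TestClustering:
    def test_two_well_separated_clusters(self):
        offs = [(i, 0.0) for i in range(10)] + [
            (i, 40.0 + (i % 3 - 1)) for i in range(10)
        ]
        model = cluster_bands(offs, n_lanes=10, eps_override=3.0, minpts_override=2)
        assert len(model.clusters) == 2
        ref, other = model.clusters
        assert ref.is_reference and abs(ref.mean) < 1e-9
        assert abs(other.mean - 40.0) < 1.0

    def test_degenerate_cluster_variance_floored(self):
        offs = [(i, 0.0) for i in range(6)] + [(i, 30.0) for i in range(6)]
        model = cluster_bands(offs, n_lanes=6, eps_override=2.0, minpts_override=2)
        assert all(c.variance >= 0.25 for c in model.clusters)

    def test_isolated_offset_is_noise_not_cluster(self):
        offs = [(i, 0.0) for i in range(8)] + [(0, 57.0)]
        model = cluster_bands(offs, n_lanes=8, eps_override=2.0, minpts_override=3)
        assert len(model.clusters) == 1  # just the reference cluster

    def test_no_reference_cluster_is_an_error(self):
        offs = [(i, 25.0) for i in range(8)]
        with pytest.raises(RuntimeError, match="reference"):
            cluster_bands(offs, n_lanes=8, eps_override=2.0, minpts_override=2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_dbscan_matches_neighbourhood_expansion_oracle(self, seed):
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 31))
        xs = rng.uniform(0, 50, size=n)
        eps = float(rng.uniform(0.5, 8.0))
        minpts = int(rng.integers(1, 6))
        got = DBSCAN(eps=eps, min_samples=minpts).fit_predict(xs.reshape(-1, 1)).tolist()
        assert canon(got) == canon(dbscan_oracle(xs.tolist(), eps, minpts))


class TestClassification:
    model = ClusterModel(
        clusters=(
            BandCluster(0, 0.0, 1.0, 10, True),
            BandCluster(1, 20.0, 1.0, 10, False),
            BandCluster(2, 40.0, 4.0, 10, False),
        ),
        epsilon_used=3.0,
        minpts_used=2,
    )

    def test_offset_at_mean_assigned_to_cluster(self):
        assert classify_band(20.0, self.model) == 1

    def test_equidistant_tie_goes_to_smaller_mean(self):
        model = ClusterModel(
            clusters=(
                BandCluster(0, 0.0, 1.0, 5, True),
                BandCluster(1, 10.0, 1.0, 5, False),
            ),
            epsilon_used=2.0,
            minpts_used=2,
        )
        assert classify_band(5.0, model, max_z=math.inf) == 0

    def test_far_offset_is_novel(self):
        assert classify_band(200.0, self.model) == NOVEL

    def test_infinite_gate_restores_nearest_assignment(self):
        assert classify_band(200.0, self.model, max_z=math.inf) == 2

    def test_mixed_variance_matches_density_oracle(self):
        from scipy.stats import norm

        for x in np.linspace(25, 35, 21):
            dens = [
                norm.pdf(x, c.mean, math.sqrt(c.variance)) for c in self.model.clusters
            ]
            expected = int(np.argmax(dens))
            assert classify_band(float(x), self.model, max_z=math.inf) == expected


class TestCalls:
    model = ClusterModel(
        clusters=(
            BandCluster(0, 0.0, 1.0, 10, True),
            BandCluster(1, 25.0, 1.0, 10, False),
            BandCluster(2, 50.0, 1.0, 10, False),
        ),
        epsilon_used=3.0,
        minpts_used=2,
    )

    def test_identical_band_sets_share_group(self):
        offs = [(0, 0.0), (0, 25.0), (1, 0.0), (1, 25.0)]
        calls = call_genotypes(offs, self.model)
        assert calls[0].presence == calls[1].presence == (1, 0)
        assert calls[0].group_id == calls[1].group_id == 0

    def test_reference_only_lane_all_zero(self):
        calls = call_genotypes([(0, 0.0)], self.model)
        assert calls[0].presence == (0, 0)

    def test_missing_lane_emitted_with_flag(self):
        calls = call_genotypes([(0, 0.0)], self.model, missing_lanes=(1,))
        assert calls[1].missing and calls[1].group_id == -1

    def test_group_ids_by_first_appearance(self):
        offs = [(0, 0.0), (0, 50.0), (1, 0.0), (1, 25.0), (2, 0.0), (2, 50.0)]
        calls = call_genotypes(offs, self.model)
        assert [c.group_id for c in calls] == [0, 1, 0]

    def test_lane_relabeling_changes_labels_not_partition(self):
        offs = [(0, 0.0), (0, 25.0), (1, 0.0), (1, 50.0), (2, 0.0), (2, 25.0)]
        pi = {0: 2, 1: 0, 2: 1}  # relabel lanes, same banding content
        perm = [(pi[lane], off) for lane, off in offs]
        calls = call_genotypes(offs, self.model)
        calls_p = call_genotypes(perm, self.model)

        def partition(calls, rename=None):
            part = {}
            for c in calls:
                lane = rename[c.lane_index] if rename else c.lane_index
                part.setdefault(c.presence, set()).add(lane)
            return set(map(frozenset, part.values()))

        inv = {v: k for k, v in pi.items()}
        assert partition(calls) == partition(calls_p, rename=inv)


class TestModelIO:
    def test_roundtrip_preserves_model(self, tmp_path):
        p = tmp_path / "model.json"
        save_model(TestCalls.model, str(p))
        assert load_model(str(p)) == TestCalls.model

    def test_loaded_model_classifies_identically(self, tmp_path):
        p = tmp_path / "model.json"
        save_model(TestCalls.model, str(p))
        loaded = load_model(str(p))
        for x in (0.0, 24.0, 51.5, 400.0):
            assert classify_band(x, loaded) == classify_band(x, TestCalls.model)

    def test_truncated_file_raises_schema_error(self, tmp_path):
        p = tmp_path / "model.json"
        save_model(TestCalls.model, str(p))
        p.write_text(p.read_text()[:40])
        with pytest.raises(ModelSchemaError):
            load_model(str(p))

    def test_wrong_schema_rejected(self, tmp_path):
        p = tmp_path / "other.json"
        p.write_text('{"schema": "something-else", "version": 1}')
        with pytest.raises(ModelSchemaError):
            load_model(str(p))
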