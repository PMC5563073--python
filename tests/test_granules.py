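"""Motility classification, docking detection and association statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import axodyn as ax
from axodyn.granules import DockEvent, GranuleTrack
from tests_oracles import dock_windows_bruteforce


def make_track(t, s, gid=0):
    return GranuleTrack(granule_id=gid, t_s=np.asarray(t, float), s_um=np.asarray(s, float))


class TestClassifyMotility:
    def test_constant_position_is_stationary(self):
        tr = make_track(np.arange(0, 63, 3), np.full(21, 10.0))
        assert ax.classify_motility(tr) == "stationary"

    def test_monotone_advance_is_anterograde(self):
        tr = make_track(np.arange(0, 63, 3), 10 + np.linspace(0, 12, 21))
        assert ax.classify_motility(tr) == "anterograde"

    def test_monotone_retreat_is_retrograde(self):
        tr = make_track(np.arange(0, 63, 3), 30 - np.linspace(0, 8, 21))
        assert ax.classify_motility(tr) == "retrograde"

    def test_reversal_is_bidirectional(self):
        s = np.concatenate([np.linspace(0, 3, 11), np.linspace(3, 0, 10)])
        tr = make_track(np.arange(0, 63, 3), 10 + s)
        assert ax.classify_motility(tr) == "bidirectional"

    def test_short_track_not_classifiable(self):
        tr = make_track([0, 3, 6], [0, 0, 0])
        assert ax.classify_motility(tr) is None

    def test_population_fractions_recover_preset(self):
        """Window classification over a generated population matches the
        preset motility fractions within 3 multinomial SE."""
        table, gt = ax.simulate_tracks(seed=42, n_granules=500)
        fr = ax.motility_fractions(ax.tracks_from_table(table))
        for cls, p in ax.GranuleKineticsPreset().fractions.items():
            se = np.sqrt(p * (1 - p) / 500)
            assert abs(fr[cls] - p) <= 3 * se, (cls, fr[cls], p)


class TestEstimateSpeeds:
    def test_single_run_speed(self):
        tr = make_track([0, 10, 20, 30], [0, 5 / 3, 10 / 3, 5.0])
        est = ax.estimate_speeds([tr])
        assert est.v_antero_um_min == pytest.approx(10.0)
        assert est.n_antero == 1 and est.n_retro == 0

    def test_all_stationary_gives_empty_result(self):
        tr = make_track(np.arange(0, 63, 3), np.full(21, 5.0))
        est = ax.estimate_speeds([tr])
        assert est.v_antero_um_min is None and est.v_retro_um_min is None

    def test_branch_samples_excluded_when_shaft_only(self):
        t = np.arange(0, 33, 3.0)
        s = np.linspace(0, 11, 11)
        tr = GranuleTrack(0, t, s, on_shaft=np.array([True] * 6 + [False] * 5))
        est_shaft = ax.estimate_speeds([tr], shaft_only=True)
        est_all = ax.estimate_speeds([tr], shaft_only=False)
        assert est_shaft.v_antero_um_min == pytest.approx(est_all.v_antero_um_min)
        # with the branch samples removed, only the first 6 frames remain
        assert est_shaft.n_antero == 1

    def test_simulated_speeds_recovered(self):
        table, _ = ax.simulate_tracks(seed=21, n_granules=300)
        est = ax.estimate_speeds(ax.tracks_from_table(table))
        assert est.v_antero_um_min == pytest.approx(10.0, rel=0.05)
        assert est.v_retro_um_min == pytest.approx(11.4, rel=0.05)


class TestGranuleDensity:
    def test_seven_on_seventy_microns(self):
        tracks = [
            make_track(np.arange(0, 63, 3), np.full(21, 30 + 5 * k), gid=k)
            for k in range(7)
        ]
        assert ax.granule_density(tracks, 70.0, shaft_length_um=100.0) == pytest.approx(1.0)

    def test_empty_tracks_zero(self):
        assert ax.granule_density([], 70.0) == 0.0

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            ax.granule_density([], 0.0)


class TestDetectDocks:
    def test_fixed_position_single_dock(self):
        tr = make_track(np.arange(0, 18, 3), np.full(6, 12.0))
        docks = ax.detect_docks(tr)
        assert len(docks) == 1
        assert docks[0].duration_s == pytest.approx(15.0)
        assert docks[0].position_um == pytest.approx(12.0)

    def test_small_oscillation_is_one_dock(self):
        t = np.arange(0, 15, 3.0)
        s = 8.0 + 0.3 * np.array([1, -1, 1, -1, 1])
        docks = ax.detect_docks(make_track(t, s), granule_diameter_um=1.0)
        assert len(docks) == 1
        assert docks[0].duration_s >= 10.0

    def test_steady_run_yields_no_docks(self):
        t = np.arange(0, 120, 3.0)
        s = 10.0 / 60.0 * t  # 10 um/min
        assert ax.detect_docks(make_track(t, s)) == []

    def test_undersampled_track_raises_three_frame_rule(self):
        tr = make_track(np.arange(0, 60, 6.0), np.zeros(10))
        with pytest.raises(ValueError, match="3 frames"):
            ax.detect_docks(tr)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_window_oracle(self, seed):
        """Greedy detection equals brute-force window enumeration on random
        run-and-pause tracks."""
        rng = np.random.default_rng(seed)
        t = np.arange(0, 180, 3.0)
        # piecewise: runs, pauses and dwells of random length
        s = [0.0]
        state = rng.integers(0, 2)
        while len(s) < len(t):
            k = int(rng.integers(2, 8))
            v = rng.choice([-0.5, 0.0, 0.0, 0.5])
            for _ in range(k):
                if len(s) >= len(t):
                    break
                s.append(s[-1] + v + rng.normal(0, 0.05))
        tr = make_track(t, np.array(s))
        got = [(d.start_s, d.end_s) for d in ax.detect_docks(tr)]
        assert got == dock_windows_bruteforce(tr.t_s, tr.s_um)


class TestAssociationStats:
    def _protrusions(self, births, origins):
        return pd.DataFrame(
            {"protrusion_id": range(len(births)), "birth_s": births,
             "origin_s_um": origins}
        )

    def test_every_protrusion_docked(self):
        prot = self._protrusions([100.0, 200.0], [10.0, 20.0])
        docks = [DockEvent(0, 10.0, 85.0, 99.0), DockEvent(1, 20.2, 185.0, 210.0)]
        frac, flags = ax.protrusion_dock_association(docks, prot)
        assert frac == 1.0 and flags.all()

    def test_no_docks_zero(self):
        prot = self._protrusions([100.0], [10.0])
        frac, _ = ax.protrusion_dock_association([], prot)
        assert frac == 0.0

    def test_empty_protrusions_undefined(self):
        frac, _ = ax.protrusion_dock_association([], self._protrusions([], []))
        assert np.isnan(frac)

    def test_monotone_in_window_and_radius(self):
        rng = np.random.default_rng(5)
        prot = self._protrusions(rng.uniform(50, 550, 40), rng.uniform(0, 50, 40))
        docks = [
            DockEvent(i, rng.uniform(0, 50), t0 := rng.uniform(0, 580), t0 + 12)
            for i in range(60)
        ]
        fracs_w = [
            ax.protrusion_dock_association(docks, prot, window_s=w)[0]
            for w in (0.0, 5.0, 10.0, 30.0, 100.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fracs_w, fracs_w[1:]))
        fracs_r = [
            ax.protrusion_dock_association(docks, prot, base_radius_um=r)[0]
            for r in (0.2, 0.5, 1.0, 3.0, 10.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fracs_r, fracs_r[1:]))

    def test_random_sites_extremes(self):
        frac0, _ = ax.random_site_dock_fraction([], (0, 50), (0, 600), 100, seed=0)
        assert frac0 == 0.0
        wall_to_wall = [DockEvent(0, s, 0.0, 600.0) for s in np.arange(0, 51, 1.0)]
        frac1, _ = ax.random_site_dock_fraction(wall_to_wall, (0, 50), (0, 600), 100, seed=0)
        assert frac1 == 1.0

    def test_random_sites_deterministic(self):
        docks = [DockEvent(0, 25.0, 100.0, 130.0)]
        a = ax.random_site_dock_fraction(docks, (0, 50), (0, 600), 300, seed=9)
        b = ax.random_site_dock_fraction(docks, (0, 50), (0, 600), 300, seed=9)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestRandomFollowControl:
    def test_all_docks_coupled_gives_one(self):
        t = np.arange(0, 60, 3.0)
        tracks = [make_track(t, np.full(len(t), 10.0 * (k + 1)), gid=k) for k in range(3)]
        prot = pd.DataFrame(
            {"protrusion_id": range(3), "birth_s": [5.0, 5.0, 5.0],
             "origin_s_um": [10.0, 20.0, 30.0]}
        )
        frac, n_res, _ = ax.random_follow_control(
            tracks, prot, (5, 35), (0, 57), n_sets=15, seed=0
        )
        assert n_res > 0 and frac == 1.0

    def test_no_protrusions_gives_zero(self):
        t = np.arange(0, 60, 3.0)
        tracks = [make_track(t, np.full(len(t), 10.0))]
        prot = pd.DataFrame({"protrusion_id": [], "birth_s": [], "origin_s_um": []})
        frac, n_res, _ = ax.random_follow_control(
            tracks, prot, (5, 15), (0, 57), n_sets=10, seed=1
        )
        assert n_res > 0 and frac == 0.0

    def test_queries_without_granules_skipped(self):
        frac, n_res, n_skip = ax.random_follow_control(
            [], pd.DataFrame({"protrusion_id": [], "birth_s": [], "origin_s_um": []}),
            (0, 50), (0, 600), n_sets=5, seed=2,
        )
        assert n_res == 0 and n_skip == 5 and np.isnan(frac)


@given(st.integers(min_value=0, max_value=10_000))
def test_fractions_always_in_unit_interval(seed):
    """Association fractions stay in [0, 1] for arbitrary random inputs."""
    rng = np.random.default_rng(seed)
    n_d, n_p = rng.integers(0, 8), rng.integers(1, 8)
    docks = [
        DockEvent(i, rng.uniform(0, 50), t0 := rng.uniform(0, 500), t0 + rng.uniform(10, 60))
        for i in range(n_d)
    ]
    prot = pd.DataFrame(
        {"protrusion_id": range(n_p), "birth_s": rng.uniform(0, 600, n_p),
         "origin_s_um": rng.uniform(0, 50, n_p)}
    )
    frac, _ = ax.protrusion_dock_association(docks, prot)
    assert 0.0 <= frac <= 1.0
    rfrac, _ = ax.random_site_dock_fraction(docks, (0, 50), (0, 600), 50, seed=seed)
    assert 0.0 <= rfrac <= 1.0
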