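"""Protrusion classification, dynamics counts, RNA presence, navigation."""

import numpy as np
import pandas as pd
import pytest

import axodyn as ax
from axodyn.branches import ProtrusionEvent


def event(pid=0, birth=0.0, death=None, origin=10.0, lengths=((0.0, 3.0),)):
    t, l = zip(*lengths)
    return ProtrusionEvent(
        protrusion_id=pid, birth_s=birth, death_s=death, origin_s_um=origin,
        length_t_s=np.array(t), length_um=np.array(l),
    )


class TestClassification:
    @pytest.mark.parametrize(
        "length,expected",
        [(3.0, "filopodium"), (12.0, "branch"), (5.0, "branch"), (0.0, "filopodium")],
    )
    def test_filopodium_branch_split(self, length, expected):
        assert ax.classify_protrusion(length) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            ax.classify_protrusion(-1.0)

    @pytest.mark.parametrize(
        "minutes,expected",
        [(10, "short_lived"), (45, "persistent"), (30, "short_lived")],
    )
    def test_lifetime_split(self, minutes, expected):
        assert ax.lifetime_class(minutes * 60.0) == expected

    @pytest.mark.parametrize(
        "length,expected", [(8.0, "short"), (20.0, "long"), (15.0, "short")]
    )
    def test_length_split(self, length, expected):
        assert ax.length_class(length) == expected

    def test_boundaries_exhaustive_and_exclusive(self):
        for x in np.linspace(0, 40, 401):
            assert ax.classify_protrusion(x) in ("filopodium", "branch")
            assert ax.length_class(x) in ("short", "long")


class TestCountDynamics:
    def test_persisting_protrusion_counts_added_only(self):
        ev = [event(birth=90.0, lengths=((90.0, 2.0),))]
        counts = ax.count_dynamics(ev, window_s=600.0, shaft_length_um=50.0)
        assert counts["filopodia_added"] == 1
        assert counts["filopodia_removed"] == 0

    def test_born_and_dying_counts_both(self):
        ev = [event(birth=60.0, death=150.0, lengths=((60.0, 7.0),))]
        counts = ax.count_dynamics(ev, window_s=600.0, shaft_length_um=50.0)
        assert counts["branches_added"] == 1
        assert counts["branches_removed"] == 1

    def test_single_frame_protrusion_counts_as_added_and_removed(self):
        ev = [event(birth=30.0, death=30.0, lengths=((30.0, 1.0),))]
        counts = ax.count_dynamics(ev, window_s=600.0, shaft_length_um=50.0)
        assert counts["filopodia_added"] == counts["filopodia_removed"] == 1

    def test_window_beyond_observation_rejected(self):
        with pytest.raises(ValueError):
            ax.count_dynamics([], window_s=600.0, observation_s=300.0)

    def test_conservation_added_minus_removed(self):
        """added - removed equals the net change in protrusion count."""
        rng = np.random.default_rng(0)
        ev = []
        for i in range(60):
            b = rng.uniform(0, 550)
            d = b + rng.exponential(200)
            ev.append(
                event(pid=i, birth=b, death=d if d < 600 else None,
                      origin=rng.uniform(0, 50), lengths=((b, rng.uniform(1, 20)),))
            )
        counts = ax.count_dynamics(ev, window_s=600.0, shaft_length_um=50.0)
        added = counts["filopodia_added"] + counts["branches_added"]
        removed = counts["filopodia_removed"] + counts["branches_removed"]
        alive_at_end = sum(e.death_s is None for e in ev)
        assert added - removed == alive_at_end

    def test_generator_rates_recovered(self):
        """Mean added counts over replicate axons match the preset rates
        (50 filopodia, 8 branches per 10 min) within 3 SE."""
        fil, br = [], []
        for seed in range(30):
            ds = ax.simulate_branching_axon(seed=300 + seed)
            # classify by eventual maximal length (the events table), not the
            # length profile: protrusions born late in the window have not
            # grown past 5 um yet and would be censored into filopodia
            events = ax.events_from_table(ds.protrusions)
            counts = ax.count_dynamics(events, window_s=600.0, shaft_length_um=100.0)
            fil.append(counts["filopodia_added"])
            br.append(counts["branches_added"])
        for got, target in ((fil, 50.0), (br, 8.0)):
            se = np.std(got, ddof=1) / np.sqrt(len(got))
            assert abs(np.mean(got) - target) <= 3 * se, (np.mean(got), target)


class TestRnaPresence:
    def _tracks(self, rows):
        return pd.DataFrame(rows, columns=["granule_id", "t_s", "s_um", "branch_id", "d_um"])

    def test_granule_parked_at_origin_scores_base(self):
        rows = [(0, t, 10.0, np.nan, np.nan) for t in np.arange(0, 120, 3.0)]
        prot = event(birth=0.0, death=300.0, origin=10.0, lengths=((0.0, 6.0),))
        pres = ax.rna_presence(prot, self._tracks(rows), frame_interval_s=3.0)
        assert pres.base_s == pytest.approx(120.0)
        assert pres.mid_s == 0.0 and pres.tip_s == 0.0

    def test_no_granules_all_zero(self):
        prot = event(birth=0.0, death=300.0)
        pres = ax.rna_presence(prot, self._tracks([]), frame_interval_s=3.0)
        assert pres.total_s == 0.0

    def test_uniform_traversal_splits_evenly(self):
        """A granule moving base-to-tip at constant speed through a branch
        with equal base/mid/tip spans accrues ~equal time per region."""
        length = 9.0
        prot = event(birth=0.0, death=300.0, origin=10.0, lengths=((0.0, length),))
        times = np.arange(0.0, 90.0, 3.0)
        d = np.linspace(0.0, length - 1e-6, len(times))
        rows = [(0, t, 10.0, 0, dd) for t, dd in zip(times, d)]
        pres = ax.rna_presence(
            prot, self._tracks(rows), frame_interval_s=3.0,
            base_radius_um=3.0, tip_fraction=1.0 / 3.0, tip_min_um=1.0,
        )
        assert pres.base_s == pytest.approx(30.0, abs=3.1)
        assert pres.mid_s == pytest.approx(30.0, abs=3.1)
        assert pres.tip_s == pytest.approx(30.0, abs=3.1)


class TestPresenceCorrelations:
    def test_proportional_gives_unit_correlation(self):
        dur = [ax.PresenceDurations(i, base_s=10.0 * i, mid_s=5.0 * i, tip_s=2.0 * i)
               for i in range(1, 8)]
        lifetimes = [100.0 * i for i in range(1, 8)]
        lengths = [-3.0 * i for i in range(1, 8)]
        out = ax.presence_correlations(dur, lifetimes, lengths)
        life = out[out["against"] == "lifetime"]
        assert np.allclose(life["r"], 1.0)
        anti = out[out["against"] == "max_length"]
        assert np.allclose(anti["r"], -1.0)

    def test_coupled_simulation_positive_correlation(self):
        """Presence generated proportional to lifetime plus noise correlates
        positively."""
        rng = np.random.default_rng(3)
        lifetimes = rng.uniform(60, 3600, 40)
        dur = [
            ax.PresenceDurations(i, base_s=0.2 * lt + rng.normal(0, 30),
                                 mid_s=0.1 * lt + rng.normal(0, 30),
                                 tip_s=0.05 * lt + rng.normal(0, 30))
            for i, lt in enumerate(lifetimes)
        ]
        out = ax.presence_correlations(dur, lifetimes, rng.uniform(5, 25, 40))
        life = out[out["against"] == "lifetime"]
        assert (life["r"] > 0.5).all()


class TestNavigation:
    @pytest.mark.parametrize(
        "net_um,stalled", [(3.0, True), (40.0, False), (5.0, False)]
    )
    def test_stalling_rule(self, net_um, stalled):
        out = ax.navigation_metrics([0.0, 3600.0], [[0.0, 0.0], [net_um, 0.0]])
        assert out["velocity_um_per_hr"] == pytest.approx(net_um)
        assert out["stalled"] is stalled

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ax.navigation_metrics([0.0], [[0.0, 0.0]])
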