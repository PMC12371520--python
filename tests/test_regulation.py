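"""Regulatory layer: affinity tables, switching, binding, silencing/recovery."""

import numpy as np
import pytest

from chromsilence import (
    Affinity,
    ChromatinState,
    Feedback,
    KineticParams,
    Species,
    TFState,
    attempt_silencing,
    bound_tfs,
    make_interaction_table,
    process_recovery,
    switch_states,
)
from chromsilence.core import min_image_distance
from chromsilence.fixtures import forced_binding_state

A, R = Species.ACTIVE, Species.REPRESSIVE
ON, OFF = TFState.ON, TFState.OFF
NS, TUA, TUR = (
    ChromatinState.NS,
    ChromatinState.TU_ACTIVE,
    ChromatinState.TU_REPRESSED,
)


class TestInteractionTables:
    @pytest.mark.parametrize("feedback", list(Feedback))
    def test_off_tfs_always_steric(self, feedback):
        t = make_interaction_table(feedback)
        for sp in Species:
            for ch in ChromatinState:
                assert t[sp, OFF, ch] == Affinity.STERIC

    @pytest.mark.parametrize("feedback", list(Feedback))
    def test_active_on_rows_identical_across_feedbacks(self, feedback):
        t = make_interaction_table(feedback)
        assert t[A, ON, TUA] == Affinity.STRONG
        assert t[A, ON, NS] == Affinity.WEAK
        assert t[A, ON, TUR] == Affinity.WEAK

    @pytest.mark.parametrize(
        "feedback,row",
        [
            ("positive", (Affinity.WEAK, Affinity.STRONG, Affinity.STRONG)),
            ("negative", (Affinity.STERIC, Affinity.STRONG, Affinity.STERIC)),
            ("neutral", (Affinity.WEAK, Affinity.WEAK, Affinity.WEAK)),
        ],
    )
    def test_repressive_on_rows(self, feedback, row):
        t = make_interaction_table(feedback)
        assert (t[R, ON, NS], t[R, ON, TUA], t[R, ON, TUR]) == row

    def test_tables_are_total_and_positive_neutral_differ_only_in_rep_on(self):
        pos = make_interaction_table("positive").as_array()
        neu = make_interaction_table("neutral").as_array()
        assert pos.shape == (2, 2, 3)
        diff = pos != neu
        assert diff[R, ON].any()
        diff[R, ON] = False
        assert not diff.any()

    def test_unknown_feedback_rejected(self):
        with pytest.raises(ValueError):
            make_interaction_table("bogus")


class TestSwitching:
    def test_p_zero_is_identity_and_p_one_flips_all(self):
        st = forced_binding_state()
        rng = np.random.default_rng(0)
        before = st.tf_state.copy()
        switch_states(st, 0.0, rng)
        assert np.array_equal(st.tf_state, before)
        switch_states(st, 1.0, rng)
        assert np.array_equal(st.tf_state, 1 - before)

    def test_stationary_on_fraction_is_half(self):
        # symmetric two-state Markov chain: stationary ON fraction = 1/2
        st = forced_binding_state()
        rng = np.random.default_rng(42)
        n, p = 10_000, 0.1
        on = 0
        for _ in range(n):
            switch_states(st, p, rng)
            on += int(st.tf_state[0])
        frac = on / n
        # autocorrelated series: se accounts for correlation time ~ 1/(2p)
        se = 0.5 * np.sqrt(1.0 / (n * p))
        assert abs(frac - 0.5) < 3 * se


class TestBoundTFs:
    def test_empty_when_nothing_in_range(self):
        st = forced_binding_state(separation=5.0)
        assert len(bound_tfs(st, 1, r_bind=1.8)) == 0

    def test_closed_boundary_at_r_bind(self):
        st = forced_binding_state(separation=1.8)
        # closed boundary: a TF at exactly the binding distance is included
        d = float(min_image_distance(st.tf_pos[0], st.pos[0], st.box_length))
        assert list(bound_tfs(st, 1, r_bind=d)) == [0]
        assert list(bound_tfs(st, 1, r_bind=np.nextafter(d, 0.0))) == []

    def test_matches_brute_force_over_random_tfs(self):
        from chromsilence import build_system

        st = build_system(10, [4], 10, 10, 5, 18.0, seed=3)
        got = set(bound_tfs(st, 4, r_bind=2.5).tolist())
        expected = {
            k
            for k in range(st.n_tf)
            if min_image_distance(st.tf_pos[k], st.pos[3], st.box_length) <= 2.5
        }
        assert got == expected

    def test_species_and_state_filters(self):
        st = forced_binding_state()
        assert list(bound_tfs(st, 1, 1.8, species=R, tf_state=ON)) == [0]
        assert list(bound_tfs(st, 1, 1.8, species=A)) == []

    def test_non_tu_bead_rejected(self):
        st = forced_binding_state()
        st.is_tu[0] = False
        st.chromatin_state[0] = NS
        with pytest.raises(ValueError, match="not a TU"):
            bound_tfs(st, 1, 1.8)


class TestSilencingRecovery:
    def kp(self, **kw):
        base = dict(p_switch=0.0, switch_interval=100, p_s=0.5,
                    silencing_interval=100, tau_r=500, r_bind=1.8)
        base.update(kw)
        return KineticParams(**base)

    def test_ps_zero_never_silences(self):
        st = forced_binding_state()
        rng = np.random.default_rng(0)
        for _ in range(200):
            attempt_silencing(st, self.kp(p_s=0.0), rng)
            st.step += 100
        assert st.chromatin_state[0] == TUA

    def test_ps_one_with_bound_repressor_silences_immediately(self):
        st = forced_binding_state()
        log = []
        attempt_silencing(st, self.kp(p_s=1.0), np.random.default_rng(0), log=log)
        assert st.chromatin_state[0] == TUR
        assert st.recovery_deadline[0] == st.step + 500
        assert [(e.tu_id, e.kind) for e in log] == [(1, "SILENCE")]

    def test_unbound_or_off_repressor_cannot_silence(self):
        st = forced_binding_state(separation=3.0)
        attempt_silencing(st, self.kp(p_s=1.0), np.random.default_rng(0))
        assert st.chromatin_state[0] == TUA
        st = forced_binding_state()
        st.tf_state[0] = OFF
        attempt_silencing(st, self.kp(p_s=1.0), np.random.default_rng(0))
        assert st.chromatin_state[0] == TUA

    def test_recovery_boundary_inclusive(self):
        st = forced_binding_state()
        attempt_silencing(st, self.kp(p_s=1.0), np.random.default_rng(0))
        st.step = 499
        process_recovery(st)
        assert st.chromatin_state[0] == TUR
        st.step = 500  # deadline exactly == now -> reactivated
        log = []
        process_recovery(st, log=log)
        assert st.chromatin_state[0] == TUA
        assert st.recovery_deadline[0] == -1
        assert [(e.tu_id, e.kind) for e in log] == [(1, "RECOVER")]

    def test_recovery_happens_at_first_attempt_after_tau_r(self):
        # silence at t0; with tau_r not a multiple of the cadence the TU
        # reactivates at the first attempt time >= t0 + tau_r
        st = forced_binding_state()
        kp = self.kp(p_s=1.0, tau_r=250)
        rng = np.random.default_rng(1)
        log = []
        for _ in range(4):
            process_recovery(st, log=log)
            attempt_silencing(st, kp, rng, log=log)
            st.step += 100
        # silenced at step 0 with deadline 250: the RECOVER event fires at
        # the first attempt time >= 250, i.e. step 300 (then re-silenced)
        assert [(e.step, e.kind) for e in log] == [
            (0, "SILENCE"),
            (300, "RECOVER"),
            (300, "SILENCE"),
        ]

    @pytest.mark.parametrize("p_s,tau_r", [(0.02, 500), (0.05, 1000)])
    def test_forced_binding_renewal_fraction(self, p_s, tau_r):
        """Pinned repressor: repressed fraction -> tau_r/(tau_r + dt/p_s)."""
        st = forced_binding_state()
        kp = self.kp(p_s=p_s, tau_r=tau_r)
        rng = np.random.default_rng(99)
        delta = kp.silencing_interval
        expected = tau_r / (tau_r + delta / p_s)
        # run enough attempts for >= 400 renewal cycles
        cycles = 400
        n_attempts = int(cycles * (tau_r + delta / p_s) / delta)
        repressed = 0
        for _ in range(n_attempts):
            process_recovery(st)
            attempt_silencing(st, kp, rng)
            repressed += int(st.chromatin_state[0] == TUR)
            st.step += delta
        frac = repressed / n_attempts
        assert frac == pytest.approx(expected, rel=0.05)

    def test_repressed_fraction_monotone_in_ps(self):
        fracs = []
        for p_s in (0.02, 0.1, 0.5):
            st = forced_binding_state()
            kp = self.kp(p_s=p_s, tau_r=300)
            rng = np.random.default_rng(5)
            rep = 0
            for _ in range(3000):
                process_recovery(st)
                attempt_silencing(st, kp, rng)
                rep += int(st.chromatin_state[0] == TUR)
                st.step += 100
            fracs.append(rep / 3000)
        assert fracs[0] < fracs[1] < fracs[2]

    def test_compound_occupancy_raises_rate(self):
        # two bound repressors, compound mode: p_eff = 1-(1-p_s)^2
        base = forced_binding_state()
        pos = np.vstack([base.pos, base.pos[1] + [0.0, 1.0, 0.0]])
        from chromsilence.core import SystemState

        st = SystemState(
            pos=pos, n_beads=1, is_tu=base.is_tu.copy(),
            chromatin_state=base.chromatin_state.copy(),
            recovery_deadline=base.recovery_deadline.copy(),
            tf_species=np.array([1, 1], dtype=np.int8),
            tf_state=np.array([1, 1], dtype=np.int8),
            box_length=base.box_length,
        )
        rng = np.random.default_rng(0)
        kp = self.kp(p_s=0.3, tau_r=1, compound_occupancy=True)
        hits = 0
        n = 4000
        for _ in range(n):
            st.chromatin_state[0] = TUA
            st.recovery_deadline[0] = -1
            attempt_silencing(st, kp, rng)
            hits += int(st.chromatin_state[0] == TUR)
        p_eff = 1 - (1 - 0.3) ** 2
        assert hits / n == pytest.approx(p_eff, abs=3 * np.sqrt(p_eff * (1 - p_eff) / n))

    def test_conservation_of_tu_identity(self):
        st = forced_binding_state()
        rng = np.random.default_rng(0)
        kp = self.kp(p_s=0.5, tau_r=200)
        for _ in range(500):
            process_recovery(st)
            switch_states(st, 0.3, rng)
            attempt_silencing(st, kp, rng)
            st.step += 100
            assert st.is_tu.sum() == 1
            assert st.chromatin_state[0] in (TUA, TUR)
            st.validate()
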