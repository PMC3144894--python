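import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from socnetlong.errors import ConfigError, ConsistencyError, RecordError
from socnetlong.survival import (
    EVENT_DEAD,
    EVENT_NONE,
    EVENT_RESIGHT,
    EVENT_RESIGHT_DEAD,
    EncounterHistory,
    ModelSpec,
    FittedModel,
    fit_model,
    history_likelihood,
    likelihood_ratio_test,
    model_average,
    model_table,
    qaicc,
    read_encounters,
    to_mark_ld,
    write_encounters,
)
from socnetlong.synthetic import simulate_encounter_histories

HAND_PARAMS = dict(S=0.8, p=0.5, r=0.2, R=0.3, Rp=0.1, F=0.9, Fp=0.0)


def enumerate_paths(history, params):
    """Independent oracle: explicit sum over every hidden-state path.

    States are tracked as (alive?, at-risk?); per interval the path
    chooses survive/die, the resight/recovery outcomes, and the risk
    transition, and the product of branch probabilities is accumulated
    whenever the implied observations match the recorded history.
    """
    T = history.n_occasions
    cap = history.captures
    ev = history.events

    def get(name, i):
        v = params[name]
        return float(np.asarray(v).ravel()[i] if np.ndim(v) else v)

    def rest_empty(i):
        return not (np.any(cap[i + 1:]) or np.any(ev[i:]))

    def rec(i, at_risk):
        if i == T - 1:
            return 1.0
        S, R, Rp, r = get("S", i), get("R", i), get("Rp", i), get("r", i)
        F, Fp, p = get("F", i), get("Fp", i), get("p", i + 1)
        total = 0.0
        # death in (i, i+1)
        for resight, recover in itertools.product((0, 1), repeat=2):
            obs = (EVENT_RESIGHT_DEAD if resight and recover
                   else EVENT_DEAD if recover
                   else EVENT_RESIGHT if resight else EVENT_NONE)
            if obs == ev[i] and cap[i + 1] == 0 and rest_empty(i + 1):
                total += ((1 - S)
                          * (Rp if resight else 1 - Rp)
                          * (r if recover else 1 - r))
        # survival
        for resight in (0, 1):
            if (EVENT_RESIGHT if resight else EVENT_NONE) != ev[i]:
                continue
            em = S * (R if resight else 1 - R)
            for next_risk in (True, False):
                trans = (F if at_risk else Fp) if next_risk else \
                    ((1 - F) if at_risk else (1 - Fp))
                if cap[i + 1] == 1:
                    capture = p if next_risk else 0.0
                else:
                    capture = (1 - p) if next_risk else 1.0
                if trans == 0.0 or capture == 0.0:
                    continue
                total += em * trans * capture * rec(i + 1, next_risk)
        return total

    return rec(history.first, True)


def all_histories(T):
    """Every capture/event combination for an animal released at occasion 0."""
    for caps in itertools.product((0, 1), repeat=T - 1):
        for evs in itertools.product((0, 1, 2, 3), repeat=T - 1):
            yield np.array((1,) + caps), np.array(evs)


class TestHistoryValidation:
    def test_events_after_dead_recovery_rejected(self):
        with pytest.raises(RecordError, match="after dead"):
            EncounterHistory("x", [1, 0, 1], [2, 0])

    def test_events_before_first_capture_rejected(self):
        with pytest.raises(RecordError, match="precede"):
            EncounterHistory("x", [0, 1, 0], [1, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(RecordError):
            EncounterHistory("x", [1, 0, 0], [0])


class TestHistoryLikelihood:
    def test_hand_enumerated_never_seen_again(self):
        h = EncounterHistory("x", [1, 0], [0])
        assert history_likelihood(h, HAND_PARAMS) == pytest.approx(0.452, abs=1e-12)

    def test_certain_recapture(self):
        h = EncounterHistory("x", [1, 1], [0])
        params = dict(S=1.0, p=1.0, r=0.0, R=0.0, Rp=0.0, F=1.0, Fp=0.0)
        assert history_likelihood(h, params) == pytest.approx(1.0)

    def test_cjs_reduction_never_seen_again(self):
        params = dict(S=0.7, p=0.6, r=0.0, R=0.0, Rp=0.0, F=1.0, Fp=0.0)
        h = EncounterHistory("x", [1, 0], [0])
        expected = (1 - 0.7) + 0.7 * (1 - 0.6)
        assert history_likelihood(h, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("T", [2, 3, 4])
    def test_matches_exhaustive_path_enumeration(self, T):
        rng = np.random.default_rng(T)
        for _ in range(30):
            params = {k: float(rng.uniform(0.05, 0.95))
                      for k in ("S", "p", "r", "R", "Rp", "F", "Fp")}
            caps = np.zeros(T, dtype=int)
            first = int(rng.integers(T - 1))
            caps[first] = 1
            caps[first + 1:] = rng.integers(0, 2, T - 1 - first)
            evs = np.zeros(T - 1, dtype=int)
            evs[first:] = rng.integers(0, 4, T - 1 - first)
            try:
                h = EncounterHistory("x", caps, evs)
            except RecordError:
                continue
            assert history_likelihood(h, params) == pytest.approx(
                enumerate_paths(h, params), abs=1e-12
            )

    @pytest.mark.parametrize("T", [2, 3])
    def test_total_probability_is_one(self, T):
        rng = np.random.default_rng(10 + T)
        params = {k: float(rng.uniform(0.1, 0.9))
                  for k in ("S", "p", "r", "R", "Rp", "F", "Fp")}
        total = 0.0
        for caps, evs in all_histories(T):
            try:
                h = EncounterHistory("x", caps, evs)
            except RecordError:
                continue
            total += history_likelihood(h, params)
        assert total == pytest.approx(1.0, abs=1e-12)


def cjs_loglik(theta, histories):
    """Independent CJS likelihood (chi recursion) on capture data only."""
    s = 1 / (1 + np.exp(-theta[0]))
    p = 1 / (1 + np.exp(-theta[1]))
    ll = 0.0
    for h in histories:
        caps = h.captures
        T = len(caps)
        last = max(np.nonzero(caps)[0])
        for i in range(h.first, last):
            ll += np.log(s) + np.log(p if caps[i + 1] else 1 - p)
        chi = 1.0
        for _ in range(T - 1 - last):
            chi = (1 - s) + s * (1 - p) * chi
        ll += np.log(chi)
    return -ll


class TestFitModel:
    def test_cjs_reduction_matches_independent_cjs_fit(self):
        truth = dict(S=0.75, p=0.6, r=0.0, R=0.0, Rp=0.0, F=1.0, Fp=0.0)
        histories = simulate_encounter_histories(truth, 600, 6, seed=5)
        spec = ModelSpec(r=0.0, R=0.0, Rp=0.0, F=1.0, Fp=0.0)
        fit = fit_model(histories, spec, compute_vcov=False)
        res = optimize.minimize(cjs_loglik, np.zeros(2), args=(histories,),
                                method="BFGS")
        s_cjs, p_cjs = 1 / (1 + np.exp(-res.x))
        assert fit.real_estimate("S")[0] == pytest.approx(s_cjs, abs=1e-4)
        assert fit.real_estimate("p")[0] == pytest.approx(p_cjs, abs=1e-4)

    def test_group_structure_recovers_ordering(self):
        rng = np.random.default_rng(0)
        histories = []
        for grp, s in (("good", 0.85), ("bad", 0.6)):
            pars = dict(S=s, p=0.8, r=0.1, R=0.3, Rp=0.05, F=0.95, Fp=0.1)
            histories += simulate_encounter_histories(
                pars, 250, 7, seed=np.random.default_rng(rng.integers(2**31)),
                group=grp, id_prefix=grp)
        fit = fit_model(histories, ModelSpec(S="group"), compute_vcov=False)
        assert fit.real_estimate("S", group="good")[0] > \
            fit.real_estimate("S", group="bad")[0]

    def test_nonconvergence_is_flagged_not_silent(self):
        histories = simulate_encounter_histories(
            dict(S=0.7, p=0.8, r=0.1, R=0.3, Rp=0.05, F=0.9, Fp=0.1), 50, 4, seed=0)
        fit = fit_model(histories, ModelSpec(), compute_vcov=False)
        assert isinstance(fit.converged, bool)


class TestModelSelection:
    def test_qaicc_arithmetic(self):
        assert qaicc(-100, 5, 100, 1.0) == pytest.approx(200 + 10 + 60 / 94)

    def test_c_hat_scales_deviance(self):
        assert qaicc(-100, 5, 100, 2.0) == pytest.approx(100 + 10 + 60 / 94)

    def test_weight_pair(self):
        w = np.exp(-np.array([0.0, 2.0]) / 2)
        w /= w.sum()
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def _two_fits(self):
        truth = dict(S=0.75, p=0.85, r=0.1, R=0.4, Rp=0.05, F=0.95, Fp=0.2)
        histories = simulate_encounter_histories(truth, 150, 5, seed=3)
        f0 = fit_model(histories, ModelSpec())
        f1 = fit_model(histories, ModelSpec(S="time"))
        return f0, f1

    def test_model_table_weights_sum_to_one(self):
        f0, f1 = self._two_fits()
        table = model_table([f0, f1])
        assert table["weight"].sum() == pytest.approx(1.0)
        assert (table["delta_qaicc"] >= 0).all()
        assert table["qaicc"].is_monotonic_increasing

    def test_identical_models_split_weight(self):
        f0, _ = self._two_fits()
        table = model_table([f0, f0])
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_mixed_data_rejected(self):
        truth = dict(S=0.75, p=0.85, r=0.1, R=0.4, Rp=0.05, F=0.95, Fp=0.2)
        f0 = fit_model(simulate_encounter_histories(truth, 100, 5, seed=1),
                       ModelSpec(), compute_vcov=False)
        f1 = fit_model(simulate_encounter_histories(truth, 120, 5, seed=2),
                       ModelSpec(), compute_vcov=False)
        with pytest.raises(ConsistencyError):
            model_table([f0, f1])

    def test_model_average_mean_and_degenerate_weights(self):
        f0, f1 = self._two_fits()
        est, se = model_average([f0], "S")
        e0, s0 = f0.real_estimate("S")
        assert est == pytest.approx(e0)
        assert se == pytest.approx(s0)
        est2, _ = model_average([f0, f1], "S")
        w = model_table([f0, f1])["weight"]
        assert min(e0, f1.real_estimate("S")[0]) <= est2 <= \
            max(e0, f1.real_estimate("S", time=0)[0]) + 1e-9

    def test_lrt_identical_and_nested(self):
        f0, f1 = self._two_fits()
        stat, df, p = likelihood_ratio_test(f0, f1)
        assert df == f1.K - f0.K
        assert 0 <= p <= 1
        with pytest.raises(ConsistencyError):
            likelihood_ratio_test(f1, f0)


class TestIO:
    def test_roundtrip(self, tmp_path):
        truth = dict(S=0.8, p=0.7, r=0.1, R=0.3, Rp=0.05, F=0.9, Fp=0.1)
        histories = simulate_encounter_histories(truth, 20, 5, seed=9,
                                                 staggered_entry=True)
        path = tmp_path / "enc.csv"
        write_encounters(histories, path)
        back = read_encounters(path)
        assert len(back) == len(histories)
        for a, b in zip(histories, back):
            np.testing.assert_array_equal(a.captures, b.captures)
            np.testing.assert_array_equal(a.events, b.events)
            assert a.group == b.group

    def test_mark_ld_string(self):
        h = EncounterHistory("x", [1, 0, 0], [1, 2])
        assert to_mark_ld(h) == "12010"
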