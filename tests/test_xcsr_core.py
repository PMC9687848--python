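"""XCSR mechanics: matching, covering, prediction, updates, GA, deletion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import xcsr_extubation as xe
from xcsr_extubation.population import FULL_RANGE, Classifier, IntervalPredicate, Population
from xcsr_extubation.xcsr import (
    XCSRParams,
    build_match_set,
    build_prediction_array,
    cover,
    denormalize,
    enforce_population_limit,
    environment_reward,
    matches,
    normalize,
    predict,
    rule_accuracy,
    run_ga,
    select_action,
    subsumes,
    update_action_set,
)

PARAMS = XCSRParams()


def make_rule(center, spread, action=0, d=2, **kw):
    cond = [IntervalPredicate(c, s) for c, s in zip(center, spread)]
    defaults = dict(prediction=10.0, prediction_error=0.0, fitness=1.0)
    defaults.update(kw)
    return Classifier(condition=cond, action=action, **defaults)


# -- matching ---------------------------------------------------------------

@pytest.mark.parametrize(
    "c,s,x,expected",
    [
        (0.5, 0.2, 0.31, True),
        (0.5, 0.2, 0.7, False),   # upper bound exclusive
        (0.5, 0.0, 0.5, False),   # empty interval
        (0.5, 0.2, 0.3, True),    # lower bound inclusive
    ],
)
def test_interval_matching_half_open(c, s, x, expected):
    assert matches(IntervalPredicate(c, s), x) is expected


@given(
    st.lists(
        st.tuples(
            st.floats(-1, 2), st.floats(0, 1.5), st.floats(-0.5, 1.5)
        ),
        min_size=1,
        max_size=10,
    )
)
def test_rule_matching_agrees_with_locuswise_inequality(loci):
    """A rule matches iff c-s <= x < c+s holds at every locus."""
    preds = [IntervalPredicate(c, s) for c, s, _ in loci]
    x = [v for _, _, v in loci]
    rule = make_rule([p.center for p in preds], [p.spread for p in preds])
    brute = all(p.center - p.spread <= v < p.center + p.spread
                for p, v in zip(preds, x))
    assert rule.matches(x) is brute


# -- normalization ----------------------------------------------------------

def test_normalize_midpoint_and_round_trip():
    frame = pd.DataFrame({"a": [10.0, 15.0, 20.0], "b": [1.0, 2.0, 5.0]})
    norm, ranges = normalize(frame)
    assert norm.loc[1, "a"] == pytest.approx(0.5)
    back = denormalize(norm, ranges)
    assert np.abs(back.to_numpy() - frame.to_numpy()).max() < 1e-9


def test_normalize_constant_column_flagged():
    frame = pd.DataFrame({"a": [3.0, 3.0, 3.0], "b": [0.0, 1.0, 2.0]})
    norm, ranges = normalize(frame)
    assert (norm["a"] == 0.5).all()
    assert bool(ranges.loc["a", "constant"]) is True
    assert bool(ranges.loc["b", "constant"]) is False


# -- covering ---------------------------------------------------------------

def test_cover_centers_on_input(rng):
    x = np.array([0.3, 0.7, 0.1])
    params = XCSRParams(p_dontcare=0.0)
    cl = cover(x, 1, params, rng)
    assert [p.center for p in cl.condition] == pytest.approx(list(x))
    assert all(0 < p.spread <= params.s_r for p in cl.condition)
    assert cl.matches(x)
    assert cl.action == 1
    assert cl.prediction == params.p_init
    assert cl.fitness == params.f_init


def test_cover_forced_dont_care(rng):
    x = np.array([0.3, 0.7])
    cl = cover(x, 0, XCSRParams(p_dontcare=1.0), rng)
    for p in cl.condition:
        assert p.lower <= 0.0 and p.upper >= 1.0


def test_cover_dont_care_rate_matches_probability(rng):
    """Monte-Carlo check of the per-locus don't-care Bernoulli rate."""
    x = np.full(10, 0.4)
    hits = total = 0
    for _ in range(1000):  # 10,000 loci
        cl = cover(x, 0, PARAMS, rng)
        hits += sum(p.spread == FULL_RANGE[1] for p in cl.condition)
        total += 10
    assert hits / total == pytest.approx(0.5, abs=0.02)


# -- match set & covering trigger -------------------------------------------

def test_match_set_covers_empty_population(rng):
    pop = Population(3)
    x = np.array([0.2, 0.5, 0.9])
    idx = build_match_set(pop, x, 0, PARAMS, rng)
    acts = set(pop.actions[idx].tolist())
    assert acts == {0, 1}
    for i in idx:
        assert pop.match_mask(x)[i]


def test_match_set_covers_missing_action_only(rng):
    pop = Population(2)
    pop.insert_classifier(make_rule([0.5, 0.5], [0.6, 0.6], action=0))
    x = np.array([0.5, 0.5])
    idx = build_match_set(pop, x, 0, PARAMS, rng)
    assert set(pop.actions[idx].tolist()) == {0, 1}
    assert pop.n == 2  # exactly one covered rule added


def test_match_set_no_covering_when_both_actions_present(rng):
    pop = Population(2)
    pop.insert_classifier(make_rule([0.5, 0.5], [0.6, 0.6], action=0))
    pop.insert_classifier(make_rule([0.5, 0.5], [0.6, 0.6], action=1))
    idx = build_match_set(pop, np.array([0.5, 0.5]), 0, PARAMS, rng)
    assert pop.n == 2
    assert len(idx) == 2


# -- prediction array and action selection ----------------------------------

def test_prediction_array_fitness_weighted_mean():
    pop = Population(1)
    pop.insert_classifier(make_rule([0.5], [0.6], action=0, prediction=1000.0, fitness=1.0))
    pop.insert_classifier(make_rule([0.4], [0.6], action=0, prediction=0.0, fitness=3.0))
    pa = build_prediction_array(pop, np.array([0, 1]))
    assert pa.expected_reward[0] == pytest.approx(250.0)


def test_prediction_array_singleton_and_symmetry():
    pop = Population(1)
    pop.insert_classifier(make_rule([0.5], [0.6], action=1, prediction=10.0, fitness=2.0))
    pa = build_prediction_array(pop, np.array([0]))
    assert pa.expected_reward[1] == pytest.approx(10.0)

    pop2 = Population(1)
    pop2.insert_classifier(make_rule([0.5], [0.6], action=0, prediction=0.0, fitness=2.0))
    pop2.insert_classifier(make_rule([0.4], [0.6], action=0, prediction=1000.0, fitness=2.0))
    pa2 = build_prediction_array(pop2, np.array([0, 1]))
    assert pa2.expected_reward[0] == pytest.approx(500.0)


def test_prediction_array_bounded_by_contributing_predictions(rng):
    """Each PA entry lies within [min p, max p] of its action's rules."""
    for _ in range(200):
        pop = Population(1)
        k = rng.integers(1, 6)
        for _ in range(k):
            pop.insert_classifier(
                make_rule([rng.random()], [2.0], action=0,
                          prediction=float(rng.uniform(0, 1000)),
                          fitness=float(rng.uniform(0.01, 5)),
                          numerosity=int(rng.integers(1, 4))),
                merge=False,
            )
        pa = build_prediction_array(pop, np.arange(pop.n))
        preds = pop.prediction[: pop.n]
        assert preds.min() - 1e-9 <= pa.expected_reward[0] <= preds.max() + 1e-9


def test_exploit_selects_argmax_and_tie_breaks(rng):
    from xcsr_extubation.xcsr import PredictionArray

    pa = PredictionArray({0: 100.0, 1: 900.0}, {0: 1.0, 1: 1.0})
    assert select_action(pa, "exploit", rng) == 1
    tie = PredictionArray({0: 500.0, 1: 500.0}, {0: 1.0, 1: 1.0})
    assert select_action(tie, "exploit", rng) == 0
    tie_fit = PredictionArray({0: 500.0, 1: 500.0}, {0: 1.0, 1: 2.0})
    assert select_action(tie_fit, "exploit", rng) == 1


def test_explore_roulette_frequencies(rng):
    from xcsr_extubation.xcsr import PredictionArray

    pa = PredictionArray({0: 100.0, 1: 900.0}, {0: 1.0, 1: 1.0})
    picks = np.array([select_action(pa, "explore", rng) for _ in range(10_000)])
    assert picks.mean() == pytest.approx(0.9, abs=0.02)


# -- reward and update -------------------------------------------------------

def test_environment_reward_schemes():
    assert environment_reward(1, 1, PARAMS) == 1000.0
    assert environment_reward(0, 1, PARAMS) == 0.0
    custom = XCSRParams(reward_correct=500.0, reward_incorrect=-500.0)
    assert environment_reward(1, 1, custom) == 500.0
    assert environment_reward(1, 0, custom) == -500.0


def test_widrow_hoff_prediction_update_past_mam():
    pop = Population(1)
    pop.insert_classifier(make_rule([0.5], [0.6], prediction=10.0, fitness=1.0))
    pop.experience[0] = 5  # past the MAM phase (1/beta = 5)
    update_action_set(pop, np.array([0]), 1000.0, PARAMS)
    assert pop.prediction[0] == pytest.approx(208.0)  # 10 + 0.2 * 990


def test_error_updated_with_pre_update_prediction():
    pop = Population(1)
    pop.insert_classifier(make_rule([0.5], [0.6], prediction=100.0, fitness=1.0))
    pop.experience[0] = 10
    update_action_set(pop, np.array([0]), 1000.0, PARAMS)
    # eps <- 0 + beta * (|1000 - 100| - 0), using p before its own update
    assert pop.error[0] == pytest.approx(0.2 * 900.0)


def test_accuracy_kappa_branches():
    assert rule_accuracy(5.0, PARAMS) == pytest.approx(1.0)
    assert rule_accuracy(20.0, PARAMS) == pytest.approx(0.1 * 2 ** (-0.1))
    assert rule_accuracy(0.0, PARAMS) == pytest.approx(1.0)


def test_mam_averaging_during_early_experience():
    pop = Population(1)
    pop.insert_classifier(make_rule([0.5], [0.6], prediction=10.0, fitness=1.0))
    update_action_set(pop, np.array([0]), 1000.0, PARAMS)
    # first update: learning rate 1/1, prediction jumps to the reward
    assert pop.prediction[0] == pytest.approx(1000.0)
    assert pop.experience[0] == 1


# -- subsumption -------------------------------------------------------------

def test_universal_rule_subsumes_any_same_action_rule():
    general = make_rule([0.5, 0.5], [1.0, 1.0], action=1, experience=25,
                        prediction_error=0.0)
    specific = make_rule([0.4, 0.6], [0.1, 0.2], action=1)
    assert subsumes(general, specific, PARAMS)


def test_identical_conditions_do_not_subsume():
    a = make_rule([0.5, 0.5], [0.3, 0.3], action=1, experience=25,
                  prediction_error=0.0)
    b = make_rule([0.5, 0.5], [0.3, 0.3], action=1)
    assert not subsumes(a, b, PARAMS)


def test_inexperienced_rule_cannot_subsume():
    general = make_rule([0.5, 0.5], [1.0, 1.0], action=1, experience=10,
                        prediction_error=0.0)
    specific = make_rule([0.5, 0.5], [0.1, 0.1], action=1)
    assert not subsumes(general, specific, PARAMS)


def test_subsumption_implies_containment_of_matches(rng):
    """Whenever g subsumes s, every input matched by s is matched by g."""
    for _ in range(100):
        g = make_rule(rng.uniform(0, 1, 2), rng.uniform(0, 1, 2), action=1,
                      experience=30, prediction_error=0.0)
        s = make_rule(rng.uniform(0, 1, 2), rng.uniform(0, 0.5, 2), action=1)
        if not subsumes(g, s, PARAMS):
            continue
        grid = rng.uniform(-0.5, 1.5, size=(400, 2))
        for x in grid:
            if s.matches(x):
                assert g.matches(x)


# -- genetic algorithm -------------------------------------------------------

def _niche_population(t_stamp=0):
    pop = Population(2)
    for k in range(2):
        pop.insert_classifier(
            make_rule([0.5, 0.5], [0.3 + 0.1 * k, 0.3], action=1,
                      prediction=100.0 * (k + 1), fitness=1.0 + k,
                      ga_timestamp=t_stamp),
            merge=False,
        )
    return pop


def test_ga_does_not_trigger_before_threshold(rng):
    pop = _niche_population(t_stamp=0)
    ran = run_ga(pop, np.array([0, 1]), np.array([0.5, 0.5]), t=10, params=PARAMS, rng=rng)
    assert not ran and pop.n == 2


def test_ga_without_variation_clones_parents(rng):
    pop = _niche_population(t_stamp=0)
    params = XCSRParams(chi=0.0, mu=0.0)
    micro_before = pop.micro_count
    ran = run_ga(pop, np.array([0, 1]), np.array([0.5, 0.5]), t=100, params=params, rng=rng)
    assert ran
    # offspring identical to parents merge into existing macroclassifiers
    assert pop.n == 2
    assert pop.micro_count == micro_before + 2


def test_mutation_steps_bounded_by_m_i(rng):
    params = XCSRParams(chi=0.0, mu=1.0, m_i=0.1, theta_sub=10**9)
    for _ in range(50):
        pop = _niche_population(t_stamp=0)
        parents_c = pop.centers[:2].copy()
        parents_s = pop.spreads[:2].copy()
        run_ga(pop, np.array([0, 1]), np.array([0.5, 0.5]), t=100,
               params=params, rng=rng)
        for child in range(2, pop.n):
            dc = np.abs(pop.centers[child] - parents_c, )
            # child comes from one of the two parents
            dev_c = np.min(np.abs(parents_c - pop.centers[child]), axis=0)
            dev_s = np.min(np.abs(parents_s - pop.spreads[child]), axis=0)
            assert (dev_c <= params.m_i + 1e-12).all()
            assert (dev_s <= params.m_i + 1e-12).all()
            assert (pop.spreads[child] >= 0).all()


def test_ga_timestamp_refreshed(rng):
    pop = _niche_population(t_stamp=0)
    run_ga(pop, np.array([0, 1]), np.array([0.5, 0.5]), t=100, params=PARAMS, rng=rng)
    assert (pop.ga_timestamp[:2] == 100).all()


# -- deletion ----------------------------------------------------------------

def test_no_deletion_at_exact_capacity(rng):
    params = XCSRParams(N=2)
    pop = _niche_population()
    deleted = enforce_population_limit(pop, params, rng)
    assert deleted == 0 and pop.micro_count == 2


def test_forced_deletion_with_zero_vote(rng):
    params = XCSRParams(N=2)
    pop = Population(1)
    keep = pop.insert_classifier(make_rule([0.5], [0.6], fitness=1.0))
    pop.as_size[keep] = 0.0  # zero vote: never chosen by the roulette
    doomed = pop.insert_classifier(make_rule([0.2], [0.1], fitness=1.0,
                                             numerosity=2))
    pop.as_size[doomed] = 5.0
    enforce_population_limit(pop, params, rng)
    assert pop.micro_count == 2
    assert pop.numerosity[doomed] == 1  # the voting rule lost a copy
    assert pop.numerosity[keep] == 1


def test_deletion_frequencies_match_vote_proportions(rng):
    """Monte-Carlo: roulette removal follows the deletion votes."""
    votes = np.array([1.0, 2.0, 7.0])
    counts = np.zeros(3)
    for _ in range(10_000):
        pop = Population(1)
        for k in range(3):
            i = pop.insert_classifier(
                make_rule([0.1 * k], [0.05], fitness=1.0), merge=False
            )
            pop.as_size[i] = votes[k]
        enforce_population_limit(pop, XCSRParams(N=2), rng)
        gone = set(range(3)) - {int(round(a / 0.1)) for a in pop.centers[: pop.n, 0]}
        counts[gone.pop()] += 1
    freq = counts / counts.sum()
    assert freq == pytest.approx(votes / votes.sum(), abs=0.02)


# -- training and prediction -------------------------------------------------

def test_training_is_deterministic_under_seed(planted2_normalized):
    X, y, _ = planted2_normalized
    params = XCSRParams(epochs=3, seed=9)
    r1 = xe.train(X, y, params)
    r2 = xe.train(X, y, params)
    np.testing.assert_array_equal(r1.curve, r2.curve)
    assert r1.population.n == r2.population.n
    np.testing.assert_array_equal(
        r1.population.centers[: r1.population.n],
        r2.population.centers[: r2.population.n],
    )
    np.testing.assert_array_equal(
        r1.population.numerosity[: r1.population.n],
        r2.population.numerosity[: r2.population.n],
    )


def test_trained_rules_have_one_predicate_per_variable(short_trained):
    result, params, X, y = short_trained
    pop = result.population
    assert pop.n_features == 40
    for cl in pop.classifiers()[:20]:
        assert len(cl.condition) == 40


def test_numerosity_conserved_every_trial(planted2_normalized):
    X, y, _ = planted2_normalized
    params = XCSRParams(epochs=2, seed=3)
    micro_counts = []
    xe.train(X, y, params, on_trial=lambda pop: micro_counts.append(pop.micro_count))
    assert micro_counts, "callback never invoked"
    assert max(micro_counts) <= params.N
    assert min(micro_counts) >= 0


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        xe.train(np.empty((0, 40)), np.empty(0, dtype=int), XCSRParams(epochs=1))


def test_predict_abstains_on_empty_population():
    pop = Population(2)
    action, pa = predict(pop, np.array([0.5, 0.5]))
    assert action is None
    assert pa.present_actions == set()


def test_predict_follows_single_matching_rule():
    pop = Population(2)
    pop.insert_classifier(make_rule([0.5, 0.5], [0.6, 0.6], action=1,
                                    prediction=900.0, fitness=2.0))
    action, pa = predict(pop, np.array([0.5, 0.5]))
    assert action == 1
    assert pa.present_actions == {1}


def test_learning_curve_is_windowed_exploit_accuracy(short_trained):
    result, params, X, y = short_trained
    # one curve point per exploit trial; half the trials are exploit
    assert result.curve.size == params.epochs * len(X) // 2
    assert np.all((0 <= result.curve) & (result.curve <= 1))
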