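"""Fold enrichment, NSAF, replicate presence and the Poisson-mixture MaxP."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from baitprey.model import (
    Age,
    Antibody,
    Channel,
    ScoreModelParams,
    ValidationError,
)
from baitprey.scoring import (
    build_profiles,
    compute_fold_enrichment,
    compute_nsaf,
    posterior_true,
    replicate_presence,
    score_prey_maxp,
)
from baitprey.simulate import SimulationConfig, simulate_apms_experiment

from conftest import make_obs


@pytest.mark.parametrize(
    "bait, control, pseudo, expected",
    [(5, 5, 0, 1.0), (16, 4, 1, 3.4), (0, 0, 1, 1.0)],
)
def test_fold_enrichment_values(bait, control, pseudo, expected):
    assert compute_fold_enrichment(bait, control, pseudo) == pytest.approx(expected)


def test_fold_enrichment_undefined_without_pseudocount():
    with pytest.raises(ValidationError):
        compute_fold_enrichment(0, 0, 0)


@settings(derandomize=True, max_examples=100)
@given(
    b=st.integers(0, 1000),
    c=st.integers(0, 1000),
    pseudo=st.floats(0.1, 5.0),
)
def test_fold_enrichment_monotone(b, c, pseudo):
    base = compute_fold_enrichment(b, c, pseudo)
    assert compute_fold_enrichment(b + 1, c, pseudo) > base
    assert compute_fold_enrichment(b, c + 1, pseudo) < base


def test_nsaf_single_prey_is_one():
    assert compute_nsaf({"A": 7}, {"A": 350}) == {"A": 1.0}


def test_nsaf_length_normalization():
    out = compute_nsaf({"A": 10, "B": 10}, {"A": 100, "B": 200})
    assert out["A"] == pytest.approx(2 / 3)
    assert out["B"] == pytest.approx(1 / 3)


def test_nsaf_all_zero_counts_error():
    with pytest.raises(ValidationError, match="abundance"):
        compute_nsaf({"A": 0, "B": 0}, {"A": 100, "B": 200})


def test_nsaf_missing_length_names_prey():
    with pytest.raises(ValidationError, match="B"):
        compute_nsaf({"A": 1, "B": 1}, {"A": 100})


@settings(derandomize=True, max_examples=50)
@given(
    counts=st.lists(st.integers(0, 100), min_size=1, max_size=8),
    scale=st.integers(2, 9),
)
def test_nsaf_sums_to_one_and_scale_invariant(counts, scale):
    if sum(counts) == 0:
        counts[0] = 1
    sc = {f"p{i}": c for i, c in enumerate(counts)}
    lengths = {f"p{i}": 100 + 37 * i for i in range(len(counts))}
    out = compute_nsaf(sc, lengths)
    assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
    scaled = compute_nsaf({k: v * scale for k, v in sc.items()}, lengths)
    for k in out:
        assert scaled[k] == pytest.approx(out[k], abs=1e-12)


def test_replicate_presence_counts_bait_channel_only():
    obs = [
        make_obs(prey="X", replicate=1, channel=Channel.BAIT),
        make_obs(prey="X", purification="p3", replicate=3, channel=Channel.BAIT),
        make_obs(prey="Y", purification="pc", channel=Channel.CONTROL),
    ]
    assert replicate_presence(obs, "X") == 2
    assert replicate_presence(obs, "Y") == 0
    assert replicate_presence(obs, "ABSENT") == 0


def test_replicate_presence_matches_brute_force_scan():
    obs, _ = simulate_apms_experiment(
        SimulationConfig(n_true_interactors=5, n_background=10,
                         n_contaminants=2, seed=11)
    )
    preys = {o.prey_id for o in obs}
    for prey in preys:
        expected = len(
            {
                o.replicate
                for o in obs
                if o.prey_id == prey
                and o.channel is Channel.BAIT
                and o.spectral_count > 0
            }
        )
        assert replicate_presence(obs, prey) == expected


def test_maxp_at_background_mean_is_low():
    params = ScoreModelParams(prior_true=0.5, lambda_bg=2, enrichment_factor=10)
    assert score_prey_maxp([2], params) < 0.5


def test_maxp_at_enriched_mean_is_high():
    params = ScoreModelParams(prior_true=0.5, lambda_bg=2, enrichment_factor=10)
    assert score_prey_maxp([20], params) > 0.99


def test_maxp_is_a_maximum():
    params = ScoreModelParams(lambda_bg=2, enrichment_factor=10)
    a, b = 3, 15
    assert score_prey_maxp([a, b], params) == max(
        score_prey_maxp([a], params), score_prey_maxp([b], params)
    )


def test_zero_background_rate_rejected():
    with pytest.raises(ValidationError, match="floor"):
        ScoreModelParams(lambda_bg=0.0)


@settings(derandomize=True, max_examples=60)
@given(
    counts=st.lists(st.integers(0, 60), min_size=1, max_size=5),
    idx=st.integers(0, 4),
    lam=st.floats(0.5, 5.0),
    factor=st.floats(2.0, 20.0),
)
def test_maxp_monotone_in_counts(counts, idx, lam, factor):
    params = ScoreModelParams(lambda_bg=lam, enrichment_factor=factor)
    base = score_prey_maxp(counts, params)
    bumped = list(counts)
    bumped[idx % len(counts)] += 1
    assert score_prey_maxp(bumped, params) >= base
    # adding a replicate never decreases the score
    assert score_prey_maxp(counts + [0], params) >= base


def test_posterior_closed_form():
    params = ScoreModelParams(prior_true=0.5, lambda_bg=2, enrichment_factor=10)
    x = 5
    num = math.exp(-20) * 20**x
    den = num + math.exp(-2) * 2**x
    assert posterior_true(x, params) == pytest.approx(num / den, rel=1e-12)


def test_true_interactors_score_higher_than_background_on_average():
    cfg = SimulationConfig(
        n_true_interactors=30, n_background=60, n_contaminants=0,
        enrichment_factor=5.0, seed=3,
    )
    obs, truth = simulate_apms_experiment(cfg)
    profiles = build_profiles(obs, enrichment_factor=5.0)
    mean_true = sum(profiles[p].maxp for p in truth.true_ids) / len(truth.true_ids)
    bg = [profiles[p].maxp for p in truth.background_ids if p in profiles]
    assert mean_true > sum(bg) / len(bg)


def test_build_profiles_aggregation():
    obs = [
        make_obs(prey="X", purification="b1", replicate=1, spectral_count=12,
                 unique_peptides=3),
        make_obs(prey="X", purification="b2", replicate=2, spectral_count=8,
                 unique_peptides=5, antibody=Antibody.PS940, age=Age.P5),
        make_obs(prey="X", purification="c1", replicate=1,
                 channel=Channel.CONTROL, spectral_count=4, unique_peptides=1),
    ]
    prof = build_profiles(obs)["X"]
    assert prof.psm_total_bait == 20
    assert prof.psm_total_control == 4
    assert prof.unique_peptides_max == 5
    assert prof.replicate_presence == 2
    assert prof.fold_ratio == pytest.approx(21 / 5)
    assert prof.conditions_seen == frozenset(
        {(Antibody.C_TERM, Age.P50), (Antibody.PS940, Age.P5)}
    )
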