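"""Two-pass filter, rescue criteria, contaminant removal, tiers, merging."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from baitprey.filtering import (
    assign_confidence_tier,
    build_screen_members,
    first_pass_filter,
    merge_literature_partners,
    remove_contaminants,
    second_pass_rescue,
)
from baitprey.model import (
    Age,
    Antibody,
    FilterConfig,
    InteractomeMember,
    ProteinList,
    Provenance,
    RescueReason,
    Tier,
    ValidationError,
)

from conftest import make_profile

CFG = FilterConfig()
EMPTY_LIT = ProteinList(name="lit", members=frozenset())


def test_first_pass_keeps_qualified_prey():
    p = make_profile(fold=3.4, unique=2)
    assert first_pass_filter([p], CFG) == {p.prey_id}


def test_first_pass_peptide_rule_beats_fold():
    p = make_profile(fold=100.0, unique=1)
    assert first_pass_filter([p], CFG) == set()


def test_first_pass_matches_predicate_scan():
    rng = random.Random(5)
    profiles = [
        make_profile(
            prey=f"P{i}",
            fold=rng.uniform(0.5, 10),
            unique=rng.randint(0, 5),
        )
        for i in range(20)
    ]
    got = first_pass_filter(profiles, CFG)
    expected = {
        p.prey_id
        for p in profiles
        if p.unique_peptides_max >= 2 and p.fold_ratio >= 1.5
    }
    assert got == expected


@settings(derandomize=True, max_examples=40)
@given(thresh=st.floats(0.5, 10.0), bump=st.floats(0.0, 5.0))
def test_raising_fold_threshold_never_grows_survivors(thresh, bump):
    rng = random.Random(9)
    profiles = [
        make_profile(prey=f"P{i}", fold=rng.uniform(0.5, 12), unique=2)
        for i in range(25)
    ]
    lo = FilterConfig(first_pass_fold=thresh)
    hi = FilterConfig(first_pass_fold=thresh + bump)
    assert first_pass_filter(profiles, hi) <= first_pass_filter(profiles, lo)


def test_first_pass_order_invariant():
    rng = random.Random(1)
    profiles = [
        make_profile(prey=f"P{i}", fold=rng.uniform(0.5, 8), unique=rng.randint(1, 4))
        for i in range(15)
    ]
    shuffled = profiles[:]
    rng.shuffle(shuffled)
    assert first_pass_filter(profiles, CFG) == first_pass_filter(shuffled, CFG)


# --- rescue criteria -------------------------------------------------------

FP_PROFILE = make_profile(prey="ATP1A1", fold=6.0, unique=3)
FP_IDS = {"ATP1A1"}


def _rescue(candidate, literature=EMPTY_LIT, family_map=None):
    return second_pass_rescue(
        candidate, [FP_PROFILE], FP_IDS, literature, family_map
    )


def test_rescue_by_literature():
    cand = make_profile(prey="NETO2", fold=1.2, unique=1)
    lit = ProteinList(name="lit", members=frozenset({"NETO2"}))
    assert _rescue(cand, literature=lit) == (True, RescueReason.LITERATURE_VALIDATED)


def test_rescue_by_family_in_first_pass():
    cand = make_profile(prey="ATP1A2", fold=1.2, unique=1)
    assert _rescue(cand) == (True, RescueReason.FAMILY_IN_FIRST_PASS)


def test_rescue_by_family_with_explicit_map():
    cand = make_profile(prey="SOMEGENE", fold=1.2, unique=1)
    fam = {"SOMEGENE": "FAM1", "ATP1A1": "FAM1"}
    assert _rescue(cand, family_map=fam) == (
        True,
        RescueReason.FAMILY_IN_FIRST_PASS,
    )


def test_rescue_by_multi_experiment_single_peptide():
    cand = make_profile(
        prey="ZZZ", fold=1.2, unique=1, replicates=1,
        conditions=((Antibody.C_TERM, Age.P50), (Antibody.PS940, Age.P50)),
    )
    assert _rescue(cand, family_map={}) == (True, RescueReason.MULTI_EXPERIMENT)


def test_no_rescue_for_isolated_single_peptide():
    cand = make_profile(
        prey="ZZZ", fold=1.2, unique=1, replicates=1,
        conditions=((Antibody.C_TERM, Age.P50),),
    )
    assert _rescue(cand, family_map={}) == (False, RescueReason.NONE)


def test_rescue_precedence_literature_first():
    cand = make_profile(prey="ATP1A2", fold=1.2, unique=1)
    lit = ProteinList(name="lit", members=frozenset({"ATP1A2"}))
    assert _rescue(cand, literature=lit) == (
        True,
        RescueReason.LITERATURE_VALIDATED,
    )


def test_multi_experiment_requires_single_peptide():
    # a two-peptide prey that failed on fold is not a criterion-(c) rescue
    cand = make_profile(
        prey="BGX", fold=1.1, unique=2, replicates=3,
        conditions=((Antibody.C_TERM, Age.P50), (Antibody.PS940, Age.P5)),
    )
    assert _rescue(cand, family_map={}) == (False, RescueReason.NONE)


# --- contaminant removal ---------------------------------------------------

def test_remove_contaminants_empty_list_is_identity():
    ids = {"A", "B"}
    assert remove_contaminants(ids, EMPTY_LIT, 0.5) == ids


def test_remove_contaminants_by_frequency():
    crap = ProteinList(
        name="crap", members=frozenset({"B", "C"}), frequency={"B": 0.6, "C": 0.3}
    )
    assert remove_contaminants({"A", "B", "C"}, crap, 0.5) == {"A", "C"}


def test_remove_contaminants_threshold_zero_removes_all_listed():
    crap = ProteinList(
        name="crap", members=frozenset({"B", "C"}), frequency={"B": 0.6, "C": 0.3}
    )
    assert remove_contaminants({"A", "B", "C"}, crap, 0.0) == {"A"}


def test_unlisted_frequency_defaults_to_one():
    crap = ProteinList(name="crap", members=frozenset({"B"}))
    assert remove_contaminants({"A", "B"}, crap, 1.0) == {"A"}


# --- tiers -----------------------------------------------------------------

@pytest.mark.parametrize(
    "fold, maxp, reps, tier",
    [
        (136.0, 1.0, 3, Tier.PLATINUM),
        (6.0, 0.92, 1, Tier.GOLD),
        (3.0, 0.69, 3, Tier.BRONZE),   # fails the Silver MaxP bound
        (4.0, 0.8, 2, Tier.SILVER),
        (8.0, 0.5, 3, Tier.BRONZE),    # high fold, weak score
        (1.5, 0.04, 3, Tier.BRONZE),
        (4.99, 0.95, 3, Tier.BRONZE),  # Silver needs maxp < 0.89
    ],
)
def test_tier_assignment(fold, maxp, reps, tier):
    p = make_profile(fold=fold, maxp=maxp, replicates=reps)
    assert assign_confidence_tier(p, CFG) is tier


@settings(derandomize=True, max_examples=100)
@given(
    fold=st.floats(0.1, 200.0),
    maxp=st.floats(0.0, 1.0),
    reps=st.integers(0, 3),
)
def test_tiering_is_total_and_exclusive(fold, maxp, reps):
    p = make_profile(fold=fold, maxp=maxp, replicates=reps)
    tier = assign_confidence_tier(p, CFG)
    assert tier in {Tier.PLATINUM, Tier.GOLD, Tier.SILVER, Tier.BRONZE}


# --- literature merge ------------------------------------------------------

def _screen(n):
    return [
        InteractomeMember(
            prey_id=f"S{i}", gene_symbol=f"S{i}",
            provenance=Provenance.SCREEN, tier=Tier.BRONZE,
        )
        for i in range(n)
    ]


def test_merge_disjoint_counts():
    lit = ProteinList(name="lit", members=frozenset(f"L{i}" for i in range(31)))
    merged = merge_literature_partners(_screen(150), lit)
    assert len(merged) == 181
    assert len(merged.screen_members) == 150
    assert len(merged.literature_members) == 31


def test_merge_does_not_duplicate_screen_hits():
    lit = ProteinList(name="lit", members=frozenset({"S0", "L1", "L2"}))
    merged = merge_literature_partners(_screen(150), lit)
    assert len(merged) == 152
    s0 = [m for m in merged.members if m.identity == "S0"]
    assert len(s0) == 1 and s0[0].provenance is Provenance.SCREEN


def test_merge_empty_literature_is_identity():
    merged = merge_literature_partners(_screen(5), EMPTY_LIT)
    assert len(merged) == 5


def test_literature_member_invariant():
    with pytest.raises(ValidationError):
        InteractomeMember(
            prey_id="L", gene_symbol="L",
            provenance=Provenance.LITERATURE, tier=Tier.GOLD,
        )


def test_build_screen_members_tiers_every_admitted_prey():
    profiles = [make_profile(prey=f"P{i}", fold=2 + i, maxp=0.5) for i in range(5)]
    members = build_screen_members(profiles, {"P1", "P3"}, CFG)
    assert {m.prey_id for m in members} == {"P1", "P3"}
    assert all(m.tier is not Tier.NA_LITERATURE for m in members)
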