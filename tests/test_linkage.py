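"""Deterministic linkage: keys, exclusions, oracle equivalence, first episodes."""

import pytest
from hypothesis import given, settings, strategies as st

import amivalid as av
from amivalid.linkage import CHART_SIDE, CLAIMS_SIDE, KeyParseError, build_key


def claims(rid, birth="1940-01-02", sex="M", adm="2008-03-01", dis="2008-03-09", pid=None):
    return av.ClaimsEncounter(
        record_id=rid, patient_id=pid, birth_date=birth, sex=sex,
        admission_date=adm, discharge_date=dis, diagnoses=("410.11",),
    )


def chart(rid, birth="1940-01-02", sex="M", adm="2008-03-01", dis="2008-03-09", pid=None):
    return av.ChartEncounter(
        record_id=rid, patient_id=pid, birth_date=birth, sex=sex,
        admission_date=adm, discharge_date=dis, diagnoses=("410.11",),
    )


class TestBuildKey:
    def test_complete_key(self):
        key = build_key(claims("r1"))
        assert key is not None and key.sex == "M"

    def test_blank_field_yields_missing_marker(self):
        assert build_key(claims("r1", sex="")) is None
        assert build_key(claims("r1", birth=None)) is None

    def test_malformed_date_names_row_and_column(self):
        with pytest.raises(KeyParseError, match="r1.*admission_date"):
            build_key(claims("r1", adm="2008-13-40"))

    def test_admission_after_discharge_rejected(self):
        with pytest.raises(KeyParseError, match="after discharge"):
            build_key(claims("r1", adm="2008-03-10", dis="2008-03-01"))

    @pytest.mark.parametrize("raw,expected", [("male", "M"), ("2", "F"), ("f", "F"), ("1", "M")])
    def test_sex_normalization(self, raw, expected):
        assert build_key(claims("r1", sex=raw)).sex == expected


class TestLinkRecords:
    def test_all_unique_and_equal(self):
        cs = [claims(f"c{i}", adm=f"2008-03-0{i}") for i in range(1, 4)]
        hs = [chart(f"h{i}", adm=f"2008-03-0{i}") for i in range(1, 4)]
        result = av.link_records(cs, hs)
        assert len(result.linked) == 3
        assert result.linkage_rate == 1.0

    def test_shared_key_excludes_all_bearers(self):
        cs = [claims("c1"), claims("c2")]  # same key
        hs = [chart("h1")]
        result = av.link_records(cs, hs)
        assert result.linked == []
        assert sorted(result.excluded_ambiguous) == [(CLAIMS_SIDE, "c1"), (CLAIMS_SIDE, "c2")]
        assert result.unmatched == [(CHART_SIDE, "h1")]

    def test_missing_key_excluded(self):
        result = av.link_records([claims("c1", sex="")], [chart("h1")])
        assert result.excluded_missing == [(CLAIMS_SIDE, "c1")]

    def test_degenerate_empty_inputs(self):
        result = av.link_records([], [])
        assert result.linked == [] and result.linkage_rate is None


def brute_force_link(claims_list, charts_list):
    """Independent all-pairs comparator with the same exclusion semantics."""
    def key(r):
        return build_key(r)

    def classify(records, others_keys, own_keys):
        linked, ambiguous, missing, unmatched = set(), set(), set(), set()
        for r in records:
            k = key(r)
            if k is None:
                missing.add(r.record_id)
            elif own_keys.count(k) > 1:
                ambiguous.add(r.record_id)
            elif others_keys.count(k) == 1:
                linked.add(r.record_id)
            else:
                unmatched.add(r.record_id)
        return linked, ambiguous, missing, unmatched

    ckeys = [key(r) for r in claims_list if key(r) is not None]
    hkeys = [key(r) for r in charts_list if key(r) is not None]
    c = classify(claims_list, hkeys, ckeys)
    h = classify(charts_list, ckeys, hkeys)
    # a record is linked only when the counterpart key is also unique
    linked_pairs = set()
    for cl in claims_list:
        for ch in charts_list:
            kc, kh = key(cl), key(ch)
            if kc is not None and kc == kh and ckeys.count(kc) == 1 and hkeys.count(kh) == 1:
                linked_pairs.add((cl.record_id, ch.record_id))
    return linked_pairs, c, h


# key pools small enough to force collisions and misses
_births = st.sampled_from(["1940-01-02", "1950-06-07", None])
_sexes = st.sampled_from(["M", "F", None])
_adms = st.sampled_from(["2008-03-01", "2008-05-02"])

record_st = st.tuples(_births, _sexes, _adms)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(record_st, max_size=8), st.lists(record_st, max_size=8))
def test_link_matches_brute_force_oracle(claims_spec, charts_spec):
    cs = [claims(f"c{i}", birth=b, sex=s, adm=a, dis="2008-08-09") for i, (b, s, a) in enumerate(claims_spec)]
    hs = [chart(f"h{i}", birth=b, sex=s, adm=a, dis="2008-08-09") for i, (b, s, a) in enumerate(charts_spec)]
    result = av.link_records(cs, hs)
    linked_pairs, (cl, ca, cm, cu), (hl, ha, hm, hu) = brute_force_link(cs, hs)

    assert {(c.claims.record_id, c.chart.record_id) for c in result.linked} == linked_pairs
    assert {rid for side, rid in result.excluded_ambiguous if side == CLAIMS_SIDE} == ca
    assert {rid for side, rid in result.excluded_ambiguous if side == CHART_SIDE} == ha
    assert {rid for side, rid in result.excluded_missing if side == CLAIMS_SIDE} == cm
    assert {rid for side, rid in result.excluded_missing if side == CHART_SIDE} == hm
    assert {rid for side, rid in result.unmatched if side == CLAIMS_SIDE} == cu - cl
    assert {rid for side, rid in result.unmatched if side == CHART_SIDE} == hu - hl

    # partition: every input record lands in exactly one bucket, per side
    for side, records in ((CLAIMS_SIDE, cs), (CHART_SIDE, hs)):
        n_linked = len(result.linked)
        n_other = sum(1 for s, _ in result.excluded_ambiguous + result.excluded_missing + result.unmatched if s == side)
        assert n_linked + n_other == len(records)

    # symmetry: swapping the tables preserves the linked key-pair set
    swapped = av.link_records(
        [claims(h.record_id, birth=h.birth_date, sex=h.sex, adm=h.admission_date, dis=h.discharge_date) for h in hs],
        [chart(c.record_id, birth=c.birth_date, sex=c.sex, adm=c.admission_date, dis=c.discharge_date) for c in cs],
    )
    assert {(c.chart.record_id, c.claims.record_id) for c in swapped.linked} == linked_pairs


def test_zero_hazard_generator_links_perfectly():
    cfg = av.GeneratorConfig(
        n_patients=300, seed=11, p_missing_key=0, n_collision_pairs=0,
        n_repeat_admissions=0, n_misplaced_charts=0,
    )
    cohort = av.generate_cohort(cfg)
    assert av.link_records(cohort.claims, cohort.charts).linkage_rate == 1.0


def test_study_shaped_cohort_reproduces_linkage_rate(study_cohort):
    result = av.link_records(study_cohort.claims, study_cohort.charts)
    assert len(result.linked) == 341
    assert result.n_claims_input == 351
    assert result.linkage_rate == pytest.approx(341 / 351)


class TestFirstEpisode:
    def _case(self, cid, pid, adm):
        return av.LinkedCase(
            case_id=cid,
            claims=claims(cid, adm=adm, dis="2008-12-30", pid=pid),
            chart=chart("h" + cid, adm=adm, dis="2008-12-30", pid=pid),
        )

    def test_keeps_earliest_admission(self):
        cases = [self._case("a", "p1", "2008-07-15"), self._case("b", "p1", "2008-02-01")]
        kept, repeats = av.select_first_episode(cases)
        assert [c.case_id for c in kept] == ["b"]
        assert repeats == [("b", "a")]

    def test_single_episode_patients_unchanged(self):
        cases = [self._case(f"c{i}", f"p{i}", "2008-03-01") for i in range(4)]
        kept, repeats = av.select_first_episode(cases)
        assert kept == cases and repeats == []

    def test_toy_cohort_accounting(self):
        cases = [self._case(f"c{i}", f"p{i}", "2008-03-01") for i in range(5)]
        cases.append(self._case("c5", "p0", "2008-06-01"))
        cases.append(self._case("c6", "p3", "2008-09-01"))
        kept, repeats = av.select_first_episode(cases)
        assert len(kept) == 5 and len(repeats) == 2

    def test_tie_is_an_error_unless_told_otherwise(self):
        cases = [self._case("b", "p1", "2008-02-01"), self._case("a", "p1", "2008-02-01")]
        with pytest.raises(av.FirstEpisodeTieError, match="p1"):
            av.select_first_episode(cases)
        kept, repeats = av.select_first_episode(cases, tie_keep_one=True)
        assert [c.case_id for c in kept] == ["a"] and repeats == [("a", "b")]
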