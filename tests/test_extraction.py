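"""Mention finding, unit inference, mistranscription checks, assembly."""
import pytest

from forumlab.extraction import (
    assemble_test_sets,
    check_mistranscription,
    compute_derived,
    convert_unit,
    extract_observations,
    find_mentions,
    infer_unit,
    resolve_mention,
)
from forumlab.types import ForumPost, Rejection
from conftest import make_obs


def _post(body, title="labs", pid="p1", author="u1", utc=1577836800):
    return ForumPost(id=pid, author=author, created_utc=utc, title=title,
                     selftext=body)


class TestFindMentions:
    def test_two_plain_mentions(self, catalog):
        ms = find_mentions(_post("FSH 5.5, LH 12"), catalog)
        got = {(m.test_id, m.value, m.unit) for m in ms}
        assert got == {("fsh", 5.5, None), ("lh", 12.0, None)}

    def test_distractor_empty(self, catalog):
        ms = find_mentions(
            _post("Has anyone tried inositol? My acne is awful."), catalog
        )
        assert ms == []

    def test_unit_captured_and_normalized(self, catalog):
        (m,) = find_mentions(_post("My DHEA-S came back at 328 mcg/dl"), catalog)
        assert (m.test_id, m.value, m.unit) == ("dheas", 328.0, "ug/dL")

    def test_ratio_beats_component_on_overlap(self, catalog):
        (m,) = find_mentions(_post("LH/FSH: 2.2"), catalog)
        assert m.test_id == "lh_fsh" and m.value == 2.2

    def test_longest_synonym_wins(self, catalog):
        (m,) = find_mentions(_post("free testosterone was 5.9 pg/mL"), catalog)
        assert m.test_id == "free_t"

    def test_word_after_number_is_not_a_unit(self, catalog):
        (m,) = find_mentions(_post("my LH was 12 and I cried"), catalog)
        assert m.unit is None

    def test_synthetic_corpus_mentions_recovered(self, catalog, small_corpus):
        """>=95% of embedded (test, value) pairs are found as raw mentions."""
        posts, truth = small_corpus
        total = hit = 0
        for post in posts:
            found = {(m.test_id, m.value) for m in find_mentions(post, catalog)}
            for m in truth.posts[post.id]:
                total += 1
                if (m.test_id, m.rendered_value) in found:
                    hit += 1
        assert total > 500
        assert hit / total >= 0.95


class TestConvertUnit:
    def test_dheas_micromolar(self, catalog):
        # 8.9 umol/L is the top of the healthy range, 328 ug/dL
        assert convert_unit("dheas", 8.9, "umol/L", catalog) == pytest.approx(
            328, abs=0.5
        )

    def test_canonical_identity(self, catalog):
        assert convert_unit("fsh", 5.5, "U/L", catalog) == 5.5

    def test_glucose_molar_mass(self, catalog):
        assert convert_unit("fpg", 5.0, "mmol/L", catalog) == pytest.approx(
            90.1, abs=0.05
        )


class TestMistranscription:
    def test_high_testosterone_accepted(self, catalog):
        # abnormally high, but reasonable for the condition
        assert check_mistranscription("total_t", 90, "ng/dL", catalog).kind == "accept"

    def test_dheas_unit_swap_reinterpreted(self, catalog):
        v = check_mistranscription("dheas", 8, "ug/dL", catalog)
        assert v.kind == "reinterpret" and v.unit == "umol/L"

    def test_negative_value_rejected(self, catalog):
        assert check_mistranscription("fsh", -3, "U/L", catalog).kind == "reject"

    def test_absurd_value_rejected(self, catalog):
        assert check_mistranscription("fsh", 9e9, "U/L", catalog).kind == "reject"


class TestInferUnit:
    def test_unitless_plausible_only_canonically(self, catalog):
        status, value, uncertain = infer_unit("total_t", 90, None, catalog)
        assert (status, value, uncertain) == ("ok", 90, False)

    def test_overlapping_ranges_flag_uncertain(self, catalog):
        # 15 is plausible for progesterone both as ng/mL and as nmol/L
        # (4.7 ng/mL); the readings disagree by far more than 20%
        status, value, uncertain = infer_unit("p", 15, None, catalog)
        assert status == "ok" and uncertain
        assert value == 15  # canonical reading preferred

    def test_explicit_canonical_unit_confident(self, catalog):
        assert infer_unit("fsh", 5.5, "U/L", catalog) == ("ok", 5.5, False)

    def test_rejection_is_returned_not_dropped(self, catalog):
        from forumlab.types import RawMention

        mention = RawMention(
            post_id="p", account_id="u", post_day="2020-01-01", test_id="fsh",
            matched_text="fsh -3", value=-3.0, unit="U/L", span=(0, 6),
        )
        assert isinstance(resolve_mention(mention, catalog), Rejection)

    def test_widening_admits_borderline_values(self, catalog):
        lo = catalog["fsh"].plausible[0]
        status, _, _ = infer_unit("fsh", lo * 0.8, "U/L", catalog)
        status_wide, _, _ = infer_unit("fsh", lo * 0.8, "U/L", catalog, widen=1.5)
        assert status == "reject" and status_wide == "ok"


class TestAssembly:
    def test_same_day_split_posts_merge(self):
        obs = [
            make_obs("fsh", 5.5, post_id="a"),
            make_obs("lh", 12.0, post_id="b"),
        ]
        (ts,) = assemble_test_sets(obs)
        assert ts.has("fsh") and ts.has("lh")

    def test_cross_day_duplicate_dropped(self):
        obs = [
            make_obs("fsh", 5.5, test_day="2020-01-01"),
            make_obs("fsh", 5.5, test_day="2020-02-01"),
        ]
        sets = assemble_test_sets(obs)
        assert len(sets) == 1 and sets[0].test_day == "2020-01-01"

    def test_different_values_both_days_kept(self):
        obs = [
            make_obs("fsh", 5.5, test_day="2020-01-01"),
            make_obs("fsh", 7.1, test_day="2020-02-01"),
        ]
        assert len(assemble_test_sets(obs)) == 2

    def test_same_day_conflict_flagged(self):
        obs = [
            make_obs("fsh", 5.5, post_id="a"),
            make_obs("fsh", 9.9, post_id="b"),
        ]
        (ts,) = assemble_test_sets(obs)
        assert ts.needs_reprocess
        assert len(ts.observations) == 2  # both kept for reprocessing

    def test_empty_input(self):
        assert assemble_test_sets([]) == []

    def test_idempotence(self, catalog, small_corpus):
        posts, _ = small_corpus
        obs, _, notes = extract_observations(posts, catalog)
        once = assemble_test_sets(obs, notes)
        flattened = [o for ts in once for o in ts.observations]
        twice = assemble_test_sets(flattened, notes)
        key = lambda sets: sorted(
            (ts.account_id, ts.test_day,
             tuple(sorted((o.test_id, o.value) for o in ts.observations)))
            for ts in sets
        )
        assert key(once) == key(twice)

    def test_demographics_populate_fields(self):
        obs = [make_obs("age", 27), make_obs("bmi", 24.4), make_obs("fsh", 5.0)]
        (ts,) = assemble_test_sets(obs)
        assert ts.age == 27 and ts.bmi == 24.4


class TestDerived:
    def test_lh_fsh_ratio(self):
        (ts,) = assemble_test_sets([make_obs("lh", 12.0), make_obs("fsh", 6.0)])
        compute_derived(ts)
        assert ts.value_of("lh_fsh") == pytest.approx(2.0)

    def test_homa_ir(self):
        (ts,) = assemble_test_sets([make_obs("fi", 12.0), make_obs("fpg", 90.0)])
        compute_derived(ts)
        assert ts.value_of("homa_ir") == pytest.approx(12 * 90 / 405)

    def test_missing_operand_no_index(self):
        (ts,) = assemble_test_sets([make_obs("fi", 12.0)])
        compute_derived(ts)
        assert not ts.has("homa_ir")

    def test_posted_value_never_overwritten(self):
        (ts,) = assemble_test_sets(
            [make_obs("lh", 12.0), make_obs("fsh", 6.0), make_obs("lh_fsh", 1.7)]
        )
        compute_derived(ts)
        assert ts.value_of("lh_fsh") == 1.7

    def test_zero_fsh_omits_ratio(self):
        (ts,) = assemble_test_sets([make_obs("lh", 12.0), make_obs("fsh", 0.0)])
        compute_derived(ts)
        assert not ts.has("lh_fsh")


def test_no_surviving_value_outside_plausible_unless_uncertain(
    catalog, small_corpus
):
    posts, _ = small_corpus
    obs, _, _ = extract_observations(posts, catalog)
    for o in obs:
        entry = catalog[o.test_id]
        if not o.uncertain:
            assert entry.plausible[0] <= o.value <= entry.plausible[1]
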