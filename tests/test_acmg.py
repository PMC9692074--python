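"""Five-tier classification engine vs an independent rule-table oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import carrierscope as cs
from carrierscope.acmg import (
    Category,
    Criterion,
    EvidenceProfile,
    Strength,
    classify_clinvar_label,
    classify_hgmd_label,
    combine_criteria,
    native_strength,
)

ALL_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


def oracle(codes_with_strengths):
    """Independent brute-force classification over the combining-rule table.

    Re-derives the category from strength tallies with an explicit list of
    satisfying count patterns, written separately from the engine.
    """
    vs = s = m = p = 0
    ba = bs = bp = 0
    for code, strength in codes_with_strengths:
        benign = code.startswith("B")
        if benign:
            if strength == "stand-alone":
                ba += 1
            elif strength in ("very-strong", "strong"):
                bs += 1
            else:
                bp += 1
        else:
            if strength in ("stand-alone", "very-strong"):
                vs += 1
            elif strength == "strong":
                s += 1
            elif strength == "moderate":
                m += 1
            else:
                p += 1
    if vs > 1:
        s, vs = s + vs - 1, 1

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely = not pathogenic and (
        (vs >= 1 and m == 1)
        or (s == 1 and (1 <= m <= 2 or p >= 2))
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign_cat = None
    if ba or bs >= 2:
        benign_cat = "B"
    elif (bs == 1 and bp >= 1) or bp >= 2:
        benign_cat = "LB"

    path_cat = "P" if pathogenic else ("LP" if likely else None)
    has_path_evidence = (vs + s + m + p) > 0
    if path_cat and benign_cat:
        return "VUS"
    if benign_cat == "B" and ba and has_path_evidence:
        return "VUS"
    if path_cat:
        return path_cat
    if benign_cat:
        return benign_cat
    return "VUS"


_SHORT = {
    Category.PATHOGENIC: "P",
    Category.LIKELY_PATHOGENIC: "LP",
    Category.VUS: "VUS",
    Category.LIKELY_BENIGN: "LB",
    Category.BENIGN: "B",
}


def engine_short(profile):
    return _SHORT[combine_criteria(profile).category]


class TestCombineCriteria:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ((), Category.VUS),                      # no evidence
            (("PVS1", "PS2"), Category.PATHOGENIC),
            (("PM2", "PP3"), Category.VUS),          # no rule fires
            (("BA1", "PM2"), Category.VUS),          # conflicting evidence
            (("PVS1", "PM2"), Category.LIKELY_PATHOGENIC),
            (("PS3", "PM2", "PP3"), Category.LIKELY_PATHOGENIC),
            (("PVS1", "PM2", "PP5"), Category.PATHOGENIC),
            (("BA1",), Category.BENIGN),
            (("BS1", "BS2"), Category.BENIGN),
            (("BS1", "BP1"), Category.LIKELY_BENIGN),
            (("BP1", "BP4"), Category.LIKELY_BENIGN),
            (("PVS1", "BS1", "BS2"), Category.BENIGN),   # lone PVS1 fires no rule
            (("PVS1", "PS1", "BS1", "BS2"), Category.VUS),  # both sides fire
        ],
    )
    def test_rule_table_examples(self, codes, expected):
        profile = EvidenceProfile.from_codes(*codes)
        assert combine_criteria(profile).category is expected

    def test_no_evidence_fires_default_rule(self):
        call = combine_criteria(EvidenceProfile())
        assert call.category is Category.VUS
        assert call.rule_fired == "default-VUS"

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="PX9"):
            EvidenceProfile.from_codes("PX9")

    def test_duplicate_base_code_rejected(self):
        with pytest.raises(ValueError, match="more than once"):
            EvidenceProfile(
                frozenset({Criterion("PM2"), Criterion("PM2", Strength.STRONG)})
            )

    def test_engine_matches_oracle_on_all_small_profiles(self):
        """Exhaustive agreement with the independent oracle on every
        profile of up to 4 criteria at native strengths."""
        for size in range(5):
            for combo in itertools.combinations(ALL_CODES, size):
                profile = EvidenceProfile.from_codes(*combo)
                expected = oracle(
                    [(c, native_strength(c).value) for c in combo]
                )
                assert engine_short(profile) == expected, combo

    def test_strength_modification_counts_applied_level(self):
        downgraded = EvidenceProfile(
            frozenset({Criterion("PVS1", Strength.STRONG), Criterion("PS1")})
        )
        reference = EvidenceProfile.from_codes("PS1", "PS2")
        assert (
            combine_criteria(downgraded).category
            is combine_criteria(reference).category
        )


criteria_strategy = st.lists(
    st.sampled_from(ALL_CODES), unique=True, max_size=8
).map(
    lambda codes: EvidenceProfile.from_codes(*codes)
)

modified_criteria_strategy = st.lists(
    st.tuples(
        st.sampled_from(ALL_CODES),
        st.sampled_from([None, *Strength]),
    ),
    unique_by=lambda t: t[0],
    max_size=8,
).map(
    lambda pairs: EvidenceProfile(
        frozenset(Criterion(c, s) for c, s in pairs)
    )
)


class TestEngineProperties:
    @settings(max_examples=300, derandomize=True)
    @given(modified_criteria_strategy)
    def test_totality(self, profile):
        """Every profile, including arbitrary applied strengths, yields
        exactly one of the five categories."""
        call = combine_criteria(profile)
        assert call.category in Category
        assert call.rule_fired

    @settings(max_examples=300, derandomize=True)
    @given(criteria_strategy)
    def test_matches_oracle_on_random_profiles(self, profile):
        expected = oracle(
            [(c.code, c.strength.value) for c in profile.criteria]
        )
        assert engine_short(profile) == expected

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.sampled_from([c for c in ALL_CODES if c.startswith("P")]),
            unique=True, min_size=1, max_size=7,
        ),
        st.data(),
    )
    def test_pathogenic_calls_are_monotone(self, codes, data):
        """Adding pathogenic-side evidence never demotes a Pathogenic call
        when no benign evidence is present."""
        profile = EvidenceProfile.from_codes(*codes)
        if combine_criteria(profile).category is not Category.PATHOGENIC:
            return
        remaining = [c for c in ALL_CODES if c.startswith("P") and c not in codes]
        extra = data.draw(st.sampled_from(remaining))
        bigger = EvidenceProfile.from_codes(*codes, extra)
        assert combine_criteria(bigger).category is Category.PATHOGENIC


class TestLabelSources:
    @pytest.mark.parametrize(
        "label,pathogenic",
        [
            ("Pathogenic", True),
            ("likely pathogenic", True),
            ("Pathogenic/Likely pathogenic", True),
            ("Likely_pathogenic", True),
            ("  PATHOGENIC  ", True),
            ("Benign", False),
            ("Uncertain significance", False),
            ("Conflicting interpretations", False),
        ],
    )
    def test_clinvar_label_mapping(self, label, pathogenic):
        assert classify_clinvar_label(label).is_pathogenic is pathogenic

    @pytest.mark.parametrize(
        "label,pathogenic",
        [("DM", True), ("DM?", False), ("DP", False), ("DFP", False), ("R", False)],
    )
    def test_hgmd_only_exact_dm(self, label, pathogenic):
        assert classify_hgmd_label(label).is_pathogenic is pathogenic


class TestClassifyPanel:
    def test_bundled_panel_all_pathogenic_under_acmg(self, panel):
        calls = cs.classify_panel(panel, "acmg2015")
        assert len(calls) == 19
        assert all(c.is_pathogenic for c in calls.values())

    def test_select_pathogenic_korean_restriction(self, pathogenic_panel, korean):
        assert len(pathogenic_panel) == 19
        korean_subset = cs.subset_population(pathogenic_panel, korean)
        assert len(korean_subset) == 7

    def test_benign_clinvar_record_excluded(self):
        rec = cs.VariantRecord(
            gene="PRF1", hgvs_c="c.1A>G", annotations={"clinvar": "Benign"},
        )
        calls = cs.classify_panel([rec], "clinvar")
        assert cs.select_pathogenic([rec], calls) == []

    def test_all_vus_panel_selects_nothing(self):
        recs = [
            cs.VariantRecord(
                gene="PRF1", hgvs_c=f"c.{i}A>G",
                evidence=EvidenceProfile.from_codes("PM2"),
            )
            for i in range(3)
        ]
        calls = cs.classify_panel(recs, "acmg2015")
        assert cs.select_pathogenic(recs, calls) == []

    def test_missing_source_errors_name_variants(self):
        rec = cs.VariantRecord(gene="PRF1", hgvs_c="c.5A>G")
        with pytest.raises(ValueError, match="PRF1:c.5A>G"):
            cs.classify_panel([rec], "acmg2015")
        with pytest.raises(ValueError, match="PRF1:c.5A>G"):
            cs.classify_panel([rec], "hgmd")

    def test_unknown_source_rejected(self, panel):
        with pytest.raises(ValueError, match="unknown classification source"):
            cs.classify_panel(panel, "acmgXXXX")
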