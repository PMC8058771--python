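import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    naive_scores,
    random_features_params,
    random_labels,
    random_scheme_params,
)
from fuse import (
    AlignmentFeatures,
    ComparisonLabel,
    PairDomainComparison,
    ScoringScheme,
    alignment_components,
    discovery_score,
    knowledge_score,
    load_scheme,
    score_all_pairs,
)

TOOLS = ("Pfam", "SMART", "PANTHER")


def features(pident=100.0, aln=100, gaps=0, len_a=100, len_b=100):
    return AlignmentFeatures("A", "B", pident, aln, gaps, len_a, len_b)


def comparison(labels: dict[str, str]) -> PairDomainComparison:
    tools = tuple(labels)
    return PairDomainComparison(
        "A", "B", tuple(ComparisonLabel(v) for v in labels.values()), tools
    )


def scheme_from(params: dict) -> ScoringScheme:
    return ScoringScheme(**params)


class TestLoadScheme:
    def test_empty_config_gives_documented_defaults(self):
        s = load_scheme()
        assert s.identity_weight == 100
        assert s.coverage_weight == 50
        assert s.gap_weight == -50
        assert s.tool_label_weights["Pfam"] == {
            "STONM": 10.0,
            "STNM": 6.0,
            "STM": 3.0,
            "NM": 0.0,
        }
        assert len(s.tools) == 14

    def test_positive_gap_weight_rejected(self):
        with pytest.raises(ValueError, match="gap_weight"):
            load_scheme({"gap_weight": 5})

    def test_label_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="STONM >= STNM"):
            load_scheme(
                {"tool_label_weights": {"Pfam": {"STNM": 11.0}}}
            )

    def test_yaml_file_overrides(self, tmp_path):
        cfg = tmp_path / "scheme.yaml"
        cfg.write_text("identity_weight: 80\ngap_weight: -10\n")
        s = load_scheme(cfg)
        assert (s.identity_weight, s.gap_weight) == (80, -10)


class TestAlignmentComponents:
    def test_perfect_self_alignment(self, default_scheme):
        assert alignment_components(features(), default_scheme) == (100.0, 0.0, 0.0)

    def test_short_alignment_penalized_by_coverage(self, default_scheme):
        ais, acs, ags = alignment_components(
            features(pident=90, aln=50), default_scheme
        )
        assert ais == 90
        assert acs == pytest.approx(0.5 * ((100 - 200) + (100 - 200)))
        assert ags == 0

    def test_gap_component(self, default_scheme):
        _, _, ags = alignment_components(features(gaps=4), default_scheme)
        assert ags == pytest.approx(-2.0)


class TestDiscoveryScore:
    def test_perfect_self_alignment_is_100(self, default_scheme):
        assert discovery_score(features(), default_scheme) == 100.0

    def test_negative_raw_score_clamped_to_zero(self, default_scheme):
        # components (90, -100, 0) -> raw -10 -> 0
        assert discovery_score(features(pident=90, aln=50), default_scheme) == 0.0

    def test_components_sum_normalized(self, default_scheme):
        # AIS 95, ACS -2, AGS -1 under defaults
        f = features(pident=95, aln=100, len_a=102, len_b=102, gaps=2)
        assert discovery_score(f, default_scheme) == pytest.approx(92.0)


class TestKnowledgeScore:
    def test_identical_proteins_with_annotations_score_100(self, default_scheme):
        c = comparison({t: "STONM" for t in TOOLS})
        assert knowledge_score(features(), c, default_scheme) == 100.0

    def test_all_np_falls_back_to_ds(self, default_scheme):
        f = features(pident=87.5)
        c = comparison({t: "NP" for t in TOOLS})
        assert knowledge_score(f, c, default_scheme) == discovery_score(
            f, default_scheme
        )

    def test_single_stnm_tool_example(self, default_scheme):
        # base 92 plus STNM weight 6 over denominator 100 + 10
        f = features(pident=95, aln=100, len_a=102, len_b=102, gaps=2)
        c = comparison({"Pfam": "STNM"})
        assert knowledge_score(f, c, default_scheme) == pytest.approx(9800 / 110)


class TestOracleEquivalence:
    def test_scalar_path_matches_straight_line_oracle(self):
        """1,000 random (features, labels, scheme) triples agree to 1e-9."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            sp = random_scheme_params(rng, TOOLS)
            fp = random_features_params(rng)
            labels = random_labels(rng, TOOLS)
            ds, ks = naive_scores(**fp, labels=labels, **sp)
            f = features(**{
                "pident": fp["pident"], "aln": fp["aln_length"],
                "gaps": fp["gap_count"], "len_a": fp["len_a"],
                "len_b": fp["len_b"],
            })
            s = scheme_from(sp)
            assert discovery_score(f, s) == pytest.approx(ds, abs=1e-9)
            assert knowledge_score(f, comparison(labels), s) == pytest.approx(
                ks, abs=1e-9
            )

    def test_vectorized_path_matches_straight_line_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sp = random_scheme_params(rng, TOOLS)
            s = scheme_from(sp)
            rows, expected = [], []
            for i in range(20):
                fp = random_features_params(rng)
                labels = random_labels(rng, TOOLS)
                expected.append(naive_scores(**fp, labels=labels, **sp))
                row = {"id_a": f"A{i}", "id_b": f"B{i}", **fp}
                rows.append((row, labels))
            feats = pd.DataFrame([r for r, _ in rows])
            comps = pd.DataFrame(
                [{"id_a": r["id_a"], "id_b": r["id_b"], **lab} for r, lab in rows]
            )
            out = score_all_pairs(feats, comps, s)
            got = out.set_index("id_a")
            for (row, _), (ds, ks) in zip(rows, expected):
                assert got.loc[row["id_a"], "DS"] == pytest.approx(ds, abs=1e-9)
                assert got.loc[row["id_a"], "KS"] == pytest.approx(ks, abs=1e-9)


@st.composite
def valid_schemes(draw):
    weights = {}
    for tool in TOOLS:
        vals = sorted(
            draw(
                st.lists(
                    st.floats(0, 50, allow_nan=False), min_size=4, max_size=4
                )
            ),
            reverse=True,
        )
        weights[tool] = dict(zip(("STONM", "STNM", "STM", "NM"), vals))
    return ScoringScheme(
        identity_weight=draw(st.floats(1, 500, allow_nan=False, exclude_min=True)),
        coverage_weight=draw(st.floats(0, 200, allow_nan=False)),
        gap_weight=-draw(st.floats(0, 200, allow_nan=False)),
        tool_label_weights=weights,
    )


class TestScoreProperties:
    @settings(deadline=None, max_examples=200)
    @given(scheme=valid_schemes())
    def test_identity_bound_for_any_valid_scheme(self, scheme):
        """Identical sequences + identical annotations give exactly 100."""
        f = features()  # self-alignment: pident 100, full coverage, no gaps
        c = comparison({t: "STONM" for t in TOOLS})
        assert discovery_score(f, scheme) == 100.0
        assert knowledge_score(f, c, scheme) == 100.0

    @settings(deadline=None, max_examples=100)
    @given(
        scheme=valid_schemes(),
        pident=st.floats(0, 100, allow_nan=False),
        gaps=st.integers(0, 8),
    )
    def test_all_np_gives_ks_equal_ds(self, scheme, pident, gaps):
        f = features(pident=pident, gaps=gaps, aln=120, len_a=110, len_b=115)
        c = comparison({t: "NP" for t in TOOLS})
        assert knowledge_score(f, c, scheme) == discovery_score(f, scheme)

    def test_label_upgrade_never_decreases_ks(self, default_scheme):
        ladder = ["NM", "STM", "STNM", "STONM"]
        f = features(pident=90, aln=110, len_a=100, len_b=105, gaps=1)
        for tool in TOOLS:
            previous = None
            for lab in ladder:
                labels = {t: "STM" for t in TOOLS}
                labels[tool] = lab
                ks = knowledge_score(f, comparison(labels), default_scheme)
                if previous is not None:
                    assert ks >= previous - 1e-12
                previous = ks

    def test_adding_np_tool_leaves_ks_unchanged(self, default_scheme):
        f = features(pident=92, aln=105, len_a=100, len_b=100, gaps=1)
        base = {t: "STNM" for t in TOOLS}
        with_np = dict(base, SMART="NP")
        without = {t: lab for t, lab in with_np.items() if t != "SMART"}
        assert knowledge_score(
            f, comparison(with_np), default_scheme
        ) == pytest.approx(
            knowledge_score(f, comparison(without), default_scheme), abs=1e-12
        )


class TestScoreAllPairs:
    def test_one_row_per_aligned_pair(self, default_scheme):
        feats = pd.DataFrame(
            [
                {"id_a": "A", "id_b": "B", "pident": 99.0, "aln_length": 100,
                 "gap_count": 0, "len_a": 100, "len_b": 100},
                {"id_a": "A", "id_b": "C", "pident": 50.0, "aln_length": 100,
                 "gap_count": 0, "len_a": 100, "len_b": 100},
                {"id_a": "B", "id_b": "C", "pident": 50.0, "aln_length": 100,
                 "gap_count": 0, "len_a": 100, "len_b": 100},
            ]
        )
        out = score_all_pairs(feats, None, default_scheme)
        assert len(out) == 3
        assert set(zip(out["id_a"], out["id_b"])) == {
            ("A", "B"), ("A", "C"), ("B", "C"),
        }

    def test_pairs_without_comparison_rows_treated_as_all_np(self, default_scheme):
        feats = pd.DataFrame(
            [{"id_a": "A", "id_b": "B", "pident": 88.0, "aln_length": 100,
              "gap_count": 0, "len_a": 100, "len_b": 100}]
        )
        out = score_all_pairs(feats, None, default_scheme)
        assert out.loc[0, "KS"] == out.loc[0, "DS"]

    def test_within_family_ks_exceeds_between_family_ks(self, tmp_path):
        """Two planted families: every within-family KS beats every
        between-family KS (brute-force separation on the fixture)."""
        from fuse import (
            FixtureSpec,
            features_table,
            filter_by_biotype,
            load_scheme,
            make_fixture,
            parse_protein_fasta,
        )
        from fuse.domain_profiles import (
            build_profiles,
            compare_pair,
            comparisons_table,
            read_interpro_tsv,
        )

        spec = FixtureSpec(within_identity=98.0, between_identity=40.0, seed=5)
        paths, truth = make_fixture(spec, tmp_path)
        cat = filter_by_biotype(parse_protein_fasta(paths["proteins"]))
        feats = features_table(paths["blast"], cat)
        scheme = load_scheme()
        anns = read_interpro_tsv(paths["interpro"])
        ids = set(feats["id_a"]) | set(feats["id_b"])
        profiles = build_profiles(anns, ids)
        comps = comparisons_table(
            [
                compare_pair(profiles[a], profiles[b])
                for a, b in zip(feats["id_a"], feats["id_b"])
            ]
        )
        scores = score_all_pairs(feats, comps, scheme)
        fam = {p: p.split("_")[0] for p in ids}
        within = scores[
            [fam[a] == fam[b] for a, b in zip(scores["id_a"], scores["id_b"])]
        ]
        between = scores[
            [fam[a] != fam[b] for a, b in zip(scores["id_a"], scores["id_b"])]
        ]
        assert len(within) == 20 and len(between) == 25
        assert within["KS"].min() > between["KS"].max()
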