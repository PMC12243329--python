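"""Resource-matrix data model, I/O, cutoff, quality score and suitability."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from residueflow import (
    ANALYSIS_GRADES,
    CompositionProfile,
    FractionStat,
    GeneratorConfig,
    QualityMeta,
    ResourceMatrix,
    apply_potential_cutoff,
    generate_matrix,
    load_matrix,
    save_matrix,
    score_data_quality,
    suitability_summary,
)
from residueflow.resource_matrix import (
    MatrixFormatError,
    MatrixValidationError,
    RubricLevel,
    matrix_columns,
)

from conftest import make_matrix, make_residue


class TestDomainTypes:
    @pytest.mark.parametrize("bad", [{"min": -0.1}, {"mean": 1.3}, {"max": 2.0}])
    def test_fraction_values_must_lie_in_unit_interval(self, bad):
        with pytest.raises(MatrixValidationError):
            FractionStat(**bad)

    def test_fraction_ordering_enforced_where_present(self):
        with pytest.raises(MatrixValidationError):
            FractionStat(min=0.5, mean=0.3)
        FractionStat(min=0.1, max=0.9)  # mean may be absent

    def test_composition_requires_exactly_the_seven_fractions(self):
        with pytest.raises(MatrixValidationError):
            CompositionProfile({"lignin": FractionStat(mean=0.3)})
        with pytest.raises(MatrixValidationError):
            CompositionProfile.from_means(starch=0.3)

    def test_composition_sum_warns_then_errors(self):
        with pytest.warns(UserWarning):
            CompositionProfile.from_means(cellulose=0.6, nfc=0.5)  # 1.10
        with pytest.raises(MatrixValidationError):
            CompositionProfile.from_means(cellulose=0.7, nfc=0.6)  # 1.30

    def test_residue_invariants(self):
        with pytest.raises(MatrixValidationError):
            make_residue("a", -1.0, lignin=0.2)
        with pytest.raises(MatrixValidationError):
            make_residue("a", 1.0, usable=0.0, lignin=0.2)
        with pytest.raises(MatrixValidationError):
            QualityMeta(0, "detailed", 2020, 2025)
        with pytest.raises(MatrixValidationError):
            QualityMeta(1, "detailed", 2030, 2025)

    def test_matrix_rejects_duplicate_ids(self):
        r = make_residue("a", 1.0, lignin=0.2)
        with pytest.raises(MatrixValidationError):
            ResourceMatrix((r, r))


class TestIO:
    def test_bundled_matrix_loads_and_validates(self, ref_matrix):
        assert len(ref_matrix) == 20
        assert len(set(ref_matrix.ids)) == 20

    def test_header_only_file_gives_empty_matrix(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(matrix_columns()) + "\n")
        assert len(load_matrix(path)) == 0

    def test_out_of_range_fraction_is_rejected_with_row_diagnostics(self, tmp_path):
        matrix = make_matrix(make_residue("ok", 1e6, lignin=0.3))
        path = tmp_path / "m.csv"
        save_matrix(matrix, path)
        text = path.read_text().replace("0.3", "1.3")
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(MatrixValidationError, match="row 0"):
            load_matrix(bad)

    def test_non_numeric_potential_names_row_and_column(self, tmp_path):
        matrix = make_matrix(make_residue("ok", 1e6, lignin=0.3))
        path = tmp_path / "m.csv"
        save_matrix(matrix, path)
        bad = tmp_path / "bad.csv"
        bad.write_text(path.read_text().replace("1000000.0", "abc"))
        with pytest.raises(MatrixValidationError, match="technical_potential"):
            load_matrix(bad)

    def test_missing_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,name\n")
        with pytest.raises(MatrixFormatError, match="missing required columns"):
            load_matrix(path)

    def test_round_trip_identity_on_bundled_matrix(self, ref_matrix, tmp_path):
        path = tmp_path / "roundtrip.csv"
        save_matrix(ref_matrix, path)
        assert load_matrix(path) == ref_matrix

    def test_absent_values_survive_round_trip_unchanged(self, tmp_path):
        r = make_residue("a", 2e6, lignin=0.25)  # only lignin mean present
        path = tmp_path / "m.csv"
        save_matrix(make_matrix(r), path)
        loaded = load_matrix(path)
        stat = loaded.get("a").composition.fractions["cellulose"]
        assert stat.min is None and stat.mean is None and stat.max is None
        assert loaded.get("a").composition.fractions["lignin"].max is None

    def test_tab_delimiter_autodetected(self, tmp_path):
        matrix = make_matrix(make_residue("a", 1e6, lignin=0.3))
        path = tmp_path / "m.tsv"
        save_matrix(matrix, path)
        path.write_text(path.read_text().replace(",", "\t"))
        assert load_matrix(path) == matrix

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(0, 25))
    def test_round_trip_identity_on_generated_matrices(
        self, seed, n, tmp_path_factory
    ):
        matrix, _ = generate_matrix(GeneratorConfig(n_residues=n, seed=seed))
        path = tmp_path_factory.mktemp("gen") / f"gen-{seed}-{n}.csv"
        save_matrix(matrix, path)
        assert load_matrix(path) == matrix


class TestPotentialCutoff:
    def test_boundary_kept_at_geq(self):
        matrix = make_matrix(
            make_residue("a", 300_000, lignin=0.2),
            make_residue("b", 250_000, lignin=0.2),
            make_residue("c", 100_000, lignin=0.2),
        )
        kept = apply_potential_cutoff(matrix, 250_000)
        assert kept.ids == ("a", "b")

    def test_zero_cutoff_is_identity_and_negative_rejected(self, ref_matrix):
        assert apply_potential_cutoff(ref_matrix, 0.0) == ref_matrix
        with pytest.raises(ValueError):
            apply_potential_cutoff(ref_matrix, -1.0)

    def test_idempotent_and_brute_force_count_on_synthetic_portfolio(self):
        matrix, _ = generate_matrix(GeneratorConfig(n_residues=77, seed=11))
        cutoff = 2.0e6
        expected = sum(1 for r in matrix if r.technical_potential >= cutoff)
        kept = apply_potential_cutoff(matrix, cutoff)
        assert len(kept) == expected
        assert apply_potential_cutoff(kept, cutoff) == kept
        # order preserved, retained mass non-increasing in cutoff
        assert list(kept.ids) == [i for i in matrix.ids if i in set(kept.ids)]
        masses = [
            apply_potential_cutoff(matrix, c).total_technical_potential
            for c in (0.0, 1e6, 2e6, 4e6, 1e8)
        ]
        assert masses == sorted(masses, reverse=True)


class TestQualityScore:
    def test_recency_limits_an_otherwise_good_residue_to_sufficient(self):
        q = QualityMeta(3, "detailed_with_series", 2010, 2025)
        assert score_data_quality(q) == 3

    def test_worst_on_all_criteria_scores_not_reliable(self):
        q = QualityMeta(1, "unclear", 1985, 2025)
        assert score_data_quality(q) == 5

    def test_best_on_all_criteria_scores_good(self):
        q = QualityMeta(3, "detailed_with_series", 2024, 2025)
        assert score_data_quality(q) == 1

    def test_score_is_monotone_in_each_criterion_over_the_full_grid(self):
        sources = [1, 2, 3, 4]
        ages = list(range(0, 36))
        grid = {}
        for n, grade, age in itertools.product(sources, ANALYSIS_GRADES, ages):
            grid[(n, grade, age)] = score_data_quality(
                QualityMeta(n, grade, 2025 - age, 2025)
            )
        for (n, grade, age), level in grid.items():
            if n + 1 in sources:
                assert grid[(n + 1, grade, age)] <= level
            gi = ANALYSIS_GRADES.index(grade)
            if gi + 1 < len(ANALYSIS_GRADES):
                assert grid[(n, ANALYSIS_GRADES[gi + 1], age)] <= level
            if age - 1 >= 0:
                assert grid[(n, grade, age - 1)] <= level

    def test_unknown_grade_rejected_at_construction(self):
        with pytest.raises(MatrixValidationError):
            QualityMeta(2, "guessed", 2020, 2025)

    def test_non_monotone_custom_rubric_rejected(self):
        rubric = {
            1: RubricLevel(1, "unclear", 30),
            2: RubricLevel(3, "detailed", 5),  # stricter than level 1
        }
        with pytest.raises(ValueError, match="stricter"):
            score_data_quality(QualityMeta(2, "detailed", 2020, 2025), rubric)


class TestSuitabilitySummary:
    def test_portfolio_shares_match_direct_division(self):
        matrix = make_matrix(
            make_residue("a", 59.7e6, lignin=0.3),
            make_residue("b", 42.6e6, lignin=0.3),
            make_residue("c", 4.1e6, lignin=0.3),
            make_residue("d", 2.4e6, lignin=0.3),
        )
        frame = suitability_summary(
            matrix,
            {
                "a": "model_process",
                "b": "principal_feasibility",
                "c": "not_exploitable",
                "d": "below_cutoff",
            },
        )
        shares = frame["share"]
        # portfolio split 54.8 / 39.2 / 3.8 / 2.2 percent
        assert shares["model_process"] == pytest.approx(0.5487, abs=5e-3)
        assert shares["principal_feasibility"] == pytest.approx(0.3915, abs=5e-3)
        assert shares["not_exploitable"] == pytest.approx(0.0377, abs=5e-3)
        assert shares["below_cutoff"] == pytest.approx(0.0221, abs=5e-3)
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)
        assert frame["mass_Mg_DM_a"].sum() == pytest.approx(
            matrix.total_technical_potential
        )

    def test_single_class_and_symmetry(self):
        matrix = make_matrix(
            make_residue("a", 5.0, lignin=0.1), make_residue("b", 5.0, lignin=0.1)
        )
        one = suitability_summary(
            matrix, {"a": "model_process", "b": "model_process"}
        )
        assert one["share"]["model_process"] == 1.0
        two = suitability_summary(
            matrix, {"a": "model_process", "b": "not_exploitable"}
        )
        assert two["share"]["model_process"] == 0.5
        assert two["share"]["not_exploitable"] == 0.5

    def test_shares_invariant_to_residue_ordering(self):
        residues = [
            make_residue(f"r{i}", float(i + 1) * 1e5, lignin=0.1) for i in range(6)
        ]
        classes = ["model_process", "principal_feasibility", "not_exploitable"]
        assign = {r.id: classes[i % 3] for i, r in enumerate(residues)}
        forward = suitability_summary(make_matrix(*residues), assign)
        backward = suitability_summary(make_matrix(*reversed(residues)), assign)
        assert forward["share"].tolist() == pytest.approx(
            backward["share"].tolist(), rel=1e-12
        )

    def test_unassigned_residue_is_an_error(self):
        matrix = make_matrix(make_residue("a", 1.0, lignin=0.1))
        with pytest.raises(ValueError, match="unassigned"):
            suitability_summary(matrix, {})
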