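import numpy as np
import pytest

from subspec.classifier import LibraryBuilder, SynonymMap, classify
from subspec.io_formats import AMINO_ACIDS, DomainSequence, MultipleAlignment
from subspec.validation import (
    SubstrateCounts,
    ValidationReport,
    compare_reports,
    evaluate,
    loo_cross_validate,
)


def _toy_groups(seed=0, sizes=(4, 4), length=40, rate=0.08):
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    groups, seqs = {}, []
    for gi, n in enumerate(sizes):
        label = f"g{gi}"
        base = aa[rng.integers(0, 20, length)]
        rows = []
        for k in range(n):
            row = base.copy()
            mask = rng.random(length) < rate
            row[mask] = aa[rng.integers(0, 20, int(mask.sum()))]
            rows.append("".join(row))
        ids = [f"{label}_{k}" for k in range(n)]
        groups[label] = MultipleAlignment(ids, rows)
        seqs += [
            DomainSequence(i, r, "A", substrate=label) for i, r in zip(ids, rows)
        ]
    return groups, seqs


class TestReportArithmetic:
    def test_counts_must_add_up(self):
        with pytest.raises(ValueError, match="add up"):
            SubstrateCounts("x", 4, 2, 1, 0)

    def test_percentages_recompute_from_counts(self):
        report = ValidationReport(
            [
                SubstrateCounts("x", 2, 2, 0, 0),
                SubstrateCounts("y", 2, 0, 1, 1),
            ]
        )
        assert report.percent_correct == pytest.approx(50.0)
        assert report.percent_false == pytest.approx(25.0)
        assert report.percent_below_threshold == pytest.approx(25.0)
        assert report.coverage_percent == pytest.approx(75.0)
        assert report.correct_of_covered_percent == pytest.approx(100 * 2 / 3)

    def test_all_correct(self):
        report = ValidationReport([SubstrateCounts("x", 2, 2, 0, 0)])
        assert report.percent_correct == 100.0
        assert report.percent_false == 0.0
        assert report.percent_below_threshold == 0.0


class TestEvaluate:
    def test_resubstitution_on_tight_groups_is_perfect(self):
        groups, seqs = _toy_groups()
        library, _ = LibraryBuilder("A", "single", threshold_bits=0.0).build(groups)
        report = evaluate(library, seqs)
        assert report.percent_correct == 100.0

    def test_unlabeled_sequence_is_hard_error(self):
        groups, seqs = _toy_groups()
        library, _ = LibraryBuilder("A", "single", threshold_bits=0.0).build(groups)
        bad = seqs + [DomainSequence("q", seqs[0].residues, "A")]
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate(library, bad)

    def test_synonyms_count_as_correct(self):
        groups, seqs = _toy_groups()
        # relabel group g1 with a synonym of g0's prediction
        groups = {"dhb": groups["g0"], "other": groups["g1"]}
        seqs = [
            DomainSequence(
                s.id, s.residues, "A", substrate="sal" if s.substrate == "g0" else "other"
            )
            for s in seqs
        ]
        library, _ = LibraryBuilder("A", "single", threshold_bits=0.0).build(groups)
        report = evaluate(library, seqs, SynonymMap())
        # predictions say "dhb"; true labels say "sal": synonymous, so correct
        assert report.row("sal").correct == report.row("sal").n

    def test_ambiguous_labels_match_any_alternative(self):
        groups, seqs = _toy_groups()
        seqs = [
            DomainSequence(
                s.id, s.residues, "A",
                substrate="g0|g1" if s.id == "g0_0" else s.substrate,
            )
            for s in seqs
        ]
        library, _ = LibraryBuilder("A", "single", threshold_bits=0.0).build(groups)
        report = evaluate(library, seqs)
        assert report.row("g0|g1").correct == 1

    def test_substrate_without_model_counts_favorably_when_below_threshold(self):
        groups, seqs = _toy_groups(sizes=(4, 4))
        library, _ = LibraryBuilder("A", "single", threshold_bits=0.0).build(
            {"g0": groups["g0"]}
        )
        # raise threshold above anything g1 sequences can reach on the g0 model
        g1_scores = [classify(library, s).bit_score for s in seqs if s.substrate == "g1"]
        library.threshold_bits = max(g1_scores) + 1.0
        report = evaluate(library, [s for s in seqs if s.substrate == "g1"])
        assert report.row("g1").below_threshold == report.row("g1").n
        assert report.row("g1").false == 0


class TestLOO:
    def test_identical_member_group_survives_loo(self):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = [aa, aa, aa]
        groups = {
            "same": MultipleAlignment([f"s{i}" for i in range(3)], rows),
            "other": MultipleAlignment(["o0", "o1"], ["W" * 20, "W" * 20]),
        }
        seqs = [
            DomainSequence(f"s{i}", aa, "A", substrate="same") for i in range(3)
        ] + [DomainSequence(f"o{i}", "W" * 20, "A", substrate="other") for i in range(2)]
        builder = LibraryBuilder("A", "single", threshold_bits=0.0)
        result = loo_cross_validate(groups, builder, seqs)
        assert result.report.row("same").correct == 3

    def test_reinserting_held_out_sequence_reproduces_resubstitution(self):
        groups, seqs = _toy_groups(seed=3)
        builder = LibraryBuilder("A", "single", threshold_bits=0.0)
        library, _ = builder.build(groups)
        # a LOO fold library for g0_0 with the sequence re-inserted equals the
        # full library prediction bit-for-bit
        full_pred = classify(library, seqs[0])
        refit = builder.refit(library.models_for("g0")[0], groups["g0"])
        import dataclasses

        rebuilt = dataclasses.replace(library)
        rebuilt.models = [refit] + [m for m in library.models if m.substrate != "g0"]
        assert classify(rebuilt, seqs[0]).bit_score == full_pred.bit_score

    def test_loo_not_better_than_resubstitution(self, contrast_ds):
        from subspec.synthetic import calibrate_threshold

        groups = contrast_ds.groups()
        builder0 = LibraryBuilder("A", "single", threshold_bits=0.0)
        library, _ = builder0.build(groups)
        thr = calibrate_threshold(library, contrast_ds.sequences)
        builder = LibraryBuilder("A", "single", threshold_bits=thr)
        resub = evaluate(builder.build(groups)[0], contrast_ds.sequences)
        loo = loo_cross_validate(groups, builder, contrast_ds.sequences)
        assert loo.report.percent_correct <= resub.percent_correct

    def test_order_invariance_of_report(self):
        groups, seqs = _toy_groups(seed=5)
        builder = LibraryBuilder("A", "single", threshold_bits=0.0)
        a = loo_cross_validate(groups, builder, seqs)
        b = loo_cross_validate(groups, builder, list(reversed(seqs)))
        assert a.report == b.report


class TestCompareReports:
    def test_identical_reports_zero_deltas(self):
        r = ValidationReport([SubstrateCounts("x", 3, 2, 1, 0)])
        deltas = compare_reports(r, r)
        assert all(
            (d.d_n, d.d_correct, d.d_false, d.d_below_threshold) == (0, 0, 0, 0)
            for d in deltas
        )

    def test_antisymmetric_under_swap(self):
        a = ValidationReport([SubstrateCounts("x", 3, 2, 1, 0)])
        b = ValidationReport([SubstrateCounts("x", 3, 1, 1, 1)])
        ab, ba = compare_reports(a, b), compare_reports(b, a)
        for d1, d2 in zip(ab, ba):
            assert d1.d_correct == -d2.d_correct
            assert d1.d_below_threshold == -d2.d_below_threshold

    def test_ensemble_improves_on_single_for_convergent_fixture(
        self, convergent_ds, convergent_libraries
    ):
        single, ensemble, _ = convergent_libraries
        rs = evaluate(single, convergent_ds.sequences)
        re = evaluate(ensemble, convergent_ds.sequences)
        deltas = compare_reports(re, rs)
        assert sum(d.d_correct for d in deltas) > 0
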