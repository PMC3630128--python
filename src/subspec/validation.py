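"""Quality metrics and leave-one-out cross-validation.

Every labeled sequence falls in exactly one of three bins: *correct*
(reliable prediction matching the true substrate, synonyms allowed),
*false* (reliable but wrong) and *below threshold* (unreliable — the
prediction is not counted either way, matching the three-way bookkeeping
used for substrate classifiers).  Coverage is the fraction of sequences
receiving a reliable annotation, and correct-of-covered the fraction of
those that are right:

    coverage            = 100 * (1 - below_total / n_total)
    correct_of_covered  = 100 * correct_total / (correct_total + false_total)

Percentages are always recomputed from the integer counts; the report
holds no independently rounded state.

Ambiguous specificities may be written as ``"a|b"`` labels: a prediction
matching any alternative counts as correct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .classifier import ModelLibrary, SynonymMap, classify
from .io_formats import DomainSequence, MultipleAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstrateCounts:
    substrate: str
    n: int
    correct: int
    false: int
    below_threshold: int

    def __post_init__(self) -> None:
        if self.correct + self.false + self.below_threshold != self.n:
            raise ValueError(f"counts for {self.substrate!r} do not add up to n")


@dataclass
class ValidationReport:
    per_substrate: list[SubstrateCounts]

    @property
    def n_total(self) -> int:
        return sum(r.n for r in self.per_substrate)

    @property
    def correct_total(self) -> int:
        return sum(r.correct for r in self.per_substrate)

    @property
    def false_total(self) -> int:
        return sum(r.false for r in self.per_substrate)

    @property
    def below_threshold_total(self) -> int:
        return sum(r.below_threshold for r in self.per_substrate)

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.correct_total / self.n_total

    @property
    def percent_false(self) -> float:
        return 100.0 * self.false_total / self.n_total

    @property
    def percent_below_threshold(self) -> float:
        return 100.0 * self.below_threshold_total / self.n_total

    @property
    def coverage_percent(self) -> float:
        return 100.0 * (1.0 - self.below_threshold_total / self.n_total)

    @property
    def correct_of_covered_percent(self) -> float:
        covered = self.correct_total + self.false_total
        return 100.0 * self.correct_total / covered if covered else math.nan

    def row(self, substrate: str) -> SubstrateCounts:
        for r in self.per_substrate:
            if r.substrate == substrate:
                return r
        raise KeyError(substrate)

    def to_table(self) -> str:
        """Tab-separated summary mirroring the per-substrate c/f/at layout."""
        lines = ["substrate\tn\tcorrect\tfalse\tbelow_threshold"]
        for r in self.per_substrate:
            lines.append(
                f"{r.substrate}\t{r.n}\t{r.correct}\t{r.false}\t{r.below_threshold}"
            )
        lines.append(
            "overall\t"
            f"{self.n_total}\t{self.percent_correct:.1f}%\t{self.percent_false:.1f}%\t"
            f"{self.percent_below_threshold:.1f}%"
        )
        lines.append(
            f"coverage\t{self.coverage_percent:.1f}%\t"
            f"correct_of_covered\t{self.correct_of_covered_percent:.1f}%\t"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class LOORecord:
    seq_id: str
    true_substrate: str
    predicted_substrate: str
    bit_score: float
    reliable: bool


@dataclass
class LOOResult:
    report: ValidationReport
    records: list[LOORecord]
    degraded_groups: list[str]  # groups whose folds used single-member models


def _alternatives(label: str) -> list[str]:
    return label.split("|")


def _is_correct(predicted: str, true_label: str, synonyms: SynonymMap) -> bool:
    return any(synonyms.equivalent(predicted, alt) for alt in _alternatives(true_label))


def _tally(
    outcomes: Sequence[tuple[str, str, bool]], synonyms: SynonymMap
) -> ValidationReport:
    """outcomes: (true label, predicted substrate, reliable) triples."""
    by_label: dict[str, list[tuple[str, bool]]] = {}
    for true_label, predicted, reliable in outcomes:
        by_label.setdefault(true_label, []).append((predicted, reliable))
    rows = []
    for label in sorted(by_label):
        entries = by_label[label]
        correct = sum(
            1 for p, rel in entries if rel and _is_correct(p, label, synonyms)
        )
        false = sum(
            1 for p, rel in entries if rel and not _is_correct(p, label, synonyms)
        )
        below = sum(1 for _, rel in entries if not rel)
        rows.append(SubstrateCounts(label, len(entries), correct, false, below))
    return ValidationReport(rows)


def evaluate(
    library: ModelLibrary,
    labeled_sequences: Sequence[DomainSequence],
    synonym_map: SynonymMap | None = None,
) -> ValidationReport:
    """Classify every labeled sequence and tally correct / false / below-threshold."""
    synonyms = synonym_map or SynonymMap()
    unlabeled = [s.id for s in labeled_sequences if not s.substrate]
    if unlabeled:
        raise ValueError("unlabeled sequences: " + ", ".join(unlabeled[:10]))
    outcomes = []
    for seq in labeled_sequences:
        pred = classify(library, seq)
        outcomes.append((seq.substrate, pred.predicted_substrate, pred.reliable))
    return _tally(outcomes, synonyms)


def loo_cross_validate(
    groups: Mapping[str, MultipleAlignment],
    builder,
    labeled_sequences: Sequence[DomainSequence],
    synonym_map: SynonymMap | None = None,
) -> LOOResult:
    """Leave-one-out cross-validation over every group of size >= 2.

    For each held-out sequence only the model(s) trained on its own
    (sub)group are rebuilt without it; all sibling models stay untouched.
    The held-out sequence is then classified against the full rebuilt
    library.  When removal empties a one-member subgroup, that model is
    dropped for the fold and the event logged.
    """
    synonyms = synonym_map or SynonymMap()
    library, _excluded = builder.build(groups)
    seq_by_id = {s.id: s for s in labeled_sequences}
    records: list[LOORecord] = []
    degraded: list[str] = []
    for substrate in sorted(groups):
        aln = groups[substrate]
        if len(aln) < 2:
            continue
        if len(aln) == 2 and substrate not in degraded:
            degraded.append(substrate)
        for held_id in aln.ids:
            fold_models = []
            for model in library.models:
                if held_id not in model.members:
                    fold_models.append(model)
                    continue
                remaining = [i for i in model.members if i != held_id]
                if not remaining:
                    logger.info(
                        "LOO fold %s: subgroup model %s emptied; dropped for this fold",
                        held_id, model.name,
                    )
                    continue
                fold_models.append(builder.refit(model, aln.subset(remaining)))
            fold_library = ModelLibrary(
                library.domain_type, fold_models, library.mode, library.threshold_bits
            )
            seq = seq_by_id.get(held_id)
            if seq is None:
                raise ValueError(f"no sequence provided for aligned id {held_id!r}")
            pred = classify(fold_library, seq)
            records.append(
                LOORecord(
                    held_id,
                    seq.substrate or substrate,
                    pred.predicted_substrate,
                    pred.bit_score,
                    pred.reliable,
                )
            )
    report = _tally(
        [(r.true_substrate, r.predicted_substrate, r.reliable) for r in records],
        synonyms,
    )
    return LOOResult(report, records, degraded)


@dataclass(frozen=True)
class ReportDelta:
    substrate: str
    d_n: int
    d_correct: int
    d_false: int
    d_below_threshold: int


def compare_reports(a: ValidationReport, b: ValidationReport) -> list[ReportDelta]:
    """Per-substrate count differences ``a - b`` over the union of substrates."""
    substrates = sorted(
        {r.substrate for r in a.per_substrate} | {r.substrate for r in b.per_substrate}
    )
    empty = SubstrateCounts("", 0, 0, 0, 0)
    deltas = []
    for substrate in substrates:
        try:
            ra = a.row(substrate)
        except KeyError:
            ra = empty
        try:
            rb = b.row(substrate)
        except KeyError:
            rb = empty
        deltas.append(
            ReportDelta(
                substrate,
                ra.n - rb.n,
                ra.correct - rb.correct,
                ra.false - rb.false,
                ra.below_threshold - rb.below_threshold,
            )
        )
    return deltas
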