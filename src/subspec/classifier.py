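"""Model libraries and thresholded substrate prediction.

A *single* library holds one profile HMM per substrate (substrates with a
lone representative sequence are excluded — no reliable model can be made
from one observation).  An *ensemble* library replaces the single model
of every well-represented substrate (at least 10 sequences for AT
domains, 15 for A domains) by 2–4 clade-specific models, one per subgroup
of a clade partition; the best-scoring model over the whole library
decides the predicted substrate.

Predictions are flagged unreliable when the winning bit score falls below
the library threshold (325 bits for AT domains, 625 for A domains in the
reference setting; both configurable per library).  Reliability is
defined on the bit score alone and never changes which substrate wins —
raising the threshold only flips the flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import DomainSequence, MultipleAlignment, AnnotationTable
from .njtree import CladePartition
from .profile_hmm import ProfileHMM, estimate_parameters, score_all

#: reference reliability thresholds in bits, per domain type
DEFAULT_THRESHOLD_BITS = {"AT": 325.0, "A": 625.0}

#: ensemble subdivision size thresholds, per domain type
DEFAULT_SIZE_THRESHOLD = {"AT": 10, "A": 15}

#: substrate labels scored as one group (interchangeable specificities)
SYNONYM_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"dhb", "sal"}),
    frozenset({"thr", "allo-thr"}),
    frozenset({"hpg", "hpg2Cl"}),
    frozenset({"dhab", "dht"}),
    frozenset({"dhpg", "dpg"}),
    frozenset({"pro", "me-pro", "mpro"}),
    frozenset({"abu", "iva"}),
    frozenset({"masp", "me-asp"}),
)


class SynonymMap:
    """Equivalence of substrate codes under the shipped synonym groups."""

    def __init__(self, groups: Sequence[frozenset[str]] = SYNONYM_GROUPS) -> None:
        self._of: dict[str, frozenset[str]] = {}
        for grp in groups:
            for code in grp:
                self._of[code] = grp

    def equivalent(self, a: str, b: str) -> bool:
        if a == b:
            return True
        return b in self._of.get(a, frozenset())

    def group_of(self, code: str) -> frozenset[str]:
        return self._of.get(code, frozenset({code}))


@dataclass
class ModelLibrary:
    domain_type: str
    models: list[ProfileHMM]
    mode: str  # "single" | "ensemble"
    threshold_bits: float

    def __post_init__(self) -> None:
        if self.domain_type not in ("A", "AT"):
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if self.mode not in ("single", "ensemble"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        per_substrate: dict[str, int] = {}
        for m in self.models:
            per_substrate[m.substrate] = per_substrate.get(m.substrate, 0) + 1
        limit = 1 if self.mode == "single" else 4
        for substrate, count in per_substrate.items():
            if count > limit:
                raise ValueError(
                    f"{count} models for substrate {substrate!r} exceeds the "
                    f"{self.mode}-library limit of {limit}"
                )

    @property
    def substrates(self) -> list[str]:
        out: list[str] = []
        for m in self.models:
            if m.substrate not in out:
                out.append(m.substrate)
        return out

    def models_for(self, substrate: str) -> list[ProfileHMM]:
        return [m for m in self.models if m.substrate == substrate]


@dataclass(frozen=True)
class Prediction:
    seq_id: str
    predicted_substrate: str
    best_model: str
    bit_score: float
    reliable: bool
    runner_up: tuple[str, float] | None


def group_alignments(
    alignment: MultipleAlignment,
    annotation: AnnotationTable,
    *,
    non_redundant_only: bool = True,
) -> dict[str, MultipleAlignment]:
    """Split an alignment into per-substrate sub-alignments."""
    groups: dict[str, MultipleAlignment] = {}
    present = set(alignment.ids)
    for substrate in annotation.substrates():
        members = [
            m
            for m in annotation.members(substrate, non_redundant_only=non_redundant_only)
            if m in present
        ]
        if members:
            groups[substrate] = alignment.subset(members)
    return groups


def build_single_library(
    groups: Mapping[str, MultipleAlignment],
    domain_type: str,
    *,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    threshold_bits: float | None = None,
) -> tuple[ModelLibrary, list[str]]:
    """One model per substrate with >= 2 member sequences.

    Returns the library and the list of excluded singleton substrates.
    """
    excluded = sorted(s for s, aln in groups.items() if len(aln) < 2)
    qualifying = sorted(s for s in groups if s not in excluded)
    if not qualifying:
        raise ValueError("no substrate group has at least 2 members")
    models = [
        estimate_parameters(
            groups[s],
            pseudocount_weight=pseudocount_weight,
            background=background,
            name=s,
            substrate=s,
            subgroup_index=0,
        )
        for s in qualifying
    ]
    threshold = (
        DEFAULT_THRESHOLD_BITS[domain_type] if threshold_bits is None else threshold_bits
    )
    return ModelLibrary(domain_type, models, "single", threshold), excluded


def build_ensemble_library(
    groups: Mapping[str, MultipleAlignment],
    domain_type: str,
    partitions: Mapping[str, CladePartition],
    *,
    size_threshold: int | None = None,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    threshold_bits: float | None = None,
) -> tuple[ModelLibrary, list[str]]:
    """2–4 clade-specific models for well-represented substrates.

    A substrate gets one model per partition part when its group size
    reaches ``size_threshold`` (10 for AT, 15 for A) and a multi-part
    partition was supplied; every other substrate falls back to its
    single model.  Singleton substrates are excluded as in
    :func:`build_single_library`.
    """
    if size_threshold is None:
        size_threshold = DEFAULT_SIZE_THRESHOLD[domain_type]
    excluded = sorted(s for s, aln in groups.items() if len(aln) < 2)
    models: list[ProfileHMM] = []
    for substrate in sorted(groups):
        if substrate in excluded:
            continue
        aln = groups[substrate]
        partition = partitions.get(substrate)
        if (
            len(aln) >= size_threshold
            and partition is not None
            and len(partition.subgroups) >= 2
        ):
            unknown = partition.members - set(aln.ids)
            if unknown:
                raise ValueError(
                    f"partition of {substrate!r} references unknown ids: "
                    + ", ".join(sorted(unknown))
                )
            for index, part in enumerate(partition.subgroups, start=1):
                models.append(
                    estimate_parameters(
                        aln.subset(part),
                        pseudocount_weight=pseudocount_weight,
                        background=background,
                        name=f"{substrate}_{index}",
                        substrate=substrate,
                        subgroup_index=index,
                    )
                )
        else:
            models.append(
                estimate_parameters(
                    aln,
                    pseudocount_weight=pseudocount_weight,
                    background=background,
                    name=substrate,
                    substrate=substrate,
                    subgroup_index=0,
                )
            )
    if not models:
        raise ValueError("no substrate group has at least 2 members")
    threshold = (
        DEFAULT_THRESHOLD_BITS[domain_type] if threshold_bits is None else threshold_bits
    )
    return ModelLibrary(domain_type, models, "ensemble", threshold), excluded


@dataclass
class LibraryBuilder:
    """Reusable library-construction procedure (for cross-validation).

    Bundles the mode, partitions and estimation settings so a fold can
    refit exactly one subgroup model with the same parameters that built
    the full library.
    """

    domain_type: str
    mode: str = "single"
    partitions: Mapping[str, CladePartition] | None = None
    size_threshold: int | None = None
    pseudocount_weight: float = 1.0
    background: np.ndarray | None = None
    threshold_bits: float | None = None

    def build(self, groups: Mapping[str, MultipleAlignment]) -> tuple[ModelLibrary, list[str]]:
        if self.mode == "single":
            return build_single_library(
                groups,
                self.domain_type,
                pseudocount_weight=self.pseudocount_weight,
                background=self.background,
                threshold_bits=self.threshold_bits,
            )
        return build_ensemble_library(
            groups,
            self.domain_type,
            self.partitions or {},
            size_threshold=self.size_threshold,
            pseudocount_weight=self.pseudocount_weight,
            background=self.background,
            threshold_bits=self.threshold_bits,
        )

    def refit(self, model: ProfileHMM, subset: MultipleAlignment) -> ProfileHMM:
        """Re-estimate one model on a reduced member alignment."""
        return estimate_parameters(
            subset,
            pseudocount_weight=self.pseudocount_weight,
            background=self.background,
            name=model.name,
            substrate=model.substrate,
            subgroup_index=model.subgroup_index,
        )


def classify(library: ModelLibrary, sequence: DomainSequence | str) -> Prediction:
    """Best-scoring model decides the substrate; the threshold decides
    reliability.  Ties are broken by model name, so classification is a
    pure function of (library, sequence)."""
    results = score_all(library, sequence)
    best = results[0]
    runner = (results[1].model_name, results[1].bit_score) if len(results) > 1 else None
    seq_id = sequence.id if isinstance(sequence, DomainSequence) else "<anonymous>"
    return Prediction(
        seq_id=seq_id,
        predicted_substrate=best.substrate,
        best_model=best.model_name,
        bit_score=best.bit_score,
        reliable=best.bit_score >= library.threshold_bits,
        runner_up=runner,
    )
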