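"""Per-substrate conservation analysis and residue selection.

Alignment columns are mapped onto the residue numbering of a reference
structure row (FabD for AT domains, GrsA for A domains), per-substrate
conservation is computed at the strictest criterion (100% identity within
the group; a gap never counts as conserved), and reduced alignments are
extracted from a column selection.  Selections can be taken as columns
conserved in at least ``k`` substrate groups, optionally excluding the
columns that are conserved with the same residue across *all* groups —
those carry no discriminative signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .io_formats import GAP, MultipleAlignment


class SelectionRule(str, Enum):
    CONSERVED_ANY_GROUP_INCL_GLOBAL = "conserved_any_group_incl_global"
    CONSERVED_ANY_GROUP_EXCL_GLOBAL = "conserved_any_group_excl_global"
    CONSERVED_MIN_K_GROUPS = "conserved_min_k_groups"
    EXPLICIT_REFERENCE_POSITIONS = "explicit_reference_positions"


@dataclass(frozen=True)
class ReferenceNumbering:
    """Map from alignment columns to residue numbers of a reference row."""

    reference_id: str
    column_to_residue: dict[int, int]

    def residue_of(self, column: int) -> int | None:
        return self.column_to_residue.get(column)

    def column_of(self, residue: int) -> int | None:
        for col, res in self.column_to_residue.items():
            if res == residue:
                return col
        return None


@dataclass(frozen=True)
class ConservationProfile:
    group: str
    conserved_columns: frozenset[int]
    consensus: dict[int, str]


@dataclass(frozen=True)
class ResidueSelection:
    name: str
    columns: tuple[int, ...]  # ascending, 1-based
    rule: SelectionRule

    def __post_init__(self) -> None:
        if list(self.columns) != sorted(set(self.columns)):
            raise ValueError("selection columns must be unique and ascending")


def build_reference_numbering(
    alignment: MultipleAlignment, reference_id: str
) -> ReferenceNumbering:
    """Number columns by the reference row: its k-th non-gap column is residue k."""
    if reference_id not in alignment.ids:
        raise ValueError(f"reference sequence {reference_id!r} is not in the alignment")
    row = alignment.row(reference_id)
    mapping: dict[int, int] = {}
    residue = 0
    for col, aa in enumerate(row, start=1):
        if aa != GAP:
            residue += 1
            mapping[col] = residue
    if not mapping:
        raise ValueError(f"reference row {reference_id!r} is all gaps")
    return ReferenceNumbering(reference_id, mapping)


def select_reference_positions(
    numbering: ReferenceNumbering, residues: Sequence[int], name: str = "reference-positions"
) -> ResidueSelection:
    """Selection of the alignment columns carrying given reference residue numbers."""
    inverse = {res: col for col, res in numbering.column_to_residue.items()}
    missing = [r for r in residues if r not in inverse]
    if missing:
        raise ValueError(
            f"reference residues not alignable: {', '.join(map(str, missing))}"
        )
    cols = sorted(inverse[r] for r in residues)
    return ResidueSelection(name, tuple(cols), SelectionRule.EXPLICIT_REFERENCE_POSITIONS)


def conservation_profile(
    alignment: MultipleAlignment, members: Sequence[str], group: str = ""
) -> ConservationProfile:
    """Columns where all members carry one identical non-gap residue.

    For a singleton member set every non-gap column is (vacuously)
    conserved.
    """
    if not members:
        raise ValueError("empty member set")
    rows = [alignment.row(m) for m in members]
    conserved: set[int] = set()
    consensus: dict[int, str] = {}
    for col in range(1, alignment.column_count + 1):
        residues = {row[col - 1] for row in rows}
        if len(residues) == 1 and GAP not in residues:
            conserved.add(col)
            consensus[col] = rows[0][col - 1]
    return ConservationProfile(group, frozenset(conserved), consensus)


def select_columns(
    profiles: Sequence[ConservationProfile],
    rule: SelectionRule = SelectionRule.CONSERVED_MIN_K_GROUPS,
    k: int = 1,
    exclude_global: bool | None = None,
    name: str = "selection",
) -> ResidueSelection:
    """Columns conserved in at least ``k`` of the given group profiles.

    ``exclude_global`` drops the columns that are conserved in *every*
    profile with a common consensus residue (identically conserved columns
    carry scaffold signal, not specificity signal).  The two ``any group``
    rules are shorthands for ``k = 1``.
    """
    if not profiles:
        raise ValueError("need at least one conservation profile")
    if rule == SelectionRule.CONSERVED_ANY_GROUP_INCL_GLOBAL:
        k, exclude_global = 1, False
    elif rule == SelectionRule.CONSERVED_ANY_GROUP_EXCL_GLOBAL:
        k, exclude_global = 1, True
    elif exclude_global is None:
        exclude_global = False
    if not 1 <= k <= len(profiles):
        raise ValueError(f"k={k} out of range for {len(profiles)} profiles")

    counts: dict[int, int] = {}
    for profile in profiles:
        for col in profile.conserved_columns:
            counts[col] = counts.get(col, 0) + 1
    selected = {col for col, n in counts.items() if n >= k}
    if exclude_global:
        selected -= globally_conserved_columns(profiles)
    return ResidueSelection(name, tuple(sorted(selected)), rule)


def globally_conserved_columns(profiles: Sequence[ConservationProfile]) -> set[int]:
    """Columns conserved in all profiles with the same consensus residue."""
    common = set.intersection(*(set(p.conserved_columns) for p in profiles))
    return {
        col
        for col in common
        if len({p.consensus[col] for p in profiles}) == 1
    }


def extract_reduced(
    alignment: MultipleAlignment, selection: ResidueSelection
) -> MultipleAlignment:
    """New alignment containing only the selected columns (row order kept)."""
    if not selection.columns:
        raise ValueError("empty residue selection")
    return alignment.slice_columns(selection.columns)


def position_frequency_matrix(
    alignment: MultipleAlignment, members: Sequence[str] | None = None
) -> dict[int, dict[str, float]]:
    """Per-column residue frequencies (gaps excluded) — a plain-text stand-in
    for a graphical sequence logo."""
    rows = (
        alignment.rows if members is None else [alignment.row(m) for m in members]
    )
    out: dict[int, dict[str, float]] = {}
    for col in range(1, alignment.column_count + 1):
        residues = [row[col - 1] for row in rows if row[col - 1] != GAP]
        freqs: dict[str, float] = {}
        for aa in residues:
            freqs[aa] = freqs.get(aa, 0.0) + 1.0
        total = sum(freqs.values())
        out[col] = {aa: n / total for aa, n in sorted(freqs.items())} if total else {}
    return out
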