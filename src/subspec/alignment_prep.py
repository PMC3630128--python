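"""Alignment homogenisation and redundancy removal.

Substrate-specific models are only comparable when the underlying
alignment is homogeneous: no sequence may stick out beyond the common
N- or C-terminal boundary of the domain.  :func:`trim_terminal_extensions`
iterates align / measure-overhang / cut until the first and last
alignment columns are gap-free, mirroring the usual manual curation loop.

Near-duplicate sequences (trivial resubmissions of the same domain) bias
model training; :func:`deduplicate` removes them by greedy single-linkage
on pairwise global-alignment identity, restricted to pairs sharing a
substrate label so that cross-substrate paralogs are never collapsed.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Protocol, Sequence

from Bio import Align

from .io_formats import (
    GAP,
    DomainSequence,
    MultipleAlignment,
    read_alignment,
    write_fasta,
)

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.98
DEFAULT_MAX_ROUNDS = 10


class Realigner(Protocol):
    """Contract: map a set of unaligned sequences to an alignment over
    exactly those sequences (same ids, ungapped rows equal the inputs)."""

    def __call__(self, sequences: Sequence[DomainSequence]) -> MultipleAlignment: ...


@dataclass
class MafftRealigner:
    """Realign through an external ``mafft`` binary (default settings)."""

    executable: str = "mafft"
    extra_args: tuple[str, ...] = ("--auto", "--quiet")

    def __call__(self, sequences: Sequence[DomainSequence]) -> MultipleAlignment:
        if shutil.which(self.executable) is None:
            raise RuntimeError(f"aligner executable {self.executable!r} not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            infile = Path(tmp) / "in.fasta"
            write_fasta(sequences, infile)
            proc = subprocess.run(
                [self.executable, *self.extra_args, str(infile)],
                capture_output=True,
                text=True,
                check=True,
            )
            outfile = Path(tmp) / "out.fasta"
            outfile.write_text(proc.stdout)
            aln = read_alignment(outfile)
        _check_contract(sequences, aln)
        return aln


@dataclass
class TemplateRealigner:
    """Deterministic aligner guided by a known template alignment.

    Each input sequence must contain the ungapped template row for its id
    as a contiguous substring; the core is laid out in the template's
    columns and any flanking residues are stacked in left/right extension
    blocks padded with gaps.  This gives the package an alignment engine
    with no external binary, suitable for tests and synthetic data whose
    true alignment is known.
    """

    template: MultipleAlignment

    def __call__(self, sequences: Sequence[DomainSequence]) -> MultipleAlignment:
        cores: dict[str, tuple[str, str, str]] = {}
        for seq in sequences:
            core = self.template.ungapped(seq.id)
            at = seq.residues.find(core)
            if at >= 0:
                cores[seq.id] = (
                    seq.residues[:at],
                    self.template.row(seq.id),
                    seq.residues[at + len(core):],
                )
                continue
            # the input may instead be a trimmed-down piece of the core:
            # blank the cut template residues so columns stay aligned
            at = core.find(seq.residues)
            if at < 0:
                raise ValueError(
                    f"sequence {seq.id!r} neither contains nor is contained "
                    "in its template core"
                )
            row, core_pos = [], 0
            for aa in self.template.row(seq.id):
                if aa == GAP:
                    row.append(GAP)
                else:
                    inside = at <= core_pos < at + len(seq.residues)
                    row.append(aa if inside else GAP)
                    core_pos += 1
            cores[seq.id] = ("", "".join(row), "")
        left = max(len(c[0]) for c in cores.values())
        right = max(len(c[2]) for c in cores.values())
        ids, rows = [], []
        for seq in sequences:
            prefix, template_row, suffix = cores[seq.id]
            rows.append(
                GAP * (left - len(prefix))
                + prefix
                + template_row
                + suffix
                + GAP * (right - len(suffix))
            )
            ids.append(seq.id)
        aln = MultipleAlignment(ids, rows)
        _check_contract(sequences, aln)
        return aln


def _check_contract(sequences: Sequence[DomainSequence], aln: MultipleAlignment) -> None:
    if sorted(aln.ids) != sorted(s.id for s in sequences):
        raise ValueError("realigner returned a different id set than its input")
    for seq in sequences:
        if aln.ungapped(seq.id) != seq.residues:
            raise ValueError(f"realigner altered the residues of {seq.id!r}")


def terminal_overhang(alignment: MultipleAlignment) -> tuple[int, int]:
    """Number of leading and trailing columns that still contain a gap.

    ``(0, 0)`` iff the first and last columns are gap-free.  When every
    column contains a gap, both counts equal the column count.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    n = alignment.column_count
    leading = 0
    while leading < n and GAP in alignment.column(leading + 1):
        leading += 1
    trailing = 0
    while trailing < n and GAP in alignment.column(n - trailing):
        trailing += 1
    return leading, trailing


@dataclass
class TrimResult:
    alignment: MultipleAlignment
    removed: dict[str, int]  # per-sequence residues cut away
    rounds: int

    @property
    def converged(self) -> bool:
        return self.alignment.warning is None


def trim_terminal_extensions(
    sequences: Sequence[DomainSequence],
    realigner: Realigner,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
) -> TrimResult:
    """Iteratively align and cut terminal extensions until the alignment ends
    are gap-free.

    Residues are removed row-wise by overhang-column membership, so rows
    without extensions lose nothing.  If ``max_rounds`` is exhausted before
    convergence the result carries a warning instead of raising.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to trim")
    current = list(sequences)
    removed = {s.id: 0 for s in sequences}
    rounds = 0
    while True:
        aln = realigner(current)
        leading, trailing = terminal_overhang(aln)
        rounds += 1
        logger.info(
            "trim round %d: leading=%d trailing=%d columns=%d",
            rounds, leading, trailing, aln.column_count,
        )
        if (leading, trailing) == (0, 0):
            return TrimResult(aln, removed, rounds)
        if leading + trailing >= aln.column_count:
            raise ValueError("overhang spans the whole alignment; nothing would remain")
        trimmed: list[DomainSequence] = []
        for seq_id, row in zip(aln.ids, aln.rows):
            kept = row[leading : aln.column_count - trailing].replace(GAP, "")
            cut = len(row.replace(GAP, "")) - len(kept)
            if not kept:
                raise ValueError(f"sequence {seq_id!r} would be trimmed to length 0")
            removed[seq_id] += cut
            old = next(s for s in current if s.id == seq_id)
            trimmed.append(replace(old, residues=kept))
        current = trimmed
        if rounds >= max_rounds:
            aln = realigner(current)
            aln.warning = f"terminal trimming did not converge within {max_rounds} rounds"
            return TrimResult(aln, removed, rounds)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions in a global pairwise alignment.

    Identity scoring (match 1, mismatch 0, affine gap cost); the
    denominator is the number of aligned columns, which for a pairwise
    alignment never includes double-gap columns.
    """
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-0.5,
    )
    alignment = aligner.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return matches / len(row_a)


def deduplicate(
    sequences: Sequence[DomainSequence],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    identity: Callable[[str, str], float] = pairwise_identity,
) -> tuple[list[DomainSequence], list[tuple[str, str, float]]]:
    """Greedy removal of (near-)duplicates within each substrate group.

    Sequences are processed in input order; one is dropped when its global
    identity to an already-kept sequence of the same substrate reaches the
    threshold.  Returns the kept list and ``(removed id, kept id,
    identity)`` records.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0.5, 1.0]")
    kept: list[DomainSequence] = []
    removed: list[tuple[str, str, float]] = []
    for seq in sequences:
        duplicate_of = None
        for ref in kept:
            if ref.substrate != seq.substrate:
                continue
            ident = identity(ref.residues, seq.residues)
            if ident >= identity_threshold:
                duplicate_of = (ref.id, ident)
                break
        if duplicate_of is None:
            kept.append(seq)
        else:
            removed.append((seq.id, duplicate_of[0], duplicate_of[1]))
    return kept, removed
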