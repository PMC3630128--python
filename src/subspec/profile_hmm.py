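"""Substrate-specific profile hidden Markov models.

A profile HMM is built from the aligned member rows of one substrate
(sub)group and scores arbitrary unaligned domain sequences in log-odds
bits against a background model.  The architecture is the plain
match/insert/delete profile: node ``k`` carries a match state ``M_k`` with
its own emission distribution, an insert state ``I_k`` emitting background
residues between nodes ``k`` and ``k+1``, and a delete state ``D_k``.
Node 0 is the silent begin state; leaving node ``M`` enters the silent end
state.  The transitions ``I -> D`` and ``D -> I`` are fixed to probability
zero, which is common profile practice and keeps parameter estimation
well-behaved for the small training groups (down to two sequences) seen in
substrate-specificity data.

Scoring uses global (whole-sequence) Viterbi alignment: the tool's
contract requires pre-excised domain sequences, so no local entry/exit
states are modeled.  The bit score is the base-2 log-odds of the best
state path versus a background that emits every residue from the null
frequencies; because the null model carries no length penalty, a
single-match model emitting residue ``a`` with probability 1 scores
``log2(1 / background[a])`` on the one-letter sequence ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AMINO_ACIDS, GAP, DomainSequence, MultipleAlignment

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_LN2 = math.log(2.0)
_NEG_INF = float("-inf")

#: uniform background over the 20 standard residues
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


def _log2(p: float) -> float:
    return math.log2(p) if p > 0.0 else _NEG_INF


@dataclass(frozen=True)
class ProfileHMM:
    """Match/insert/delete profile with log-odds scoring.

    Transition rows (index ``k`` runs over nodes ``0..M``; node 0 is the
    begin state, treated as ``M_0``):

    * ``t_match[k] = (M_k->M_{k+1}, M_k->I_k, M_k->D_{k+1})``
    * ``t_insert[k] = (I_k->M_{k+1}, I_k->I_k)``
    * ``t_delete[k] = (D_k->M_{k+1}, D_k->D_{k+1})`` (row 0 is unused)

    At ``k = M`` the ``->M`` slot is the transition into the end state and
    the ``->D`` slot is zero.
    """

    name: str
    substrate: str
    subgroup_index: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M+1, 20)
    t_match: np.ndarray  # (M+1, 3)
    t_insert: np.ndarray  # (M+1, 2)
    t_delete: np.ndarray  # (M+1, 2)
    background: np.ndarray  # (20,)
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = self.match_emissions.shape[0]
        if m < 1:
            raise ValueError("a profile needs at least one match state")
        expected = {
            "match_emissions": (m, 20),
            "insert_emissions": (m + 1, 20),
            "t_match": (m + 1, 3),
            "t_insert": (m + 1, 2),
            "t_delete": (m + 1, 2),
            "background": (20,),
        }
        for attr, shape in expected.items():
            got = getattr(self, attr).shape
            if got != shape:
                raise ValueError(f"{attr} has shape {got}, expected {shape}")
        for attr in ("match_emissions", "insert_emissions"):
            rows = getattr(self, attr)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{attr} rows of model {self.name!r} do not sum to 1")
        for attr in ("t_match", "t_insert"):
            rows = getattr(self, attr)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{attr} rows of model {self.name!r} do not sum to 1")
        if not np.allclose(self.t_delete[1:].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"t_delete rows of model {self.name!r} do not sum to 1")
        if self.t_match[m, 2] != 0.0 or self.t_delete[m, 1] != 0.0:
            raise ValueError("transitions into D beyond the last node must be 0")

    @property
    def match_count(self) -> int:
        return self.match_emissions.shape[0]


@dataclass(frozen=True)
class ScoreResult:
    model_name: str
    substrate: str
    bit_score: float
    raw_log_odds: float
    path_length: int

    def __post_init__(self) -> None:
        if math.isfinite(self.bit_score):
            assert abs(self.bit_score - self.raw_log_odds / _LN2) < 1e-9


def assign_match_columns(alignment: MultipleAlignment) -> list[bool]:
    """Flag each column as a match column (gap fraction < 0.5; ties are match)."""
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    n = len(alignment)
    flags: list[bool] = []
    for col in range(1, alignment.column_count + 1):
        gaps = alignment.column(col).count(GAP)
        flags.append(gaps / n <= 0.5)
    if not any(flags):
        raise ValueError("alignment yields zero match columns")
    return flags


def estimate_parameters(
    alignment: MultipleAlignment,
    match_flags: list[bool] | None = None,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    *,
    name: str = "model",
    substrate: str = "?",
    subgroup_index: int = 0,
) -> ProfileHMM:
    """Estimate a profile from an aligned (sub)group.

    Match emissions are per-column residue counts plus
    ``pseudocount_weight * background``, normalized.  Transition counts are
    read off each row's path through the match/insert/delete skeleton and
    smoothed with the same Laplace weight over the legal moves.  Insert
    states emit background residues.  Ambiguous ``X`` residues contribute
    no emission counts; transitions the reduced architecture cannot
    represent (an insertion directly followed by a deletion, or vice
    versa) are skipped when counting.
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if match_flags is None:
        match_flags = assign_match_columns(alignment)
    if len(match_flags) != alignment.column_count:
        raise ValueError("match_flags length does not fit the alignment")
    w = float(pseudocount_weight)
    if w < 0:
        raise ValueError("pseudocount_weight must be >= 0")

    m = sum(match_flags)
    if m == 0:
        raise ValueError("no match columns")
    # node index for each match column (1-based nodes)
    node_of_col = []
    node = 0
    for flag in match_flags:
        if flag:
            node += 1
        node_of_col.append(node if flag else None)

    match_counts = np.zeros((m, 20))
    cm = np.zeros((m + 1, 3))  # from M_k
    ci = np.zeros((m + 1, 2))  # from I_k
    cd = np.zeros((m + 1, 2))  # from D_k

    for row in alignment.rows:
        prev = ("M", 0)  # begin
        for col0, aa in enumerate(row):
            flag = match_flags[col0]
            if flag:
                k = node_of_col[col0]
                cur = ("M", k) if aa != GAP else ("D", k)
                if aa not in (GAP, "X"):
                    match_counts[k - 1, _AA_INDEX[aa]] += 1
            else:
                if aa == GAP:
                    continue
                cur = ("I", prev[1] if prev[0] != "D" else None)
                if cur[1] is None:  # D -> I: unrepresentable, skip the residue
                    continue
            _count_transition(cm, ci, cd, prev, cur)
            prev = cur
        _count_transition(cm, ci, cd, prev, ("M", m + 1))  # into the end state

    match_emissions = match_counts + w * background
    sums = match_emissions.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0.0  # only possible at w == 0 with all-X/gap columns
    match_emissions[zero] = background
    sums[zero] = 1.0
    match_emissions /= match_emissions.sum(axis=1, keepdims=True)

    t_match = _normalize_transitions(cm, w, last_forbidden=2)
    t_insert = _normalize_transitions(ci, w, last_forbidden=None)
    t_delete = _normalize_transitions(cd, w, last_forbidden=1)
    t_delete[0] = (1.0, 0.0)  # D_0 does not exist

    insert_emissions = np.tile(background, (m + 1, 1))
    return ProfileHMM(
        name=name,
        substrate=substrate,
        subgroup_index=subgroup_index,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        t_match=t_match,
        t_insert=t_insert,
        t_delete=t_delete,
        background=background,
        members=tuple(alignment.ids),
    )


def _count_transition(cm, ci, cd, prev, cur) -> None:
    state, k = prev
    if state == "M":
        slot = {("M", k + 1): 0, ("I", k): 1, ("D", k + 1): 2}.get(cur)
        table = cm
    elif state == "I":
        slot = {("M", k + 1): 0, ("I", k): 1}.get(cur)
        table = ci
    else:
        slot = {("M", k + 1): 0, ("D", k + 1): 1}.get(cur)
        table = cd
    if slot is None:  # I->D (or any other unrepresentable hop): dropped
        return
    table[k, slot] += 1


def _normalize_transitions(counts: np.ndarray, w: float, last_forbidden: int | None) -> np.ndarray:
    out = counts + w
    if last_forbidden is not None:
        out[-1, last_forbidden] = 0.0
    sums = out.sum(axis=1, keepdims=True)
    fallback = sums[:, 0] == 0.0  # w == 0 and an unvisited state: default to ->M
    out[fallback, 0] = 1.0
    return out / out.sum(axis=1, keepdims=True)


def _emission_bits(emissions: np.ndarray, background: np.ndarray) -> list[list[float]]:
    with np.errstate(divide="ignore"):
        table = np.log2(emissions) - np.log2(background)
    return table.tolist()


def viterbi_bits(hmm: ProfileHMM, sequence: DomainSequence | str) -> ScoreResult:
    """Best-path log-odds score of a sequence under the profile, in bits.

    Global dynamic program over match/insert/delete states; emissions score
    ``log2(p / background)`` (0 for the ambiguity code X), transitions score
    ``log2(p)``.
    """
    residues = sequence if isinstance(sequence, str) else sequence.residues
    if not residues:
        raise ValueError("cannot score an empty sequence")
    x = [_AA_INDEX.get(aa) for aa in residues]  # None for X
    length = len(x)
    m = hmm.match_count

    em = _emission_bits(hmm.match_emissions, hmm.background)
    ei = _emission_bits(hmm.insert_emissions, hmm.background)
    with np.errstate(divide="ignore"):
        tm = np.log2(np.where(hmm.t_match > 0, hmm.t_match, np.nan))
        ti = np.log2(np.where(hmm.t_insert > 0, hmm.t_insert, np.nan))
        td = np.log2(np.where(hmm.t_delete > 0, hmm.t_delete, np.nan))
    tm = np.where(np.isnan(tm), _NEG_INF, tm).tolist()
    ti = np.where(np.isnan(ti), _NEG_INF, ti).tolist()
    td = np.where(np.isnan(td), _NEG_INF, td).tolist()

    # vm[k][i]: best score ending in M_k having emitted i residues (M_0 = begin)
    vm = [[_NEG_INF] * (length + 1) for _ in range(m + 1)]
    vi = [[_NEG_INF] * (length + 1) for _ in range(m + 1)]
    vd = [[_NEG_INF] * (length + 1) for _ in range(m + 1)]
    bm = [[0] * (length + 1) for _ in range(m + 1)]
    bi = [[0] * (length + 1) for _ in range(m + 1)]
    bd = [[0] * (length + 1) for _ in range(m + 1)]
    vm[0][0] = 0.0

    for k in range(m + 1):
        row_em = em[k - 1] if k >= 1 else None
        for i in range(length + 1):
            if k >= 1:
                if i >= 1:
                    cands = (
                        vm[k - 1][i - 1] + tm[k - 1][0],
                        vi[k - 1][i - 1] + ti[k - 1][0],
                        vd[k - 1][i - 1] + td[k - 1][0],
                    )
                    best = max(cands)
                    if best > _NEG_INF:
                        aa = x[i - 1]
                        vm[k][i] = best + (row_em[aa] if aa is not None else 0.0)
                        bm[k][i] = cands.index(best)
                cands = (vm[k - 1][i] + tm[k - 1][2], vd[k - 1][i] + td[k - 1][1])
                best = max(cands)
                if best > _NEG_INF:
                    vd[k][i] = best
                    bd[k][i] = cands.index(best)
            if i >= 1:
                cands = (vm[k][i - 1] + tm[k][1], vi[k][i - 1] + ti[k][1])
                best = max(cands)
                if best > _NEG_INF:
                    aa = x[i - 1]
                    vi[k][i] = best + (ei[k][aa] if aa is not None else 0.0)
                    bi[k][i] = cands.index(best)

    finals = (
        vm[m][length] + tm[m][0],
        vi[m][length] + ti[m][0],
        vd[m][length] + td[m][0],
    )
    bits = max(finals)
    if math.isfinite(bits):
        path_length = _trace_path_length(finals.index(bits), m, length, bm, bi, bd)
    else:  # no legal path (possible only for unsmoothed models)
        path_length = 0
    raw = bits * _LN2 if math.isfinite(bits) else bits
    return ScoreResult(
        model_name=hmm.name,
        substrate=hmm.substrate,
        bit_score=bits,
        raw_log_odds=raw,
        path_length=path_length,
    )


def _trace_path_length(final_state: int, m: int, length: int, bm, bi, bd) -> int:
    state, k, i = ("M", "I", "D")[final_state], m, length
    count = 0
    while not (state == "M" and k == 0):
        count += 1
        if state == "M":
            choice = bm[k][i]
            k, i = k - 1, i - 1
            state = ("M", "I", "D")[choice]
        elif state == "I":
            choice = bi[k][i]
            i -= 1
            state = ("M", "I")[choice]
        else:
            choice = bd[k][i]
            k -= 1
            state = ("M", "D")[choice]
    return count


def score_all(library, sequence: DomainSequence | str) -> list[ScoreResult]:
    """Score a sequence with every model in a library, best first.

    Sorting is stable and ties are broken by model name, so the result is
    deterministic.
    """
    if not library.models:
        raise ValueError("empty model library")
    results = [viterbi_bits(model, sequence) for model in library.models]
    return sorted(results, key=lambda r: (-r.bit_score, r.model_name))
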