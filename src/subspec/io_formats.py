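"""Readers, writers and core record types.

Everything the tool exchanges with the outside world passes through here:
FASTA and aligned FASTA for domain sequences, a tab-separated annotation
table linking sequence ids to substrate codes, Newick for guide trees, and
a plain-text serialization of profile-HMM libraries.

Substrate codes are case-insensitive on input and canonicalized to the
registered spelling on output.  The ambiguity code ``X`` is accepted in
sequences (it is scored neutrally downstream); ``B``, ``Z`` and ``U`` are
rejected because curated domain sets do not contain them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a domain sequence (the 20 standard letters plus X)
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"

MODEL_LIBRARY_FORMAT_VERSION = "subspec-hmm-library v1"


class FormatError(ValueError):
    """Raised for any malformed external input."""


# ---------------------------------------------------------------------------
# core record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainSequence:
    """One A or AT domain protein sequence with optional substrate label."""

    id: str
    residues: str
    domain_type: str  # "A" or "AT"
    substrate: str | None = None
    redundant: bool = False
    source_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.domain_type not in ("A", "AT"):
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if GAP in self.residues or "." in self.residues:
            raise ValueError(
                f"gap character in unaligned input (sequence {self.id!r})"
            )
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in VALID_RESIDUES:
                raise ValueError(
                    f"invalid residue {aa!r} at position {pos} of sequence "
                    f"{self.id!r} (allowed: 20 standard amino acids and X)"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SubstrateVocabulary:
    """Controlled vocabulary of substrate codes for one domain type.

    ``codes`` maps the canonical spelling to a human-readable long name.
    Lookup is case-insensitive; :meth:`canonicalize` returns the registered
    spelling.
    """

    domain_type: str
    codes: dict[str, str]
    _folded: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for code in self.codes:
            key = code.casefold()
            if key in folded:
                raise ValueError(f"substrate code {code!r} duplicated after case folding")
            folded[key] = code
        object.__setattr__(self, "_folded", folded)

    def __contains__(self, code: str) -> bool:
        return code.casefold() in self._folded

    def canonicalize(self, code: str) -> str:
        try:
            return self._folded[code.casefold()]
        except KeyError:
            raise KeyError(f"unknown substrate code {code!r} for domain type {self.domain_type}") from None

    def long_name(self, code: str) -> str:
        return self.codes[self.canonicalize(code)]

    @classmethod
    def from_codes(cls, domain_type: str, codes: Iterable[str]) -> "SubstrateVocabulary":
        """An open vocabulary where every long name equals its code (synthetic data)."""
        return cls(domain_type, {c: c for c in codes})


#: acyl-CoA extender/starter units loaded by PKS acyl-transferase domains
AT_VOCABULARY = SubstrateVocabulary(
    "AT",
    {
        "MC": "malonyl-CoA",
        "MMC": "methylmalonyl-CoA",
        "EMC": "ethylmalonyl-CoA",
        "MOMC": "methoxymalonyl-CoA",
        "PC": "propionyl-CoA",
        "IBuC": "isobutyryl-CoA",
        "2MBuC": "2-methylbutyryl-CoA",
        "3MbuC": "3-methylbutyryl-CoA",
        "BzC": "benzoyl-CoA",
        "AC": "acetyl-CoA",
        "CH": "cyclohexanecarbonyl-CoA",
        "CP": "cyclopentanecarbonyl-CoA",
    },
)

#: amino-acid substrates activated by NRPS adenylation domains; proteinogenic
#: residues use the lower-case three-letter code
A_VOCABULARY = SubstrateVocabulary(
    "A",
    {
        "ala": "alanine", "arg": "arginine", "asn": "asparagine",
        "asp": "aspartate", "cys": "cysteine", "gln": "glutamine",
        "glu": "glutamate", "gly": "glycine", "his": "histidine",
        "ile": "isoleucine", "leu": "leucine", "lys": "lysine",
        "met": "methionine", "phe": "phenylalanine", "pro": "proline",
        "ser": "serine", "thr": "threonine", "trp": "tryptophan",
        "tyr": "tyrosine", "val": "valine",
        "aad": "2-amino-adipic acid",
        "abu": "2-amino-butyric acid",
        "allo-thr": "allo-threonine",
        "b-ala": "beta-alanine",
        "bht": "beta-hydroxy-tyrosine",
        "b-lys": "beta-lysine",
        "bmt": "(4R)-4[(E)-2-butenyl]-4-methyl-L-threonine",
        "dab": "2,4-diamino-butyric acid",
        "dhab": "2,3-dehydroaminobutyric acid",
        "dhb": "2,3-dihydroxy-benzoic acid",
        "dhpg": "3,5-dihydroxy-phenyl-glycine",
        "dpg": "3,5-dihydroxy-phenyl-glycine (dpg)",
        "dht": "dehydro-threonine",
        "fN5H-orn": "N5-formyl-N5-hydroxyornithine",
        "horn": "N5-hydroxyornithine",
        "hpg": "4-hydroxy-phenyl-glycine",
        "hpg2Cl": "3,5-dichloro-4-hydroxy-L-phenylglycine",
        "hyv-d": "D-hydroxyisovalerate",
        "iva": "isovaline",
        "masp": "methyl-aspartate",
        "me-asp": "methyl-aspartate (me-asp)",
        "mpro": "methyl-proline",
        "me-pro": "methyl-proline (me-pro)",
        "orn": "ornithine",
        "pheac": "phenylacetate",
        "phe-ac": "phenylacetate (phe-ac)",
        "pip": "pipecolic acid",
        "sal": "salicylic acid",
        "sar": "sarcosine",
    },
)

VOCABULARIES = {"A": A_VOCABULARY, "AT": AT_VOCABULARY}


@dataclass(frozen=True)
class AnnotationRow:
    seq_id: str
    substrate: str
    domain_type: str
    redundant: bool


@dataclass
class AnnotationTable:
    """Per-sequence substrate labels and redundancy flags."""

    rows: list[AnnotationRow]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.seq_id in seen:
                raise FormatError(f"duplicate annotation for sequence id {row.seq_id!r}")
            seen.add(row.seq_id)
        self._by_id = {row.seq_id: row for row in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, seq_id: str) -> AnnotationRow:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def substrate_of(self, seq_id: str) -> str:
        return self._by_id[seq_id].substrate

    def members(self, substrate: str, *, non_redundant_only: bool = False) -> list[str]:
        return [
            r.seq_id
            for r in self.rows
            if r.substrate == substrate and not (non_redundant_only and r.redundant)
        ]

    def substrates(self) -> list[str]:
        out: list[str] = []
        for r in self.rows:
            if r.substrate not in out:
                out.append(r.substrate)
        return out


@dataclass
class MultipleAlignment:
    """Gapped sequence rows over a fixed column count.

    Columns are addressed 1-based throughout the package, matching the way
    alignment positions are quoted in the literature.
    """

    ids: list[str]
    rows: list[str]
    warning: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate alignment ids: {', '.join(dupes)}")
        if self.rows:
            n = len(self.rows[0])
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != n]
            if ragged:
                raise FormatError(
                    "alignment rows have unequal lengths; offending ids: "
                    + ", ".join(ragged)
                )
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col`` across all rows."""
        return "".join(r[col - 1] for r in self.rows)

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        return MultipleAlignment(list(ids), [self.row(i) for i in ids])

    def slice_columns(self, cols: Sequence[int]) -> "MultipleAlignment":
        """New alignment keeping only the given 1-based columns, in the given order."""
        return MultipleAlignment(
            list(self.ids), ["".join(r[c - 1] for c in cols) for r in self.rows]
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, domain_type: str) -> list[DomainSequence]:
    """Read unaligned domain sequences from a FASTA file.

    Ids are the header token up to the first whitespace; residues are
    upper-cased.  Gap characters, duplicate ids and non-amino-acid letters
    (other than X) are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    seen: set[str] = set()
    out: list[DomainSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        try:
            out.append(DomainSequence(rec.id, residues, domain_type))
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
    return out


def write_fasta(sequences: Iterable[DomainSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file; all records must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    return MultipleAlignment(ids, rows)


def write_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=seq_id, description="")
        for seq_id, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

_ANNOTATION_HEADER = ["seq_id", "substrate", "domain_type", "redundant"]


def read_annotation(
    path: str | Path, vocabulary: SubstrateVocabulary | None = None
) -> AnnotationTable:
    """Read a tab-separated annotation table (seq_id, substrate, domain_type, redundant).

    When a vocabulary is given, substrate codes are validated against it and
    canonicalized; unknown codes are hard errors.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANNOTATION_HEADER:
            raise FormatError(
                f"bad annotation header {header!r}; expected {_ANNOTATION_HEADER!r}"
            )
        rows: list[AnnotationRow] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            seq_id, substrate, domain_type, redundant = parts
            if domain_type not in ("A", "AT"):
                raise FormatError(f"{path}:{lineno}: unknown domain type {domain_type!r}")
            if redundant not in ("0", "1", "true", "false"):
                raise FormatError(f"{path}:{lineno}: bad redundancy flag {redundant!r}")
            if vocabulary is not None:
                try:
                    substrate = vocabulary.canonicalize(substrate)
                except KeyError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc.args[0]}") from exc
            rows.append(
                AnnotationRow(seq_id, substrate, domain_type, redundant in ("1", "true"))
            )
    return AnnotationTable(rows)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ANNOTATION_HEADER) + "\n")
        for row in table.rows:
            fh.write(
                f"{row.seq_id}\t{row.substrate}\t{row.domain_type}\t"
                f"{1 if row.redundant else 0}\n"
            )


def cross_validate_annotation(
    table: AnnotationTable, sequences: Sequence[DomainSequence]
) -> None:
    """Check that every annotated id resolves against the loaded sequence set."""
    have = {s.id for s in sequences}
    missing = [r.seq_id for r in table.rows if r.seq_id not in have]
    if missing:
        raise FormatError(
            "annotation references unknown sequence ids: " + ", ".join(missing[:10])
        )


# ---------------------------------------------------------------------------
# Newick trees (thin dendropy wrappers so callers share one taxon convention)
# ---------------------------------------------------------------------------


def read_newick(path: str | Path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# model library serialization
# ---------------------------------------------------------------------------


def _fmt_floats(values) -> str:
    return " ".join(repr(float(v)) for v in values)


def write_model_library(library, path: str | Path) -> None:
    """Serialize a model library as documented plain text, one block per model.

    The format round-trips every probability at full precision (floats are
    written with ``repr``).
    """
    models = library.models
    if not models:
        raise ValueError("refusing to write an empty model library")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate model names: {', '.join(dupes)}")
    buf = io.StringIO()
    buf.write(MODEL_LIBRARY_FORMAT_VERSION + "\n")
    buf.write(f"DOMAIN_TYPE {library.domain_type}\n")
    buf.write(f"MODE {library.mode}\n")
    buf.write(f"THRESHOLD_BITS {library.threshold_bits!r}\n")
    buf.write(f"MODELS {len(models)}\n")
    for m in models:
        buf.write(f"MODEL {m.name}\n")
        buf.write(f"SUBSTRATE {m.substrate}\n")
        buf.write(f"SUBGROUP {m.subgroup_index}\n")
        buf.write("MEMBERS " + " ".join(m.members) + "\n")
        buf.write(f"M {m.match_count}\n")
        buf.write(f"BACKGROUND {_fmt_floats(m.background)}\n")
        for k in range(m.match_count):
            buf.write(f"MATCH {k + 1} {_fmt_floats(m.match_emissions[k])}\n")
        for k in range(m.match_count + 1):
            buf.write(f"INSERT {k} {_fmt_floats(m.insert_emissions[k])}\n")
        for k in range(m.match_count + 1):
            buf.write(f"TRANSM {k} {_fmt_floats(m.t_match[k])}\n")
        for k in range(m.match_count + 1):
            buf.write(f"TRANSI {k} {_fmt_floats(m.t_insert[k])}\n")
        for k in range(m.match_count + 1):
            buf.write(f"TRANSD {k} {_fmt_floats(m.t_delete[k])}\n")
        buf.write("END\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_model_library(path: str | Path):
    import numpy as np

    from .classifier import ModelLibrary
    from .profile_hmm import ProfileHMM

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != MODEL_LIBRARY_FORMAT_VERSION:
        got = lines[0] if lines else "<empty file>"
        raise FormatError(
            f"model library version mismatch: expected "
            f"{MODEL_LIBRARY_FORMAT_VERSION!r}, got {got!r}"
        )
    it = iter(lines[1:])

    def expect(keyword: str) -> str:
        line = next(it)
        if not line.startswith(keyword + " "):
            raise FormatError(f"expected {keyword!r} line, got {line!r}")
        return line[len(keyword) + 1 :]

    domain_type = expect("DOMAIN_TYPE")
    mode = expect("MODE")
    threshold = float(expect("THRESHOLD_BITS"))
    n_models = int(expect("MODELS"))
    models = []
    for _ in range(n_models):
        name = expect("MODEL")
        substrate = expect("SUBSTRATE")
        subgroup = int(expect("SUBGROUP"))
        members = tuple(expect("MEMBERS").split())
        m_count = int(expect("M"))
        background = np.array([float(x) for x in expect("BACKGROUND").split()])

        def read_block(keyword: str, n_rows: int, first_index: int):
            out = []
            for k in range(n_rows):
                parts = expect(keyword).split()
                if int(parts[0]) != k + first_index:
                    raise FormatError(f"{keyword} rows out of order near {name!r}")
                out.append([float(x) for x in parts[1:]])
            return np.array(out)

        match_emissions = read_block("MATCH", m_count, 1)
        insert_emissions = read_block("INSERT", m_count + 1, 0)
        t_match = read_block("TRANSM", m_count + 1, 0)
        t_insert = read_block("TRANSI", m_count + 1, 0)
        t_delete = read_block("TRANSD", m_count + 1, 0)
        if next(it) != "END":
            raise FormatError(f"missing END after model {name!r}")
        models.append(
            ProfileHMM(
                name=name,
                substrate=substrate,
                subgroup_index=subgroup,
                match_emissions=match_emissions,
                insert_emissions=insert_emissions,
                t_match=t_match,
                t_insert=t_insert,
                t_delete=t_delete,
                background=background,
                members=members,
            )
        )
    return ModelLibrary(
        domain_type=domain_type, models=models, mode=mode, threshold_bits=threshold
    )
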