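"""Peptide data model and position-wise TAA-MoA comparison.

Tumor-associated antigens (TAAs) of the cancer-testis family (MAGE, SSX)
are HLA-A*02:01-restricted nonamers.  A microbiota-derived antigen (MoA)
mimics a TAA when the two sequences are identical or differ at one or two
positions, typically by residues of the same chemical class.  This module
holds the peptide types, the position-wise comparison, and the chemical
classification of substitutions (identity / conservative / non-conservative,
mirroring the green / orange / red annotation used for mimic tables).

Positions are 1-based throughout, matching the convention used when a
substitution is reported "at position 7" of a nonamer.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Default chemical-class partition of the 20 residues.  Each residue
#: belongs to exactly one class; a substitution within a class is
#: "conservative".
DEFAULT_CLASSES: dict[str, str] = {
    **{aa: "aliphatic-hydrophobic" for aa in "AVLIMC"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar-uncharged" for aa in "STNQ"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "GP"},
}


class Source(str, enum.Enum):
    """Origin of a peptide in the screening library."""

    TAA = "TAA"
    MOA = "MoA"
    VIRAL = "viral_control"


class SubstitutionKind(str, enum.Enum):
    IDENTITY = "identity"
    CONSERVATIVE = "conservative"
    NON_CONSERVATIVE = "non_conservative"


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    if sequence != sequence.upper():
        warnings.warn(
            f"lowercase residues in {sequence!r} upper-cased", stacklevel=3
        )
        sequence = sequence.upper()
    for ch in sequence:
        if ch not in _AA_SET:
            raise ValueError(
                f"invalid amino-acid symbol {ch!r} in sequence {sequence!r}"
            )
    return sequence


@dataclass(frozen=True)
class Peptide:
    """A peptide over the canonical 20-letter amino-acid alphabet.

    The data model accepts any length; pipeline stages that assume
    nonamers check the length themselves.
    """

    sequence: str
    name: str = ""
    source: Source = Source.MOA
    organism: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass(frozen=True)
class ClassScheme:
    """A total partition of the amino-acid alphabet into chemical classes."""

    mapping: Mapping[str, str]
    name: str = "default-6-class"

    def __post_init__(self) -> None:
        missing = _AA_SET - set(self.mapping)
        extra = set(self.mapping) - _AA_SET
        if missing or extra:
            raise ValueError(
                f"class scheme must map exactly the 20 residues; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def class_of(self, residue: str) -> str:
        if residue not in self.mapping:
            raise ValueError(f"residue {residue!r} outside the amino-acid alphabet")
        return self.mapping[residue]

    def same_class(self, a: str, b: str) -> bool:
        return self.class_of(a) == self.class_of(b)

    def to_dict(self) -> dict[str, str]:
        """Serializable form, so classifications are reproducible."""
        return {"name": self.name, **{aa: self.mapping[aa] for aa in AMINO_ACIDS}}


DEFAULT_SCHEME = ClassScheme(DEFAULT_CLASSES)


class Blosum62Scheme:
    """Alternative conservative rule: BLOSUM62 score >= 0.

    Not a partition; exposes the same ``same_class``/``class_of`` duck
    interface used by :func:`classify_substitution`.
    """

    name = "blosum62-nonnegative"

    def __init__(self) -> None:
        from Bio.Align import substitution_matrices

        self._matrix = substitution_matrices.load("BLOSUM62")

    def class_of(self, residue: str) -> str:
        if residue not in _AA_SET:
            raise ValueError(f"residue {residue!r} outside the amino-acid alphabet")
        return residue  # no discrete classes; pairwise rule only

    def same_class(self, a: str, b: str) -> bool:
        if a not in _AA_SET or b not in _AA_SET:
            bad = a if a not in _AA_SET else b
            raise ValueError(f"residue {bad!r} outside the amino-acid alphabet")
        return float(self._matrix[a, b]) >= 0

    def to_dict(self) -> dict[str, str]:
        return {"name": self.name}


@dataclass(frozen=True)
class SubstitutionRecord:
    """One aligned position of a TAA/MoA pair."""

    position: int  # 1-based
    taa_residue: str
    moa_residue: str
    kind: SubstitutionKind

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if (self.kind == SubstitutionKind.IDENTITY) != (
            self.taa_residue == self.moa_residue
        ):
            raise ValueError("kind 'identity' iff residues are equal")


def classify_substitution(
    taa_residue: str, moa_residue: str, scheme: ClassScheme = DEFAULT_SCHEME
) -> SubstitutionKind:
    """Classify an aligned residue pair.

    identity if equal; conservative if different but in the same chemical
    class of ``scheme``; non_conservative otherwise.
    """
    for res in (taa_residue, moa_residue):
        scheme.class_of(res)  # raises on invalid residue
    if taa_residue == moa_residue:
        return SubstitutionKind.IDENTITY
    if scheme.same_class(taa_residue, moa_residue):
        return SubstitutionKind.CONSERVATIVE
    return SubstitutionKind.NON_CONSERVATIVE


def positional_diff(
    taa: Peptide | str,
    moa: Peptide | str,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> list[SubstitutionRecord]:
    """Positions (1-based, ascending) at which two equal-length peptides differ.

    Returns non-identity records only; an empty list iff the sequences are
    identical.  Raises on a length mismatch (never truncates) and on any
    symbol outside the 20-letter alphabet.
    """
    ts = taa.sequence if isinstance(taa, Peptide) else _validate_sequence(taa)
    ms = moa.sequence if isinstance(moa, Peptide) else _validate_sequence(moa)
    if len(ts) != len(ms):
        raise ValueError(
            f"length mismatch: {len(ts)} vs {len(ms)} ({ts!r} vs {ms!r})"
        )
    records = []
    for i, (a, b) in enumerate(zip(ts, ms), start=1):
        if a != b:
            records.append(
                SubstitutionRecord(i, a, b, classify_substitution(a, b, scheme))
            )
    return records


@dataclass(frozen=True)
class EpitopePair:
    """A TAA nonamer paired with a candidate MoA mimic."""

    taa: Peptide
    moa: Peptide
    substitutions: tuple[SubstitutionRecord, ...] = field(default=())
    scheme: ClassScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if len(self.taa) != len(self.moa):
            raise ValueError("TAA and MoA must have equal length")
        if not self.substitutions:
            object.__setattr__(
                self,
                "substitutions",
                tuple(positional_diff(self.taa, self.moa, self.scheme)),
            )

    @property
    def hamming(self) -> int:
        return sum(
            1 for r in self.substitutions if r.kind != SubstitutionKind.IDENTITY
        )

    @property
    def n_identical(self) -> int:
        return len(self.taa) - self.hamming


def pair_report(pair: EpitopePair, scheme: ClassScheme | None = None) -> dict:
    """Per-position annotation of an epitope pair.

    ``flag`` mirrors the mimic-table color legend: identical positions
    "green", conservative substitutions "orange", non-conservative "red".
    """
    scheme = scheme or pair.scheme
    flags = {
        SubstitutionKind.IDENTITY: "green",
        SubstitutionKind.CONSERVATIVE: "orange",
        SubstitutionKind.NON_CONSERVATIVE: "red",
    }
    positions = []
    subs = {r.position: r for r in positional_diff(pair.taa, pair.moa, scheme)}
    for i in range(1, len(pair.taa) + 1):
        rec = subs.get(i)
        kind = rec.kind if rec else SubstitutionKind.IDENTITY
        positions.append(
            {
                "position": i,
                "taa_residue": pair.taa.sequence[i - 1],
                "moa_residue": pair.moa.sequence[i - 1],
                "kind": kind.value,
                "flag": flags[kind],
            }
        )
    return {
        "taa": pair.taa.name or pair.taa.sequence,
        "moa": pair.moa.name or pair.moa.sequence,
        "n_identical": pair.n_identical,
        "hamming": pair.hamming,
        "substitution_positions": sorted(subs),
        "positions": positions,
        "scheme": scheme.to_dict(),
    }


# ---------------------------------------------------------------------------
# The study's printed peptide table: the seven HLA-A*02:01 cancer-testis
# TAA nonamers and the eleven mimic sequences printed alongside them
# (organism of origin where reported).  MoA labels follow the
# <TAA>-<FIRM|BACT><n> convention (FIRM = Firmicutes, BACT = Bacteroidetes).

STUDY_TAAS: dict[str, Peptide] = {
    name: Peptide(seq, name=name, source=Source.TAA, organism="Homo sapiens")
    for name, seq in [
        ("MAGE-A1", "KVLEYVIKV"),
        ("MAGE-A3", "KVAELVHFL"),
        ("MAGE-A3/12", "FLWGPRALV"),
        ("MAGE-A10", "GLYDGMEHL"),
        ("MAGE-C1", "KVVEFLAML"),
        ("MAGE-C2", "ALKDVEERV"),
        ("SSX2", "KASEKIFYV"),
    ]
}

#: Printed mimics: label -> (TAA name, sequence, source organism).
STUDY_MOAS: dict[str, Peptide] = {
    name: Peptide(seq, name=name, source=Source.MOA, organism=org)
    for name, taa, seq, org in [
        ("A1-MIM1", "MAGE-A1", "KVLEYVTKV", "Staphylococcus pettenkoferi"),
        ("A1-FIRM4", "MAGE-A1", "KVLEYIIKI", "Tissierellales"),
        ("A3-MIM1", "MAGE-A3", "KIAELVHFL", "Sedimentibacter sp."),
        ("A3/12-MIM1", "MAGE-A3/12", "FLWGPKALV", "Chitinophagaceae bacterium"),
        ("A3/12-BACT1", "MAGE-A3/12", "FLWGSIALV", "Bacteroidales"),
        ("A10-MIM1", "MAGE-A10", "GLYDGMEYI", "Clostridium kluyveri"),
        ("C1-MIM1", "MAGE-C1", "KTVEFLAMV", "Lachnospiraceae bacterium"),
        ("C2-MIM1", "MAGE-C2", "ALSDVEERV", "Loigolactobacillus jiayinensis"),
        ("C2-FIRM3", "MAGE-C2", "ALKDVEEPV", "Eubacterium sp."),
        ("SSX2-MIM1", "SSX2", "KVSEKIFYL", "Flavobacterium sp. CG_9.1"),
        ("SSX2-BACT2", "SSX2", "KAYEKIFYV", "Bacteroidaceae"),
    ]
}

#: MoA label -> TAA name (homology-group membership of the printed mimics).
STUDY_MOA_GROUPS: dict[str, str] = {
    "A1-MIM1": "MAGE-A1",
    "A1-FIRM4": "MAGE-A1",
    "A3-MIM1": "MAGE-A3",
    "A3/12-MIM1": "MAGE-A3/12",
    "A3/12-BACT1": "MAGE-A3/12",
    "A10-MIM1": "MAGE-A10",
    "C1-MIM1": "MAGE-C1",
    "C2-MIM1": "MAGE-C2",
    "C2-FIRM3": "MAGE-C2",
    "SSX2-MIM1": "SSX2",
    "SSX2-BACT2": "SSX2",
}


# ---------------------------------------------------------------------------
# I/O

def read_peptides_csv(path) -> list[Peptide]:
    """Read peptides from CSV with columns name,sequence,source,organism."""
    peptides = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "sequence", "source"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"peptide CSV needs header columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            peptides.append(
                Peptide(
                    row["sequence"].strip(),
                    name=row["name"].strip(),
                    source=Source(row["source"].strip()),
                    organism=(row.get("organism") or "").strip() or None,
                )
            )
    return peptides


def read_peptides_fasta(path, source: Source = Source.MOA) -> list[Peptide]:
    """Read peptides from FASTA (name taken from the record id)."""
    from Bio import SeqIO

    return [
        Peptide(str(rec.seq), name=rec.id, source=source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_peptides_csv(peptides: Iterable[Peptide], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "sequence", "source", "organism"])
        for p in peptides:
            writer.writerow([p.name, p.sequence, p.source.value, p.organism or ""])
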