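"""Exhaustive nonamer scanning of protein sequences for TAA-homologous windows.

Because the epitope model is a fixed-length, gap-free nonamer, homology
search reduces to exact enumeration: every length-9 window of every
protein is compared position-by-position against the query, and windows
with at least ``min_identical`` identical residues are reported together
with their conservative-substitution counts.  No heuristics, E-values or
gapped alignment are involved.

The module also builds position frequency matrices ("sequence logos") over
mimic sets and derives their consensus sequence: information content per
position is IC(p) = log2(20) - H(p) bits, with H the Shannon entropy of the
raw residue frequencies, and symbol height = frequency x IC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .peptides import (
    AMINO_ACIDS,
    ClassScheme,
    DEFAULT_SCHEME,
    Peptide,
    Source,
)

logger = logging.getLogger(__name__)

#: Ambiguity codes occasionally present in protein databases; windows
#: containing any of them are skipped (they have no chemical class).
AMBIGUOUS_RESIDUES = frozenset("XBZUO*")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with minimal provenance labels."""

    id: str
    sequence: str
    organism: str = ""
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set(AMINO_ACIDS) - AMBIGUOUS_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r} has invalid symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MimicryHit:
    """A window of a protein scored against a query nonamer.

    ``score = n_identical + w * n_conservative`` is reporting-only; the
    hit gate is ``n_identical >= min_identical``.
    """

    protein_id: str
    window_start: int  # 1-based offset of the window in the protein
    window_peptide: Peptide
    n_identical: int
    n_conservative: int
    score: float
    organism: str = ""


def _encode(seq: str) -> np.ndarray:
    """Map residues to 0..19, ambiguity codes to -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq):
        out[i] = _AA_INDEX.get(ch, -1)
    return out


def _class_codes(scheme: ClassScheme) -> np.ndarray:
    labels = {}
    codes = np.empty(20, dtype=np.int8)
    for aa, i in _AA_INDEX.items():
        cls = scheme.class_of(aa)
        codes[i] = labels.setdefault(cls, len(labels))
    return codes


def scan_proteins(
    query: Peptide | str,
    proteins: Iterable[ProteinRecord],
    min_identical: int = 6,
    scheme: ClassScheme = DEFAULT_SCHEME,
    conservative_weight: float = 0.5,
) -> list[MimicryHit]:
    """Exhaustively scan proteins for windows homologous to ``query``.

    Every length-9 window with at least ``min_identical`` identical
    residues is returned; windows containing ambiguous residues are
    skipped and counted in a log summary.  Hits are sorted by
    (score desc, protein_id, window_start), so the ordering is
    deterministic.
    """
    qseq = query.sequence if isinstance(query, Peptide) else Peptide(query).sequence
    k = len(qseq)
    if k != 9:
        raise ValueError(f"query must be a nonamer, got length {k}")
    if not 0 <= min_identical <= 9:
        raise ValueError("min_identical must be in 0..9")

    q = _encode(qseq)
    cls = _class_codes(scheme)
    qcls = cls[q]
    hits: list[MimicryHit] = []
    n_skipped = 0
    for prot in proteins:
        enc = _encode(prot.sequence)
        if len(enc) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = (windows >= 0).all(axis=1)
        n_skipped += int((~valid).sum())
        ident = (windows == q).sum(axis=1)
        keep = valid & (ident >= min_identical)
        if not keep.any():
            continue
        wcls = np.where(windows >= 0, cls[np.clip(windows, 0, 19)], -1)
        conserv = ((windows != q) & (wcls == qcls)).sum(axis=1)
        for idx in np.flatnonzero(keep):
            n_id = int(ident[idx])
            n_cons = int(conserv[idx])
            window_seq = prot.sequence[idx : idx + k]
            hits.append(
                MimicryHit(
                    protein_id=prot.id,
                    window_start=int(idx) + 1,
                    window_peptide=Peptide(
                        window_seq,
                        name=f"{prot.id}:{idx + 1}",
                        source=Source.MOA,
                        organism=prot.organism or None,
                    ),
                    n_identical=n_id,
                    n_conservative=n_cons,
                    score=n_id + conservative_weight * n_cons,
                    organism=prot.organism,
                )
            )
    if n_skipped:
        logger.info("skipped %d windows containing ambiguous residues", n_skipped)
    hits.sort(key=lambda h: (-h.score, h.protein_id, h.window_start))
    return hits


# ---------------------------------------------------------------------------
# Sequence logos

@dataclass(frozen=True)
class LogoMatrix:
    """Position frequency matrix with per-position information content.

    ``frequencies`` has shape (length, 20), rows summing to 1 in the
    fixed column order of :data:`AMINO_ACIDS`; ``information`` holds
    IC(p) = log2(20) - H(p) in bits.
    """

    frequencies: np.ndarray
    information: np.ndarray
    n_sequences: int
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 2 or f.shape[1] != 20:
            raise ValueError("frequency matrix must be (length, 20)")
        if (f < 0).any() or not np.allclose(f.sum(axis=1), 1.0):
            raise ValueError("rows must be non-negative and sum to 1")
        ic = np.asarray(self.information, dtype=float)
        if (ic < -1e-9).any() or (ic > np.log2(20) + 1e-9).any():
            raise ValueError("information content must lie in [0, log2(20)]")

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def symbol_heights(self) -> np.ndarray:
        """Stack heights for rendering: frequency x information content."""
        return self.frequencies * self.information[:, None]


def build_logo(sequences: Sequence[Peptide | str]) -> LogoMatrix:
    """Position frequency matrix + information content from aligned peptides.

    Frequencies are raw counts / n, without pseudocounts or background
    correction; see :func:`build_logo_kl` for the background-corrected
    variant.
    """
    seqs = [s.sequence if isinstance(s, Peptide) else Peptide(s).sequence
            for s in sequences]
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must have equal length")
    counts = np.zeros((length, 20))
    for s in seqs:
        for p, ch in enumerate(s):
            counts[p, _AA_INDEX[ch]] += 1
    freqs = counts / len(seqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = np.clip(np.log2(20) - entropy, 0.0, np.log2(20))
    return LogoMatrix(freqs, information, n_sequences=len(seqs))


def build_logo_kl(
    sequences: Sequence[Peptide | str], background: np.ndarray | None = None
) -> LogoMatrix:
    """Kullback-Leibler background-corrected logo (off by default upstream).

    Per-position "information" is the KL divergence of the observed
    frequencies from ``background`` (uniform if not given), clipped into
    the [0, log2(20)] display range.
    """
    logo = build_logo(sequences)
    bg = np.full(20, 1 / 20) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    f = logo.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / bg), 0.0)
    kl = np.clip(terms.sum(axis=1), 0.0, np.log2(20))
    return LogoMatrix(f, kl, n_sequences=logo.n_sequences)


def consensus_sequence(logo: LogoMatrix) -> tuple[Peptide, list[bool]]:
    """Modal residue per position, with ambiguity flags for tied maxima.

    Ties are resolved alphabetically for the string form and flagged in
    the returned boolean list (True = tie at that position).
    """
    letters = []
    ambiguous = []
    for p in range(logo.length):
        row = logo.frequencies[p]
        top = row.max()
        tied = [logo.alphabet[i] for i in np.flatnonzero(np.isclose(row, top))]
        letters.append(min(tied))
        ambiguous.append(len(tied) > 1)
    return Peptide("".join(letters), name="consensus"), ambiguous


# ---------------------------------------------------------------------------
# I/O

def read_proteins_fasta(path) -> list[ProteinRecord]:
    """Read proteins from FASTA; organism parsed from ``[...]`` in the
    description when present (NCBI convention)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        organism = ""
        if "[" in desc and desc.rstrip().endswith("]"):
            organism = desc[desc.rindex("[") + 1 : desc.rindex("]")]
        records.append(ProteinRecord(rec.id, str(rec.seq), organism=organism))
    return records


def hits_to_frame(query: Peptide | str, hits: Sequence[MimicryHit]):
    """Hits as a DataFrame in the documented TSV column order."""
    import pandas as pd

    qseq = query.sequence if isinstance(query, Peptide) else query
    return pd.DataFrame(
        [
            {
                "query": qseq,
                "protein_id": h.protein_id,
                "organism": h.organism,
                "window_start": h.window_start,
                "window_peptide": h.window_peptide.sequence,
                "n_identical": h.n_identical,
                "n_conservative": h.n_conservative,
                "score": h.score,
            }
            for h in hits
        ],
        columns=[
            "query", "protein_id", "organism", "window_start",
            "window_peptide", "n_identical", "n_conservative", "score",
        ],
    )


def logo_to_frame(logo: LogoMatrix):
    """Logo as a positions x 20 DataFrame plus an IC column."""
    import pandas as pd

    df = pd.DataFrame(
        logo.frequencies,
        columns=list(logo.alphabet),
        index=pd.RangeIndex(1, logo.length + 1, name="position"),
    )
    df["IC"] = logo.information
    return df
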