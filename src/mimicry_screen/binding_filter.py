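"""Affinity/stability selection of candidate epitopes.

MHC binding predictions (affinity in nM, complex stability in hours) are
consumed as precomputed tables — this module never invokes a predictor.
The selection rule is the strong-binder gate used throughout the
screening design: predicted affinity strictly below 100 nM and, when
stability predictions are required, stability strictly above 1 h.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .peptides import Peptide

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^HLA-([A-Z]+\d*)\*?(\d{2}):?(\d{2})$")


def normalize_allele(allele: str) -> str:
    """Canonical HLA allele form, e.g. 'hla-a0201' -> 'HLA-A*02:01'."""
    s = allele.strip().upper().replace(" ", "")
    if not s.startswith("HLA-"):
        s = "HLA-" + s
    m = _ALLELE_RE.match(s)
    if not m:
        return s
    return f"HLA-{m.group(1)}*{m.group(2)}:{m.group(3)}"


@dataclass(frozen=True)
class BindingPrediction:
    """One (peptide, allele) prediction row."""

    peptide: Peptide
    allele: str
    affinity_nM: float
    stability_hours: float | None = None

    def __post_init__(self) -> None:
        if not self.affinity_nM > 0:
            raise ValueError(
                f"affinity must be positive, got {self.affinity_nM} "
                f"for {self.peptide.sequence}"
            )
        if self.stability_hours is not None and self.stability_hours < 0:
            raise ValueError("stability must be non-negative")
        object.__setattr__(self, "allele", normalize_allele(self.allele))


def select_candidates(
    predictions: list[BindingPrediction],
    affinity_cut_nM: float = 100.0,
    stability_cut_h: float = 1.0,
    require_stability: bool = True,
) -> list[BindingPrediction]:
    """Keep predictions with affinity < cut and (optionally) stability > cut.

    Both cuts are strict inequalities: a peptide at exactly 100 nM or
    exactly 1 h is dropped.  Input order is preserved; kept/dropped
    counts are logged.
    """
    if affinity_cut_nM <= 0 or stability_cut_h <= 0:
        raise ValueError("cuts must be positive")
    if require_stability:
        missing = [p.peptide.sequence for p in predictions
                   if p.stability_hours is None]
        if missing:
            raise ValueError(
                "stability required but missing for peptides: "
                + ", ".join(missing)
            )
    kept = [
        p
        for p in predictions
        if p.affinity_nM < affinity_cut_nM
        and (not require_stability or p.stability_hours > stability_cut_h)
    ]
    logger.info(
        "select_candidates: kept %d / %d (affinity < %g nM%s)",
        len(kept), len(predictions), affinity_cut_nM,
        f", stability > {stability_cut_h} h" if require_stability else "",
    )
    return kept


def library_summary(predictions: list[BindingPrediction]) -> dict:
    """Mean predicted affinity and the count of peptides below that mean."""
    if not predictions:
        raise ValueError("empty prediction table")
    affinities = [p.affinity_nM for p in predictions]
    mean = sum(affinities) / len(affinities)
    return {
        "mean_affinity_nM": mean,
        "n_below_mean": sum(1 for a in affinities if a < mean),
        "n_total": len(affinities),
    }


# ---------------------------------------------------------------------------
# I/O: TSV with columns peptide,allele,affinity_nM,stability_h

def read_predictions_tsv(path) -> list[BindingPrediction]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "affinity_nM"}
    if not required <= set(df.columns):
        raise ValueError(f"prediction TSV needs columns {sorted(required)}")
    rows = []
    for rec in df.itertuples(index=False):
        stab = getattr(rec, "stability_h", None)
        rows.append(
            BindingPrediction(
                Peptide(rec.peptide),
                rec.allele,
                float(rec.affinity_nM),
                None if stab is None or pd.isna(stab) else float(stab),
            )
        )
    return rows


def write_predictions_tsv(predictions: list[BindingPrediction], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "peptide": p.peptide.sequence,
                "allele": p.allele,
                "affinity_nM": p.affinity_nM,
                "stability_h": p.stability_hours,
            }
            for p in predictions
        ]
    ).to_csv(path, sep="\t", index=False)
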