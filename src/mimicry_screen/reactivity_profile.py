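"""Subject-level readouts: MoA-reactive, TAA-reactive and cross-reactive
CD8+ T-cell specificities.

The sorting scheme yields two sequencing samples per subject: a
single-stained fraction (cells binding one fluorochrome channel — MoA and
viral multimers) and a double-stained fraction (cells binding both
channels — TAA and potentially cross-reactive cells).  A subject is
cross-reactive for a homology group when the TAA and at least one of its
homologous MoAs are both called significant in the double-stained
fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .barcode_enrichment import Fraction, Group, ReadCountMatrix

@dataclass(frozen=True)
class HomologyGroup:
    """A TAA with its homologous MoA mimics (e.g. SSX2: SSX2-BACT1..3)."""

    taa: str
    moas: tuple[str, ...]


@dataclass
class SubjectProfile:
    """Per-subject significant specificities and their class breakdown.

    Percentages (when any response exists) partition the subject's
    total estimated reactive-cell frequency into the MoA, TAA and CROSS
    classes and sum to 100.
    """

    subject_id: str
    group: Group
    significant_moa: set[str] = field(default_factory=set)
    significant_taa: set[str] = field(default_factory=set)
    cross_pairs: set[tuple[str, str]] = field(default_factory=set)
    pct_moa: float | None = None
    pct_taa: float | None = None
    pct_cross: float | None = None


def _group_index(homology_groups: list[HomologyGroup]) -> dict[str, str]:
    """MoA name -> TAA name; raises if a MoA sits in two groups."""
    index: dict[str, str] = {}
    for g in homology_groups:
        for moa in g.moas:
            if moa in index and index[moa] != g.taa:
                raise ValueError(f"MoA {moa!r} mapped to two homology groups")
            index[moa] = g.taa
    return index


def classify_responses(
    results: pd.DataFrame,
    matrix: ReadCountMatrix,
    homology_groups: list[HomologyGroup],
) -> dict[str, SubjectProfile]:
    """Build per-subject profiles from per-(barcode, sample) calls.

    MoA responses are read from each subject's single-stained fraction,
    TAA responses from the double-stained fraction, and a cross pair
    (TAA, MoA) is recorded when both members of a homology group are
    significant in the double-stained fraction.  Barcodes whose antigen
    class is TAA but that belong to no homology group — or MoAs missing
    from every group — raise with the list of orphans.
    """
    if matrix.annotations is None:
        raise ValueError("barcode annotations are required")
    ann = matrix.annotations
    moa_to_taa = _group_index(homology_groups)
    known_taas = {g.taa for g in homology_groups}

    orphans = []
    for bc in ann.index:
        cls = ann.loc[bc, "antigen_class"]
        if cls == "TAA" and ann.loc[bc, "peptide"] not in known_taas and \
                bc not in known_taas:
            orphans.append(bc)
        elif cls == "MoA" and bc not in moa_to_taa:
            orphans.append(bc)
    if orphans:
        raise ValueError(f"barcodes with no homology-group mapping: {orphans}")

    sig = results.loc[results["significant"].astype(bool)]
    profiles: dict[str, SubjectProfile] = {}
    for meta in matrix.samples:
        if meta.group not in (Group.HS, Group.CP) or meta.subject_id is None:
            continue
        prof = profiles.setdefault(
            meta.subject_id, SubjectProfile(meta.subject_id, meta.group)
        )
        called = set(sig.loc[sig["sample_id"] == meta.sample_id, "barcode"])
        if meta.fraction == Fraction.SINGLE_STAINED:
            prof.significant_moa |= {
                bc for bc in called
                if ann.loc[bc, "antigen_class"] in ("MoA", "viral_control")
            }
        elif meta.fraction == Fraction.DOUBLE_STAINED:
            taas = {bc for bc in called if ann.loc[bc, "antigen_class"] == "TAA"}
            moas = {bc for bc in called if ann.loc[bc, "antigen_class"] == "MoA"}
            prof.significant_taa |= taas
            for moa in moas:
                taa = moa_to_taa[moa]
                if taa in taas:
                    prof.cross_pairs.add((taa, moa))
    return profiles


def fraction_percentages(
    profiles: dict[str, SubjectProfile],
    results: pd.DataFrame,
    matrix: ReadCountMatrix,
    weighting: str = "frequency",
) -> dict[str, SubjectProfile]:
    """Fill pct_moa / pct_taa / pct_cross per subject.

    Class weights are summed estimated T-cell frequencies of the class's
    significant specificities (``weighting="frequency"``) or plain
    specificity counts (``weighting="count"``).  Specificities in a
    cross pair (the TAA and its paired MoAs, double-stained fraction)
    form the CROSS class; remaining double-stained TAAs the TAA class;
    everything else (single-stained MoA/viral and unpaired double-
    stained MoAs) the MoA class.  A subject with no responses keeps the
    percentages as missing.
    """
    if weighting not in ("frequency", "count"):
        raise ValueError("weighting must be 'frequency' or 'count'")
    ann = matrix.annotations
    sample_of = {
        (s.subject_id, s.fraction): s.sample_id
        for s in matrix.samples
        if s.subject_id is not None
    }
    sig = results.loc[results["significant"].astype(bool)]

    def weight(sample_id: str, barcode: str) -> float:
        if weighting == "count":
            return 1.0
        row = sig[(sig["sample_id"] == sample_id) & (sig["barcode"] == barcode)]
        if row.empty:
            return 0.0
        freq = row["est_frequency_pct"].iloc[0]
        return 0.0 if freq is None or (isinstance(freq, float) and math.isnan(freq)) else float(freq)

    for prof in profiles.values():
        ss = sample_of.get((prof.subject_id, Fraction.SINGLE_STAINED))
        ds = sample_of.get((prof.subject_id, Fraction.DOUBLE_STAINED))
        cross_taas = {t for t, _ in prof.cross_pairs}
        cross_moas = {m for _, m in prof.cross_pairs}

        w_cross = sum(weight(ds, bc) for bc in cross_taas | cross_moas if ds)
        w_taa = sum(
            weight(ds, bc) for bc in prof.significant_taa - cross_taas if ds
        )
        w_moa = sum(weight(ss, bc) for bc in prof.significant_moa if ss)
        if ds is not None:
            ds_called = set(sig.loc[sig["sample_id"] == ds, "barcode"])
            ds_moas = {
                bc for bc in ds_called
                if ann is not None and ann.loc[bc, "antigen_class"] == "MoA"
            }
            w_moa += sum(weight(ds, bc) for bc in ds_moas - cross_moas)

        total = w_moa + w_taa + w_cross
        if total > 0:
            prof.pct_moa = 100.0 * w_moa / total
            prof.pct_taa = 100.0 * w_taa / total
            prof.pct_cross = 100.0 * w_cross / total
    return profiles


def cross_reactive_pairs(
    profiles: dict[str, SubjectProfile]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cohort-level table of (subject, group, TAA, MoA) cross pairs plus
    per-group counts of subjects with at least one pair."""
    rows = [
        {
            "subject_id": prof.subject_id,
            "group": prof.group.value,
            "taa": taa,
            "moa": moa,
        }
        for prof in profiles.values()
        for taa, moa in sorted(prof.cross_pairs)
    ]
    table = pd.DataFrame(rows, columns=["subject_id", "group", "taa", "moa"])
    tallies = {
        grp.value: sum(
            1 for p in profiles.values() if p.group == grp and p.cross_pairs
        )
        for grp in (Group.HS, Group.CP)
    }
    return table.sort_values(["group", "subject_id", "taa", "moa"]).reset_index(
        drop=True
    ), tallies


def significance_matrix(
    results: pd.DataFrame, matrix: ReadCountMatrix, fraction: Fraction
) -> pd.DataFrame:
    """Subjects x pMHC boolean matrix of significant calls in one sorted
    fraction (heatmap-style export)."""
    ids = {
        s.sample_id: s.subject_id
        for s in matrix.samples
        if s.fraction == fraction and s.subject_id is not None
    }
    sub = results[results["sample_id"].isin(ids)].copy()
    sub["subject_id"] = sub["sample_id"].map(ids)
    return (
        sub.pivot_table(
            index="subject_id", columns="barcode", values="significant",
            aggfunc="any", fill_value=False,
        )
        .astype(bool)
        .sort_index()
    )


# ---------------------------------------------------------------------------
# Group comparison

#: Largest combined sample size for which the Mann-Whitney p-value is
#: computed by exhaustive enumeration of group assignments.
EXACT_ENUMERATION_LIMIT = 12


def mann_whitney_compare(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U comparison of two groups.

    For combined n <= 12 the p-value is exact, by enumerating all
    C(n, n_a) assignments of the pooled values (ties handled by the
    0.5-count convention); larger samples use the normal approximation
    with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    def u_stat(x, y):
        return float(
            sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                for xi in x for yj in y)
        )

    u_obs = u_stat(a, b)
    n, m = a.size, b.size
    if n + m <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        center = n * m / 2.0
        dev = abs(u_obs - center)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            if abs(u - center) >= dev - 1e-12:
                count += 1
            total += 1
        return {"U": u_obs, "p_two_sided": count / total, "method": "exact"}
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {"U": float(res.statistic), "p_two_sided": float(res.pvalue),
            "method": "asymptotic"}


# ---------------------------------------------------------------------------
# I/O

def profiles_to_frame(profiles: dict[str, SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "group": p.group.value,
                "n_moa": len(p.significant_moa),
                "n_taa": len(p.significant_taa),
                "n_cross_pairs": len(p.cross_pairs),
                "significant_moa": ";".join(sorted(p.significant_moa)),
                "significant_taa": ";".join(sorted(p.significant_taa)),
                "cross_pairs": ";".join(
                    f"{t}|{m}" for t, m in sorted(p.cross_pairs)
                ),
                "pct_moa": p.pct_moa,
                "pct_taa": p.pct_taa,
                "pct_cross": p.pct_cross,
            }
            for p in sorted(profiles.values(), key=lambda x: x.subject_id)
        ]
    )
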