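"""Synthetic inputs emulating the statistical structure of the screening study.

Three generators cover the pipeline's input surface:

* proteomes with planted near-identical nonamer windows (for the
  homology scanner);
* barcode x sample count matrices with lognormal baseline abundances,
  negative-binomial sequencing noise at dispersion 0.1, and spiked
  antigen-specific enrichments (for the enrichment statistics);
* full cohorts — 10 healthy subjects and 15 cancer patients by default,
  each with a single-stained and a double-stained sorted fraction —
  with planted MoA-only, TAA-only and cross-reactive responses (for the
  end-to-end profile classification).

All randomness flows from a single integer seed through
``numpy.random.default_rng``; a fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcode_enrichment import (
    Fraction,
    Group,
    ReadCountMatrix,
    SampleMeta,
)
from .mimicry_scan import ProteinRecord
from .peptides import (
    AMINO_ACIDS,
    DEFAULT_SCHEME,
    Peptide,
    Source,
    STUDY_MOA_GROUPS,
    STUDY_MOAS,
    STUDY_TAAS,
)
from .reactivity_profile import HomologyGroup

_TAA_PREFIX = {
    "MAGE-A1": "A1",
    "MAGE-A3": "A3",
    "MAGE-A3/12": "A3/12",
    "MAGE-A10": "A10",
    "MAGE-C1": "C1",
    "MAGE-C2": "C2",
    "SSX2": "SSX2",
}


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class PlantedWindow:
    """A homolog to plant in a synthetic proteome."""

    query: str
    n_mutations: int = 0
    positions: tuple[int, ...] | None = None  # 1-based; chosen at random if None

    def __post_init__(self) -> None:
        if self.n_mutations not in (0, 1, 2):
            raise ValueError("n_mutations must be 0, 1 or 2 (mimic structure)")


@dataclass(frozen=True)
class ProteomeSpec:
    n_proteins: int = 100
    protein_length: int = 300
    plants: tuple[PlantedWindow, ...] = ()


@dataclass(frozen=True)
class ExperimentSpec:
    n_barcodes: int = 124          # 7 TAAs + 53 MoAs + 64 viral controls
    n_baseline_replicates: int = 3
    depth: int = 1_000_000
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    alpha: float = 0.1
    #: Noise of the baseline technical aliquots; None = Poisson sampling
    #: noise (replicate aliquots of one pool), a float = NB dispersion.
    baseline_alpha: float | None = None
    n_samples: int = 1
    plants: tuple[tuple[str, str, float], ...] = ()  # (barcode, sample, fold)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        for _, _, fold in self.plants:
            if fold < 1:
                raise ValueError("planted folds must be >= 1")


@dataclass(frozen=True)
class PlantedProfile:
    """Planted responses for one subject.

    ``cross`` lists (TAA, MoAs-of-its-group) planted together in the
    double-stained fraction.
    """

    moa_single: tuple[str, ...] = ()
    taa_double: tuple[str, ...] = ()
    cross: tuple[tuple[str, tuple[str, ...]], ...] = ()


@dataclass(frozen=True)
class CohortSpec:
    n_hs: int = 10
    n_cp: int = 15
    n_moas_total: int = 53
    n_viral: int = 64
    depth: int = 1_000_000
    n_baseline_replicates: int = 3
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    alpha: float = 0.1
    baseline_alpha: float | None = None  # None = Poisson aliquot noise
    fold: float = 32.0
    plants: dict[str, PlantedProfile] | None = None  # None -> study-like default


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    proteome: ProteomeSpec = ProteomeSpec()
    experiment: ExperimentSpec = ExperimentSpec()
    cohort: CohortSpec = CohortSpec()


# ---------------------------------------------------------------------------
# Peptide library

def simulate_moa_set(
    taa: Peptide,
    n: int,
    rng: np.random.Generator,
    labels: list[str] | None = None,
    seed_moas: dict[str, Peptide] | None = None,
) -> dict[str, Peptide]:
    """A set of ``n`` mimics of ``taa``, each at Hamming distance 0-2.

    Mutated positions are budgeted so that no position is mutated in
    half or more of the set; the modal residue at every position then
    equals the TAA residue, so the consensus of the set reproduces the
    TAA by construction (the structure reported for the real mimic
    table).  ``seed_moas`` (e.g. the printed mimics) count against the
    per-position budget.
    """
    length = len(taa)
    max_per_pos = math.ceil(n / 2) - 1   # strictly fewer than n/2
    counts = [0] * length
    out: dict[str, Peptide] = {}
    if seed_moas:
        for name, moa in seed_moas.items():
            if len(moa) != length:
                raise ValueError("seed mimic length mismatch")
            for i, (a, b) in enumerate(zip(taa.sequence, moa.sequence)):
                if a != b:
                    counts[i] += 1
            out[name] = moa
    prefix = _TAA_PREFIX.get(taa.name, taa.name or "TAA")
    if labels is None:
        labels = [f"{prefix}-SYN{i + 1}" for i in range(n - len(out))]
    same_class = {
        aa: [b for b in AMINO_ACIDS
             if b != aa and DEFAULT_SCHEME.same_class(aa, b)]
        for aa in AMINO_ACIDS
    }
    for label in labels:
        if len(out) >= n:
            break
        k = int(rng.integers(1, 3))  # 1 or 2 substitutions
        allowed = [p for p in range(length) if counts[p] + 1 <= max_per_pos]
        k = min(k, len(allowed))
        positions = sorted(
            rng.choice(allowed, size=k, replace=False)
        ) if k else []
        seq = list(taa.sequence)
        for p in positions:
            orig = seq[p]
            pool = same_class[orig] if (rng.random() < 0.7 and same_class[orig]) \
                else [b for b in AMINO_ACIDS if b != orig]
            seq[p] = str(rng.choice(pool))
            counts[p] += 1
        out[label] = Peptide(
            "".join(seq), name=label, source=Source.MOA, organism="synthetic"
        )
    return out


def make_study_library(
    rng: np.random.Generator,
    n_moas_total: int = 53,
    include_printed: bool = True,
) -> tuple[dict[str, Peptide], list[HomologyGroup]]:
    """The 7 study TAAs with a full mimic panel (printed mimics plus
    synthetic fill-ins to the requested total), as peptides + groups."""
    n_taas = len(STUDY_TAAS)
    base, extra = divmod(n_moas_total, n_taas)
    peptides: dict[str, Peptide] = dict(STUDY_TAAS)
    groups: list[HomologyGroup] = []
    for i, (taa_name, taa) in enumerate(STUDY_TAAS.items()):
        n_here = base + (1 if i < extra else 0)
        seeds = (
            {m: STUDY_MOAS[m] for m, t in STUDY_MOA_GROUPS.items()
             if t == taa_name}
            if include_printed else None
        )
        moas = simulate_moa_set(taa, n_here, rng, seed_moas=seeds)
        peptides.update(moas)
        groups.append(HomologyGroup(taa=taa_name, moas=tuple(moas)))
    return peptides, groups


# ---------------------------------------------------------------------------
# Proteomes

def simulate_proteome(
    spec: ProteomeSpec, seed: int | np.random.Generator
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Background proteins of i.i.d. uniform composition with planted
    homolog windows; returns records plus a planted-truth table with
    columns protein_id, offset (1-based), planted_peptide, query,
    mutated_positions."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins = [
        "".join(rng.choice(aa, size=spec.protein_length))
        for _ in range(spec.n_proteins)
    ]
    truth_rows = []
    for plant in spec.plants:
        query = Peptide(plant.query).sequence
        if len(query) > spec.protein_length:
            raise ValueError("planted window longer than protein")
        if plant.positions is not None:
            positions = [p - 1 for p in plant.positions]
            if len(positions) != plant.n_mutations:
                raise ValueError("positions length must equal n_mutations")
        else:
            positions = sorted(
                rng.choice(len(query), size=plant.n_mutations, replace=False)
            )
        window = list(query)
        for p in positions:
            window[p] = str(
                rng.choice([b for b in AMINO_ACIDS if b != window[p]])
            )
        target = int(rng.integers(spec.n_proteins))
        offset = int(rng.integers(spec.protein_length - len(query) + 1))
        seq = proteins[target]
        proteins[target] = (
            seq[:offset] + "".join(window) + seq[offset + len(query):]
        )
        truth_rows.append(
            {
                "protein_id": f"prot{target:04d}",
                "offset": offset + 1,
                "planted_peptide": "".join(window),
                "query": query,
                "mutated_positions": ",".join(str(p + 1) for p in positions),
            }
        )
    records = [
        ProteinRecord(f"prot{i:04d}", seq, organism="synthetic",
                      taxon_label="synthetic")
        for i, seq in enumerate(proteins)
    ]
    return records, pd.DataFrame(
        truth_rows,
        columns=["protein_id", "offset", "planted_peptide", "query",
                 "mutated_positions"],
    )


def proteome_to_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id} [{rec.organism}]\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Barcode count experiments

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float | None
) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + alpha mu^2);
    alpha None gives Poisson (the alpha -> 0 limit)."""
    mean = np.asarray(mean, dtype=float)
    if alpha is None:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_barcode_experiment(
    spec: ExperimentSpec, seed: int | np.random.Generator
) -> tuple[ReadCountMatrix, pd.DataFrame]:
    """Baseline triplicates plus experiment samples with optional spiked
    enrichments.

    Baseline barcode abundances are lognormal; every count is drawn
    NB(mean = abundance share x depth, dispersion alpha).  Planted
    (barcode, sample, fold) triples multiply the mean in that sample.
    Returns the count matrix and the planted-truth table.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    barcodes = [f"bc{i:04d}" for i in range(spec.n_barcodes)]
    abundance = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma,
                              spec.n_barcodes)
    shares = abundance / abundance.sum()
    base_mean = shares * spec.depth

    columns = {}
    samples = []
    for j in range(spec.n_baseline_replicates):
        sid = f"baseline-{j + 1}"
        columns[sid] = _nb_draw(rng, base_mean, spec.baseline_alpha)
        samples.append(SampleMeta(sid, Group.BASELINE))
    plant_map: dict[tuple[str, str], float] = {
        (bc, s): fold for bc, s, fold in spec.plants
    }
    truth_rows = []
    for j in range(spec.n_samples):
        sid = f"sample-{j + 1}"
        mean = base_mean.copy()
        for i, bc in enumerate(barcodes):
            fold = plant_map.get((bc, sid))
            if fold is not None:
                mean[i] *= fold
                truth_rows.append(
                    {"barcode": bc, "sample_id": sid, "fold": fold,
                     "baseline_mean": base_mean[i]}
                )
        columns[sid] = _nb_draw(rng, mean, spec.alpha)
        samples.append(
            SampleMeta(sid, Group.HS, subject_id=f"subject-{j + 1}",
                       fraction=Fraction.SINGLE_STAINED,
                       pct_multimer_pos_cd8=1.0)
        )
    counts = pd.DataFrame(columns, index=barcodes)
    matrix = ReadCountMatrix(counts=counts, samples=samples)
    truth = pd.DataFrame(
        truth_rows, columns=["barcode", "sample_id", "fold", "baseline_mean"]
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Cohorts

def default_cohort_plants(
    subjects: dict[str, Group], groups: list[HomologyGroup],
    rng: np.random.Generator,
) -> dict[str, PlantedProfile]:
    """A study-like planted-response pattern.

    Every subject reacts to a handful of MoAs in the single-stained
    fraction (consistent reactivity to a MAGE-C2 mimic plus random
    others); a few subjects carry TAA-only responses; one cancer
    patient is planted with a TAA plus three homologous mimics in the
    double-stained fraction (the broad cross-reactive pattern), and two
    further subjects with single cross pairs.
    """
    by_taa = {g.taa: g for g in groups}
    all_moas = [m for g in groups for m in g.moas]
    consistent = by_taa["MAGE-C2"].moas[0]
    subject_ids = list(subjects)
    cp_ids = [s for s, g in subjects.items() if g == Group.CP]
    hs_ids = [s for s, g in subjects.items() if g == Group.HS]

    def pick(ids, i):
        return ids[i] if i < len(ids) else (ids[-1] if ids else None)

    # cross-reactive subjects: two healthy, three patients; one patient
    # (the 4th) carries the broad TAA + 3-mimic pattern
    cross_plan: dict[str, list] = {}

    def add_cross(sid, taa, n_moas):
        if sid is None:
            return
        grp = by_taa[taa]
        cross_plan.setdefault(sid, []).append(
            (taa, tuple(grp.moas[:n_moas]))
        )

    add_cross(pick(cp_ids, 3), "SSX2", 3)        # broad T-004-like
    add_cross(pick(hs_ids, 9), "MAGE-A1", 1)     # H-010-like
    add_cross(pick(hs_ids, 3), "MAGE-C1", 1)     # H-004-like
    add_cross(pick(cp_ids, 0), "MAGE-A1", 1)     # T-001-like (two groups)
    add_cross(pick(cp_ids, 0), "MAGE-C1", 1)
    add_cross(pick(cp_ids, 5), "MAGE-A1", 1)     # T-006-like

    taa_only = pick(hs_ids, 6)                   # H-007-like MAGE-A1 binder

    plants: dict[str, PlantedProfile] = {}
    for sid in subject_ids:
        n_extra = int(rng.integers(1, 4))
        extra = list(rng.choice(
            [m for m in all_moas if m != consistent], size=n_extra,
            replace=False,
        ))
        cross = tuple(cross_plan.get(sid, ()))
        taa_double = ("MAGE-A1",) if sid == taa_only and not cross else ()
        plants[sid] = PlantedProfile(
            moa_single=tuple([consistent] + extra),
            taa_double=taa_double,
            cross=cross,
        )
    return plants


def simulate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator
) -> dict:
    """End-to-end input bundle: counts, sample metadata, homology groups,
    barcode annotations and planted truth profiles.

    Each subject contributes a single-stained and a double-stained
    sample; triplicate baselines and one non-HLA-matched negative
    control complete the design.  Planted responses multiply the
    barcode's baseline mean by ``spec.fold`` in the target sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    peptides, groups = make_study_library(rng, n_moas_total=spec.n_moas_total)
    moa_to_taa = {m: g.taa for g in groups for m in g.moas}
    viral = {
        f"VIR-{i + 1:03d}": Peptide(
            "".join(rng.choice(list(AMINO_ACIDS), size=9)),
            name=f"VIR-{i + 1:03d}", source=Source.VIRAL,
        )
        for i in range(spec.n_viral)
    }
    peptides = {**peptides, **viral}

    barcodes = list(peptides)
    annotations = pd.DataFrame(
        {
            "peptide": [peptides[b].name for b in barcodes],
            "antigen_class": [
                {"TAA": "TAA", "MoA": "MoA", "viral_control": "viral_control"}[
                    peptides[b].source.value
                ]
                for b in barcodes
            ],
            "homology_group": [moa_to_taa.get(b, b if b in STUDY_TAAS else "")
                               for b in barcodes],
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    subjects = {f"H-{i + 1:03d}": Group.HS for i in range(spec.n_hs)}
    subjects.update({f"T-{i + 1:03d}": Group.CP for i in range(spec.n_cp)})
    plants = spec.plants
    if plants is None:
        plants = default_cohort_plants(subjects, groups, rng)

    # validate planted cross responses against the homology groups
    for sid, prof in plants.items():
        for taa, moas in prof.cross:
            if taa not in {g.taa for g in groups}:
                raise ValueError(f"unknown TAA {taa!r} in planted cross")
            for m in moas:
                if moa_to_taa.get(m) != taa:
                    raise ValueError(
                        f"cross planted for MoA {m!r} outside the homology "
                        f"group of {taa!r}"
                    )

    n = len(barcodes)
    abundance = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, n)
    shares = abundance / abundance.sum()
    base_mean = shares * spec.depth
    index = {bc: i for i, bc in enumerate(barcodes)}

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    for j in range(spec.n_baseline_replicates):
        sid = f"baseline-{j + 1}"
        columns[sid] = _nb_draw(rng, base_mean, spec.baseline_alpha)
        samples.append(SampleMeta(sid, Group.BASELINE))

    truth: dict[str, dict] = {}
    for sid, grp in subjects.items():
        prof = plants.get(sid, PlantedProfile())
        planted_ss = set(prof.moa_single)
        planted_ds = set(prof.taa_double)
        cross_pairs = set()
        for taa, moas in prof.cross:
            planted_ds.add(taa)
            planted_ds.update(moas)
            cross_pairs.update((taa, m) for m in moas)
        for fraction, planted in (
            (Fraction.SINGLE_STAINED, planted_ss),
            (Fraction.DOUBLE_STAINED, planted_ds),
        ):
            tag = "SS" if fraction == Fraction.SINGLE_STAINED else "DS"
            col_id = f"{sid}-{tag}"
            mean = base_mean.copy()
            for bc in planted:
                mean[index[bc]] *= spec.fold
            columns[col_id] = _nb_draw(rng, mean, spec.alpha)
            samples.append(
                SampleMeta(
                    col_id, grp, subject_id=sid, fraction=fraction,
                    pct_multimer_pos_cd8=float(
                        np.round(rng.uniform(0.05, 2.0), 4)
                    ),
                )
            )
        truth[sid] = {
            "group": grp,
            "moa_single": planted_ss,
            "taa_double": set(prof.taa_double) | {t for t, _ in cross_pairs},
            "cross_pairs": cross_pairs,
        }

    columns["negctrl"] = _nb_draw(rng, base_mean, spec.alpha)  # a real (non-matched) sorted sample
    samples.append(
        SampleMeta("negctrl", Group.NEGATIVE_CONTROL, subject_id=None,
                   fraction=Fraction.NONE, pct_multimer_pos_cd8=0.0)
    )

    counts = pd.DataFrame(columns, index=pd.Index(barcodes, name="barcode"))
    matrix = ReadCountMatrix(counts=counts, samples=samples,
                             annotations=annotations)
    return {
        "matrix": matrix,
        "peptides": peptides,
        "homology_groups": groups,
        "truth_profiles": truth,
        "spec": spec,
    }
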