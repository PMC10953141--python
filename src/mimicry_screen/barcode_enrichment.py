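"""T-cell response calling from DNA-barcoded pMHC multimer sequencing counts.

Each pMHC multimer in the staining library carries a unique DNA barcode;
sequencing the barcodes of sorted multimer-positive CD8+ T cells, next to
triplicate aliquots of the original multimer pool (the baseline), turns
antigen recognition into a count-enrichment problem:

1. reads are clonally reduced (collapsed by unique molecule tag) to
   remove PCR duplication;
2. samples are scaled by trimmed-mean-of-M-values (TMM) normalization
   factors so that barcode counts are comparable across samples;
3. each experiment sample is compared barcode-by-barcode with the mean
   of the normalized baselines under a negative binomial model with a
   fixed dispersion (variance = mu + alpha * mu^2, alpha = 0.1 by
   default), one-sided toward enrichment;
4. p-values are Benjamini-Hochberg adjusted, and a barcode is called a
   true T-cell response when FDR < 0.1%, log2 fold change > 2, and it
   accounts for at least 1/1,000 of the sample's barcode reads;
5. the frequency of the responding T cells, as a percentage of CD8+
   cells, is the barcode's read fraction times the sample's percentage
   of multimer-positive CD8+ cells;
6. specificities called significant in a non-HLA-matched negative
   control sample are removed everywhere (non-specific binding).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class Group(str, enum.Enum):
    HS = "HS"                     # healthy subject
    CP = "CP"                     # cancer patient
    NEGATIVE_CONTROL = "negative_control"
    BASELINE = "baseline"


class Fraction(str, enum.Enum):
    SINGLE_STAINED = "single_stained"   # one fluorochrome: MoA / viral binders
    DOUBLE_STAINED = "double_stained"   # both channels: TAA and cross binders
    NONE = "none"


@dataclass(frozen=True)
class SampleMeta:
    """Role and sort-fraction annotation of one sequencing sample."""

    sample_id: str
    group: Group
    subject_id: str | None = None
    fraction: Fraction = Fraction.NONE
    pct_multimer_pos_cd8: float | None = None

    def __post_init__(self) -> None:
        if self.group == Group.BASELINE and self.subject_id is not None:
            raise ValueError("baseline samples carry no subject")
        if self.pct_multimer_pos_cd8 is not None and not (
            0 <= self.pct_multimer_pos_cd8 <= 100
        ):
            raise ValueError("pct_multimer_pos_cd8 must be in [0, 100]")


@dataclass(frozen=True)
class DispersionParam:
    """Negative binomial overdispersion: variance = mu + alpha * mu^2."""

    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("dispersion alpha must be positive")


@dataclass
class ReadCountMatrix:
    """Barcode x sample counts with sample roles and barcode annotation.

    ``counts`` is the raw layer; ``reduced`` (optional) the clonally
    reduced layer.  ``annotations`` maps each barcode to its peptide,
    antigen class (TAA / MoA / viral_control) and homology group.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    reduced: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        meta_ids = [s.sample_id for s in self.samples]
        if sorted(meta_ids) != sorted(self.counts.columns):
            raise ValueError("sample metadata and count columns disagree")
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample ids")
        if self.reduced is not None:
            if not self.reduced.index.equals(self.counts.index) or list(
                self.reduced.columns
            ) != list(self.counts.columns):
                raise ValueError("reduced layer must align with raw layer")

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def baseline_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == Group.BASELINE]

    def tested_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.group != Group.BASELINE]

    def working_layer(self) -> pd.DataFrame:
        """Clonally reduced counts when present, else raw."""
        return self.reduced if self.reduced is not None else self.counts


# ---------------------------------------------------------------------------
# Clonal reduction

def clonally_reduce(
    records: Iterable[tuple],
    samples: list[SampleMeta] | None = None,
    annotations: pd.DataFrame | None = None,
) -> ReadCountMatrix:
    """Collapse (barcode, molecule_tag, sample) read records by unique tag.

    The reduced count per (barcode, sample) is the number of distinct
    molecule tags; the raw count (number of records) is kept alongside.
    Records with a missing tag fall back to raw counting for that cell,
    with a prominent warning.
    """
    df = pd.DataFrame(records, columns=["barcode", "molecule_tag", "sample"])
    if df.empty:
        raise ValueError("no read records")
    missing = df["molecule_tag"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} read records lack a molecule tag; "
            "raw counts used for the affected cells",
            stacklevel=2,
        )
    raw = df.groupby(["barcode", "sample"]).size().unstack(fill_value=0)
    red = (
        df[~missing]
        .groupby(["barcode", "sample"])["molecule_tag"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(index=raw.index, columns=raw.columns, fill_value=0)
    )
    # records without a tag cannot be deduplicated: counted raw
    n_missing = (
        df[missing]
        .groupby(["barcode", "sample"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=raw.index, columns=raw.columns, fill_value=0)
    )
    red = red + n_missing
    raw = raw.astype(int)
    red = red.astype(int)
    if samples is None:
        samples = [SampleMeta(c, Group.BASELINE) for c in raw.columns]
    return ReadCountMatrix(
        counts=raw, samples=samples, reduced=red, annotations=annotations
    )


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(
    counts: pd.DataFrame | "ReadCountMatrix",
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample scaling factors by the trimmed mean of M-values.

    For each sample k against the reference r, on barcodes nonzero in
    both: M = log2((x_k/N_k)/(x_r/N_r)) and A = 0.5*log2(x_k x_r /
    (N_k N_r)) with column totals N; the upper and lower ``trim_m`` of
    the M distribution and ``trim_a`` of the A distribution are dropped
    and the remaining M are averaged with inverse-variance (delta
    method) weights, giving the composition factor f_k.  The returned
    factor absorbs sequencing depth — factor_k ∝ N_k * f_k, rescaled to
    geometric mean 1 — so that ``count / factor`` is directly comparable
    across samples.

    The default reference is the sample whose total count is closest to
    the median total.  A sample sharing no nonzero barcodes with the
    reference gets composition factor 1 with a warning.
    """
    if isinstance(counts, ReadCountMatrix):
        counts = counts.working_layer()
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    if reference is None:
        reference = (totals - totals.median()).abs().idxmin()
    x_r = counts[reference].to_numpy(dtype=float)
    n_r = totals[reference]

    log_factors = {}
    for sample in counts.columns:
        if sample == reference:
            log_factors[sample] = 0.0
            continue
        x_k = counts[sample].to_numpy(dtype=float)
        n_k = totals[sample]
        mask = (x_k > 0) & (x_r > 0)
        if not mask.any():
            warnings.warn(
                f"sample {sample!r} shares no nonzero barcodes with the "
                f"reference; factor set to 1",
                stacklevel=2,
            )
            log_factors[sample] = 0.0
            continue
        xk, xr = x_k[mask], x_r[mask]
        m = np.log2((xk / n_k) / (xr / n_r))
        a = 0.5 * np.log2((xk / n_k) * (xr / n_r))
        w = 1.0 / ((n_k - xk) / (n_k * xk) + (n_r - xr) / (n_r * xr))
        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        log_factors[sample] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    f = pd.Series(
        {s: 2.0 ** lf for s, lf in log_factors.items()}, dtype=float
    ).reindex(counts.columns)
    factors = f * totals / n_r
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    factors.name = "tmm_factor"
    return factors


def _double_trim_mask(
    m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float
) -> np.ndarray:
    """Keep entries inside both the M-trim and A-trim rank windows."""
    n = len(m)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    lo_m, hi_m = n * trim_m, n * (1 - trim_m)
    lo_a, hi_a = n * trim_a, n * (1 - trim_a)
    return (rank_m > lo_m) & (rank_m <= hi_m + 1e-9) & \
           (rank_a > lo_a) & (rank_a <= hi_a + 1e-9)


# ---------------------------------------------------------------------------
# Per-barcode statistics

def normalized_log2fc(
    count: float,
    baseline_counts: Sequence[float],
    factor: float = 1.0,
    baseline_factors: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> float:
    """log2((count/factor + pc) / (mean of normalized baselines + pc)).

    The pseudocount guards zeros in both numerator and denominator.
    """
    if len(baseline_counts) == 0:
        raise ValueError("baseline counts must be non-empty")
    if baseline_factors is None:
        baseline_factors = [1.0] * len(baseline_counts)
    base = np.mean(
        [c / f for c, f in zip(baseline_counts, baseline_factors, strict=True)]
    )
    return float(np.log2((count / factor + pseudocount) / (base + pseudocount)))


def nb_tail_pvalue(
    observed: int | np.ndarray,
    mu: float | np.ndarray,
    alpha: DispersionParam | float = DispersionParam(),
) -> float | np.ndarray:
    """One-sided upper tail P(X >= observed) under NB(mean mu, var mu+alpha*mu^2).

    observed = 0 gives exactly 1 (the whole support).  Vectorized over
    both arguments.
    """
    a = alpha.alpha if isinstance(alpha, DispersionParam) else float(alpha)
    if a <= 0:
        raise ValueError("dispersion alpha must be positive")
    mu_arr = np.asarray(mu, dtype=float)
    if (mu_arr <= 0).any():
        raise ValueError("NB mean mu must be positive")
    obs = np.asarray(observed)
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    r = 1.0 / a
    p_success = r / (r + mu_arr)
    out = stats.nbinom.sf(obs - 1, r, p_success)
    # the true tail mass is positive; guard against floating underflow
    out = np.maximum(out, np.finfo(float).tiny)
    if np.isscalar(observed) and np.isscalar(mu):
        return float(out)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_tcell_frequency(
    read_fraction: float, pct_multimer_pos_cd8: float | None
) -> float | None:
    """Responding-T-cell frequency as a percentage of CD8+ cells.

    The barcode's share of the sample's reads times the percentage of
    multimer-positive CD8+ cells.  ``None`` (not 0) when the multimer
    percentage was not recorded.
    """
    if not 0 <= read_fraction <= 1:
        raise ValueError("read_fraction must be in [0, 1]")
    if pct_multimer_pos_cd8 is None:
        return None
    if not 0 <= pct_multimer_pos_cd8 <= 100:
        raise ValueError("pct_multimer_pos_cd8 must be in [0, 100]")
    return read_fraction * pct_multimer_pos_cd8


# ---------------------------------------------------------------------------
# The pipeline

def run_enrichment(
    matrix: ReadCountMatrix,
    alpha: DispersionParam | float = DispersionParam(0.1),
    fdr_cut: float = 0.001,
    lfc_cut: float = 2.0,
    fraction_cut: float = 0.001,
    pseudocount: float = 1.0,
    mean_floor: float = 0.5,
    bh_family: str = "global",
) -> pd.DataFrame:
    """Full barcode-enrichment analysis: one row per (barcode, sample).

    Baseline expectation per barcode is the mean of the TMM-normalized
    triplicate baselines, floored at ``mean_floor`` normalized reads (so
    a barcode absent from the baseline cannot become infinitely
    significant), then rescaled to each sample's depth for the NB test.
    ``bh_family`` is "global" (all barcode x tested-sample pairs, the
    default) or "per_sample".

    Returns a DataFrame with columns barcode, sample_id, log2fc, p_value,
    fdr, read_fraction, significant, est_frequency_pct — deterministic
    for identical inputs and configuration.
    """
    if isinstance(alpha, (int, float)):
        alpha = DispersionParam(float(alpha))
    if bh_family not in ("global", "per_sample"):
        raise ValueError("bh_family must be 'global' or 'per_sample'")
    baselines = matrix.baseline_ids()
    if not baselines:
        raise ValueError("at least one baseline sample is required")
    tested = matrix.tested_ids()
    if not tested:
        raise ValueError("no experiment samples to test")
    layer = matrix.working_layer()
    totals = layer.sum(axis=0)
    if (totals[tested] <= 0).any():
        bad = list(totals[tested][totals[tested] <= 0].index)
        raise ValueError(f"tested samples with zero totals: {bad}")

    # reference = baseline replicate with median total count
    base_totals = totals[baselines]
    reference = (base_totals - base_totals.median()).abs().idxmin()
    factors = tmm_factors(layer, reference=reference)

    norm = layer / factors
    base_mean = norm[baselines].mean(axis=1)              # normalized scale
    nb_base = np.maximum(base_mean.to_numpy(), mean_floor)

    rows = []
    for sample in tested:
        obs = layer[sample].to_numpy()
        f_k = factors[sample]
        mu = nb_base * f_k                                 # sample's raw scale
        pvals = nb_tail_pvalue(obs, mu, alpha)
        lfc = np.log2(
            (norm[sample].to_numpy() + pseudocount)
            / (base_mean.to_numpy() + pseudocount)
        )
        frac = obs / totals[sample]
        meta = matrix.meta(sample)
        for i, bc in enumerate(layer.index):
            rows.append(
                {
                    "barcode": bc,
                    "sample_id": sample,
                    "log2fc": float(lfc[i]),
                    "p_value": float(pvals[i]),
                    "read_fraction": float(frac[i]),
                    "pct_multimer_pos_cd8": meta.pct_multimer_pos_cd8,
                }
            )
    results = pd.DataFrame(rows)

    if bh_family == "global":
        results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    else:
        results["fdr"] = (
            results.groupby("sample_id", sort=False)["p_value"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    logger.info(
        "BH family: %s (%d tests over %d samples)",
        bh_family, len(results), len(tested),
    )

    results = call_significant(
        results, fdr_cut=fdr_cut, lfc_cut=lfc_cut, fraction_cut=fraction_cut
    )
    results["est_frequency_pct"] = [
        estimate_tcell_frequency(rf, pct) if sig else None
        for rf, pct, sig in zip(
            results["read_fraction"],
            results["pct_multimer_pos_cd8"],
            results["significant"],
        )
    ]
    results = results.drop(columns=["pct_multimer_pos_cd8"])
    return results[
        ["barcode", "sample_id", "log2fc", "p_value", "fdr",
         "read_fraction", "significant", "est_frequency_pct"]
    ]


def call_significant(
    results: pd.DataFrame,
    fdr_cut: float = 0.001,
    lfc_cut: float = 2.0,
    fraction_cut: float = 0.001,
) -> pd.DataFrame:
    """Flag true T-cell responses: FDR < cut, log2FC > cut, and at least
    ``fraction_cut`` of the sample's barcode reads."""
    out = results.copy()
    out["significant"] = (
        (out["fdr"] < fdr_cut)
        & (out["log2fc"] > lfc_cut)
        & (out["read_fraction"] >= fraction_cut)
    )
    per_sample = out.groupby("sample_id", sort=False)["significant"].sum()
    logger.info("significant calls per sample: %s", per_sample.to_dict())
    return out


def apply_negative_control(
    results: pd.DataFrame,
    matrix: ReadCountMatrix | None = None,
    control_sample_id: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove specificities that light up in the negative-control sample.

    Any barcode called significant in the non-HLA-matched control is
    un-called in every sample (non-specific multimer binding).  Returns
    the filtered results and the list of removed barcodes.
    """
    if control_sample_id is None and matrix is not None:
        controls = [
            s.sample_id for s in matrix.samples
            if s.group == Group.NEGATIVE_CONTROL
        ]
        control_sample_id = controls[0] if controls else None
    if control_sample_id is None:
        warnings.warn("no negative-control sample; results passed through",
                      stacklevel=2)
        return results, []
    in_control = results["sample_id"] == control_sample_id
    removed = sorted(
        results.loc[in_control & results["significant"], "barcode"].unique()
    )
    if removed:
        logger.info(
            "negative control %s: removing %d non-specific barcodes: %s",
            control_sample_id, len(removed), removed,
        )
    out = results.copy()
    mask = out["barcode"].isin(removed) & out["significant"]
    out.loc[mask, "significant"] = False
    out.loc[mask, "est_frequency_pct"] = None
    return out, removed


# ---------------------------------------------------------------------------
# I/O

def read_counts_tsv(counts_path, samples_path, annotations_path=None) -> ReadCountMatrix:
    """Read a counts TSV (rows barcodes, columns samples) plus a samples
    metadata TSV with columns sample_id,group,subject_id,fraction,
    pct_multimer_pos_cd8."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t")
    samples = []
    for rec in meta.itertuples(index=False):
        subject = getattr(rec, "subject_id", None)
        if subject is not None and (pd.isna(subject) or subject == ""):
            subject = None
        pct = getattr(rec, "pct_multimer_pos_cd8", None)
        if pct is not None and pd.isna(pct):
            pct = None
        samples.append(
            SampleMeta(
                sample_id=str(rec.sample_id),
                group=Group(rec.group),
                subject_id=subject,
                fraction=Fraction(getattr(rec, "fraction", "none")),
                pct_multimer_pos_cd8=None if pct is None else float(pct),
            )
        )
    annotations = None
    if annotations_path is not None:
        annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return ReadCountMatrix(counts=counts, samples=samples,
                           annotations=annotations)


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def samples_to_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "group": s.group.value,
                "subject_id": s.subject_id or "",
                "fraction": s.fraction.value,
                "pct_multimer_pos_cd8": s.pct_multimer_pos_cd8,
            }
            for s in samples
        ]
    )
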