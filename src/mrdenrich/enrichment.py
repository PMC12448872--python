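"""Selectivity and enrichment statistics for variant-selective capture assays.

The central quantity is the selectivity ``S`` of a probe: the ratio of the
fraction of input alternate (variant) molecules recovered to the fraction of
input wild-type molecules recovered.  For a non-selective assay (plain
hybridization capture) S = 1; S > 1 means the assay enriches the targeted
allele.  Because S is a ratio of recovery *fractions* it is independent of the
input variant allele frequency (VAF), so estimates from samples at different
dilution levels can be averaged.

Given recovered alternate molecules ``m``, wild-type molecules ``w`` and input
VAF ``f``::

    S = (1 - f) * m / (f * w)

A panel-wide (global) selectivity ``S_g`` follows by applying the same formula
to molecule counts summed over probes; within a sample this is algebraically
identical to the harmonic mean of per-probe S weighted by each probe's
alternate-molecule count.  ``S_g`` in turn determines the enrichment factor
(output over input VAF) and hence how much less sequencing a selective assay
needs than a non-selective one at equal off-target ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "selectivity",
    "probe_selectivity",
    "global_selectivity",
    "enrichment_factor",
    "relative_sequencing",
    "classify_selectivity",
    "fold_enrichment",
    "haploid_copies",
    "expected_input_molecules",
    "recovery_fraction",
    "theoretical_lod",
    "theoretical_depth",
    "SelectivitySummary",
]

#: Selectivity categories as half-open-left, closed-right intervals on S.
SELECTIVITY_BINS = (
    ("nonselective", 0.0, 1.0),
    ("weakly_selective", 1.0, 10.0),
    ("selective", 10.0, 50.0),
    ("strongly_selective", 50.0, math.inf),
)


@dataclass(frozen=True)
class SelectivitySummary:
    """Per-probe and panel-level selectivity summary."""

    per_probe: pd.DataFrame  # columns: probe_id, selectivity, n_samples, category
    global_selectivity: float
    n_probes: int


def _check_vaf(f: float) -> None:
    if not (0.0 < f < 1.0):
        raise ValueError(f"input VAF must lie in (0, 1), got {f!r}")


def selectivity(m: float, w: float, f: float) -> float:
    """Selectivity S = (1 - f) m / (f w) of one probe in one sample.

    Parameters
    ----------
    m : recovered alternate (variant) molecule count.
    w : recovered wild-type molecule count.
    f : input VAF of the variant, in (0, 1).

    Returns ``nan`` when ``w == 0`` (undefined selectivity; callers exclude
    such samples from averages rather than treating them as infinite).
    """
    _check_vaf(f)
    if m < 0 or w < 0:
        raise ValueError("molecule counts must be non-negative")
    if w == 0:
        return math.nan
    return (1.0 - f) * m / (f * w)


def probe_selectivity(
    records: pd.DataFrame, min_vaf: float = 0.001
) -> pd.DataFrame:
    """Per-probe selectivity: mean of per-sample S over samples with f >= min_vaf.

    ``records`` needs columns ``probe_id``, ``sample_id``, ``vaf``,
    ``total_alt``, ``total_wt``.  Samples with zero recovered wild-type
    molecules are excluded from the mean (their S is undefined).  Probes with
    no qualifying sample get ``NaN``, not zero.
    """
    qual = records[(records["vaf"] >= min_vaf) & (records["vaf"] < 1.0)].copy()
    if qual.empty:
        return pd.DataFrame(
            {"probe_id": pd.Series(dtype=object),
             "selectivity": pd.Series(dtype=float),
             "n_samples": pd.Series(dtype=int)}
        )
    qual["S"] = [
        selectivity(m, w, f)
        for m, w, f in zip(qual["total_alt"], qual["total_wt"], qual["vaf"])
    ]
    out = (
        qual.groupby("probe_id", sort=True)["S"]
        .agg(selectivity="mean", n_samples=lambda s: int(s.notna().sum()))
        .reset_index()
    )
    out["category"] = [
        classify_selectivity(s) if np.isfinite(s) else None
        for s in out["selectivity"]
    ]
    return out


def global_selectivity(records: pd.DataFrame, min_vaf: float = 0.001) -> float:
    """Panel-wide selectivity S_g.

    Within each qualifying sample (VAF >= ``min_vaf``) S is computed on
    molecule counts summed over all probes — equivalently the
    alternate-count-weighted harmonic mean of the per-probe S values — and the
    per-sample values are then averaged.
    """
    qual = records[(records["vaf"] >= min_vaf) & (records["vaf"] < 1.0)]
    if qual.empty:
        return math.nan
    vals = []
    for (_, f), grp in qual.groupby(["sample_id", "vaf"], sort=True):
        s = selectivity(grp["total_alt"].sum(), grp["total_wt"].sum(), float(f))
        if np.isfinite(s):
            vals.append(s)
    return float(np.mean(vals)) if vals else math.nan


def weighted_harmonic_mean_selectivity(
    per_probe_s: np.ndarray, weights: np.ndarray
) -> float:
    """Harmonic mean of per-probe S weighted by alternate-molecule counts.

    Identical to the aggregate-count S within a sample; exposed so the
    identity can be verified on real tables.
    """
    s = np.asarray(per_probe_s, dtype=float)
    m = np.asarray(weights, dtype=float)
    keep = (m > 0) & np.isfinite(s) & (s > 0)
    if not keep.any():
        return math.nan
    return float(m[keep].sum() / (m[keep] / s[keep]).sum())


def enrichment_factor(s_g: float, f_i: float) -> float:
    """Enrichment factor EF = S_g / (1 - f_i + f_i S_g): output over input VAF."""
    _check_vaf(f_i)
    if s_g <= 0:
        raise ValueError("global selectivity must be positive")
    return s_g / (1.0 - f_i + f_i * s_g)


def relative_sequencing(s_g: float, f_i: float) -> tuple[float, float]:
    """Relative sequencing amount c_r = 1/EF and percent depth reduction.

    Returns ``(c_r, reduction_percent)`` where reduction = (1 - c_r) * 100:
    the fraction of a non-selective assay's sequencing a selective assay with
    global selectivity ``s_g`` needs to see the same variant molecules at
    input VAF ``f_i``.
    """
    ef = enrichment_factor(s_g, f_i)
    c_r = 1.0 / ef
    return c_r, (1.0 - c_r) * 100.0


def classify_selectivity(s: float) -> str:
    """Map a selectivity value onto its category.

    Intervals are half-open at the left and closed at the right:
    nonselective (0, 1], weakly (1, 10], selective (10, 50], strongly > 50.
    """
    if not s >= 0:  # also rejects NaN
        raise ValueError(f"selectivity must be >= 0, got {s!r}")
    for name, lo, hi in SELECTIVITY_BINS:
        if lo < s <= hi:
            return name
    return "nonselective"  # S == 0


def fold_enrichment(mean_s_condition: float, mean_s_reference: float) -> float:
    """Fold enrichment between two conditions as the ratio of mean selectivities."""
    if mean_s_reference <= 0:
        raise ValueError("reference mean selectivity must be positive")
    return mean_s_condition / mean_s_reference


def haploid_copies(input_mass_pg: float, pg_per_haploid_genome: float = 3.158) -> float:
    """Number of haploid genome copies in an input mass of human DNA."""
    if input_mass_pg <= 0 or pg_per_haploid_genome <= 0:
        raise ValueError("masses must be positive")
    return input_mass_pg / pg_per_haploid_genome


def expected_input_molecules(
    input_mass_pg: float, vaf: float, pg_per_haploid_genome: float = 3.158
) -> float:
    """Expected alternate molecules entering library prep for a heterozygous-
    derived variant diluted to ``vaf`` (copies x VAF)."""
    return haploid_copies(input_mass_pg, pg_per_haploid_genome) * vaf


def recovery_fraction(recovered: float, input_molecules: float) -> float:
    """Fraction of input molecules recovered end-to-end."""
    if input_molecules <= 0:
        raise ValueError("input molecule count must be positive")
    return recovered / input_molecules


def theoretical_lod(n_variants: int, haploid_copies: float = 6060.0) -> float:
    """Theoretical 95% limit of detection of a multi-variant assay, in ppm.

    Assumes perfect per-molecule detection: a sample is detected when at least
    one tumour-derived fragment covering any tracked variant is present, so
    0.95 = 1 - exp(-tcf * copies * n_variants) with tcf the tumour cell
    fraction.  Solving gives tcf = ln(20) / (copies * n_variants), returned in
    parts per million.
    """
    if n_variants < 1 or haploid_copies < 1:
        raise ValueError("n_variants and haploid_copies must be >= 1")
    return math.log(20.0) / (haploid_copies * n_variants) * 1e6


def theoretical_depth(
    n_variants: int,
    reads_per_variant: int = 100_000,
    nt_per_read_pair: int = 300,
    enrichment: float = 1.0,
) -> float:
    """Theoretical sequencing need in gigabases for deep per-variant coverage.

    n_variants x reads x nucleotides / 1e9, divided by the enrichment factor
    for a variant-selective assay (enrichment = 1 for conventional capture).
    """
    if min(n_variants, reads_per_variant, nt_per_read_pair) < 1 or enrichment < 1:
        raise ValueError("counts must be >= 1 and enrichment >= 1")
    return n_variants * reads_per_variant * nt_per_read_pair / 1e9 / enrichment
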