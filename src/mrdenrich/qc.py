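"""Sample-level quality control.

Two checks gate every downstream statistic:

* **failed samples** — each sample carries a handful of control probes
  against germline variants that return comparable molecule numbers run to
  run; any control probe below 100 molecules marks the sample failed (e.g.
  an inhibited enrichment reaction), and failed samples are excluded from
  analysis;
* **cross-contamination** — a blank contaminated with foreign DNA shows
  alternate molecules that also carry the germline SNP phased with the
  target variant.  The contamination ratio (molecules with both the variant
  and the linked SNP over molecules covering both sites with the variant)
  approaches 1 for contamination but ~0 for genuine background errors, so a
  blank is flagged when its aggregate alternate duplex molecules exceed a
  molecule threshold AND the ratio exceeds a ratio threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "detect_failed_sample",
    "contamination_ratio",
    "flag_contaminated",
    "qc_cohort",
    "MIN_CONTROL_MOLECULES",
    "DEFAULT_MOLECULE_THRESHOLD",
    "DEFAULT_RATIO_THRESHOLD",
]

MIN_CONTROL_MOLECULES = 100
#: Blanks show background below ~8 alternate duplex molecules panel-wide;
#: counts above this with a high phased-SNP ratio indicate contamination.
DEFAULT_MOLECULE_THRESHOLD = 8
DEFAULT_RATIO_THRESHOLD = 0.5


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    failed: bool
    failing_control_probes: tuple[str, ...] = ()
    contamination_ratio: float = math.nan
    contaminated: bool = False
    notes: str = ""

    @property
    def status(self) -> str:
        if self.failed:
            return "failed"
        if self.contaminated:
            return "contaminated"
        return "pass"


def detect_failed_sample(
    control_counts: dict[str, int] | pd.Series,
    min_molecules: int = MIN_CONTROL_MOLECULES,
) -> tuple[bool, list[str]]:
    """Failed iff any control probe returned fewer than ``min_molecules``.

    An empty/missing control set is itself a failure (no evidence the sample
    processed correctly).  Returns (failed, failing probe ids).
    """
    items = dict(control_counts)
    if not items:
        return True, []
    failing = sorted(p for p, c in items.items() if c < min_molecules)
    return bool(failing), failing


def contamination_ratio(n_both_snps: int, n_variant_covering_second_site: int) -> float:
    """Fraction of variant molecules (covering the linked-SNP site) that also
    carry the phased SNP; NaN when no molecule covers both sites."""
    if n_both_snps < 0 or n_variant_covering_second_site < 0:
        raise ValueError("molecule counts must be non-negative")
    if n_both_snps > n_variant_covering_second_site:
        raise ValueError(
            "molecules with both SNPs cannot exceed molecules covering both sites"
        )
    if n_variant_covering_second_site == 0:
        return math.nan
    return n_both_snps / n_variant_covering_second_site


def flag_contaminated(
    total_alt_duplex: int,
    ratio: float,
    molecule_threshold: int = DEFAULT_MOLECULE_THRESHOLD,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> bool:
    """Blank-sample contamination flag: both conditions must hold.

    Elevated molecules with a near-zero phased ratio are elevated background,
    not contamination; a high ratio on a handful of molecules is within
    blank noise.
    """
    if not np.isfinite(ratio):
        return False
    return total_alt_duplex > molecule_threshold and ratio > ratio_threshold


def qc_cohort(
    counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    blank_sample_ids: set[str] | None = None,
    min_molecules: int = MIN_CONTROL_MOLECULES,
    molecule_threshold: int = DEFAULT_MOLECULE_THRESHOLD,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list[QCReport]:
    """QC every sample in a cohort; a pure function of the count tables.

    ``counts`` is the molecule-count table (with ``phased_both`` /
    ``phased_denominator`` columns when phased-SNP data exist);
    ``control_counts`` has (probe_id, sample_id, count).  Contamination is
    only assessed for ``blank_sample_ids``.
    """
    reports = []
    sample_ids = sorted(
        set(counts["sample_id"]).union(control_counts["sample_id"])
    )
    ctrl_by_sample = {
        sid: dict(zip(grp["probe_id"], grp["count"]))
        for sid, grp in control_counts.groupby("sample_id")
    }
    for sid in sample_ids:
        failed, failing = detect_failed_sample(
            ctrl_by_sample.get(sid, {}), min_molecules
        )
        notes = "missing control-probe data" if sid not in ctrl_by_sample else ""
        ratio = math.nan
        contaminated = False
        if blank_sample_ids is not None and sid in blank_sample_ids:
            sample = counts[counts["sample_id"] == sid]
            total_dup = int(sample["duplex_alt"].sum())
            if {"phased_both", "phased_denominator"} <= set(sample.columns):
                num = int(sample["phased_both"].sum())
                den = int(sample["phased_denominator"].sum())
                ratio = contamination_ratio(num, den)
            contaminated = flag_contaminated(
                total_dup, ratio, molecule_threshold, ratio_threshold
            )
            if total_dup > molecule_threshold and not contaminated:
                notes = (notes + "; " if notes else "") + "elevated background"
        reports.append(
            QCReport(
                sample_id=sid,
                failed=failed,
                failing_control_probes=tuple(failing),
                contamination_ratio=ratio,
                contaminated=contaminated,
                notes=notes,
            )
        )
    return reports
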