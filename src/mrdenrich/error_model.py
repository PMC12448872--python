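"""Background-error modelling from blank (expected-negative) samples.

Sequencing assays for rare variants see spurious alternate molecules from
polymerase errors, hybridization-buffer damage and low-level somatic
background.  Error rates depend strongly on the substitution type (e.g. C>T
deamination artefacts) and are higher for molecules observed on a single
strand than for duplex-confirmed molecules.

Two Gamma priors on the per-site Poisson error rate λ_e are provided:

* a **type-level prior**, moment-matched across all probes of one
  substitution type: α = μ²/σ², β = μ/σ² where μ and σ² are the mean and
  variance of the per-probe rate estimates;
* a **site-specific prior**, the conjugate Gamma posterior of the counts
  observed at one site in N blank samples under a weak Gamma(0.1, 1) prior:
  α = 0.1 + Σx_i, β = 1 + N.

Both use the rate parameterization (mean α/β).  The Gamma prior marginalizes
the Poisson likelihood into a negative binomial, which downstream thresholding
and MRD calling use directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BackgroundPrior",
    "SUBSTITUTION_TYPES",
    "per_site_error_rate",
    "type_prior",
    "site_prior",
    "fit_type_priors",
    "fit_site_priors",
]

#: SNV substitution classes (pyrimidine-context convention) and indel classes:
#: single/multi-base deletions and insertions.
SUBSTITUTION_TYPES = (
    "C>A", "C>G", "C>T", "T>A", "T>C", "T>G",
    "SDEL", "SINS", "MDEL", "MINS",
)


@dataclass(frozen=True)
class BackgroundPrior:
    """Gamma(alpha, beta) prior on a per-site error rate (rate param., mean α/β)."""

    alpha: float
    beta: float
    scope: Literal["substitution-type", "site-specific"] = "substitution-type"
    substitution_type: str | None = None

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Gamma parameters must be positive, got α={self.alpha}, β={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / self.beta


class DegeneratePriorError(ValueError):
    """Raised when moment matching is impossible (zero variance across probes)."""


def per_site_error_rate(counts: Sequence[float]) -> float:
    """Per-site error-rate estimate λ̂: the mean count across blank samples."""
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        return float("nan")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return float(x.mean())


def type_prior(
    rates: Sequence[float],
    substitution_type: str | None = None,
    ddof: int = 0,
) -> BackgroundPrior:
    """Moment-matched Gamma prior across all probes of one substitution type.

    α = μ²/σ², β = μ/σ².  ``ddof=0`` (population variance) by default;
    pass ``ddof=1`` for the sample-variance convention.
    """
    r = np.asarray(rates, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 2:
        raise ValueError("need at least two probe rate estimates for moment matching")
    mu = float(r.mean())
    var = float(r.var(ddof=ddof))
    # var below float noise relative to mu^2 is effectively zero
    if mu <= 0 or var <= mu * mu * 1e-12:
        raise DegeneratePriorError(
            "zero variance or mean across probes: moment matching is degenerate; "
            "use the site-specific prior instead"
        )
    return BackgroundPrior(
        alpha=mu * mu / var,
        beta=mu / var,
        scope="substitution-type",
        substitution_type=substitution_type,
    )


def site_prior(counts: Sequence[float], substitution_type: str | None = None) -> BackgroundPrior:
    """Site-specific prior: conjugate Gamma posterior of blank counts.

    Under x_i ~ Poisson(λ_e) and λ_e ~ Gamma(0.1, 1), the posterior is
    Gamma(0.1 + Σ x_i, 1 + N); this posterior serves as the per-site prior in
    downstream detection and MRD models.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one blank-sample count")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return BackgroundPrior(
        alpha=0.1 + float(x.sum()),
        beta=1.0 + x.size,
        scope="site-specific",
        substitution_type=substitution_type,
    )


def _blank_counts(records: pd.DataFrame, channel: str) -> pd.DataFrame:
    col = {"duplex": "duplex_alt", "single_strand": "single_strand_alt"}[channel]
    return records[["probe_id", "sample_id", col]].rename(columns={col: "count"})


def fit_type_priors(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    channel: Literal["duplex", "single_strand"] = "duplex",
    exclude_ms: bool = True,
    ddof: int = 0,
) -> pd.DataFrame:
    """Fit one moment-matched prior per substitution type from blank counts.

    ``records`` is a molecule-count table restricted to blank samples;
    ``panel`` maps ``probe_id`` to ``substitution_type`` and ``ms_flag``.
    Microsatellite/homopolymer-flagged probes are excluded by default because
    polymerase slippage inflates their rates far beyond their class.
    Duplex and single-strand channels are always fitted separately.
    Returns a tidy frame (substitution_type, channel, alpha, beta, n_probes).
    """
    probes = panel
    if exclude_ms and "ms_flag" in panel.columns:
        probes = panel[~panel["ms_flag"].astype(bool)]
    counts = _blank_counts(records, channel)
    merged = counts.merge(
        probes[["probe_id", "substitution_type"]], on="probe_id", how="inner"
    )
    rows = []
    for sub, grp in merged.groupby("substitution_type", sort=True):
        rates = grp.groupby("probe_id")["count"].mean()
        try:
            prior = type_prior(rates.to_numpy(), substitution_type=str(sub), ddof=ddof)
        except (ValueError, DegeneratePriorError):
            continue
        rows.append(
            {"substitution_type": sub, "channel": channel,
             "alpha": prior.alpha, "beta": prior.beta, "n_probes": rates.size}
        )
    return pd.DataFrame(
        rows, columns=["substitution_type", "channel", "alpha", "beta", "n_probes"]
    )


def fit_site_priors(
    records: pd.DataFrame,
    channel: Literal["duplex", "single_strand"] = "duplex",
) -> pd.DataFrame:
    """Fit the conjugate site-specific prior for every probe from blank counts.

    Returns a tidy frame (probe_id, channel, alpha, beta, n_samples).
    """
    counts = _blank_counts(records, channel)
    rows = []
    for probe, grp in counts.groupby("probe_id", sort=True):
        prior = site_prior(grp["count"].to_numpy())
        rows.append(
            {"probe_id": probe, "channel": channel,
             "alpha": prior.alpha, "beta": prior.beta, "n_samples": len(grp)}
        )
    return pd.DataFrame(rows)
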