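"""Per-variant calling: FPR budgets, count thresholds, LoD95 and VAF inference.

The assay is modelled as a Poisson process per probe: the expected number of
recovered alternate molecules for probe p in sample i at input VAF f is

    mu = r_p * s_i * C * f  + background

where C is the number of haploid genome copies loaded into library prep,
s_i a positive per-sample scaling factor and r_p the probe's recovery rate
(expected alternate molecules per input alternate molecule).  Background
error molecules follow a Poisson with a Gamma-distributed rate, so the
marginal background count is negative binomial.

* ``call_threshold`` finds the smallest count whose background tail
  probability stays within a per-variant false-positive budget,
* ``lod95`` inverts the signal model to the input VAF at which 95% of
  samples exceed that threshold,
* ``infer_vaf`` forms a grid posterior over f from duplex and single-strand
  counts jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import BackgroundPrior

__all__ = [
    "ProbePerformance",
    "VariantCall",
    "fpr_budget",
    "call_threshold",
    "call_threshold_fixed_rate",
    "calibrate_probe_performance",
    "lod95",
    "infer_vaf",
    "crossvalidate",
]

_DEFAULT_GRID = np.logspace(-7, 0, 500)


@dataclass(frozen=True)
class ProbePerformance:
    """Calibrated per-probe signal model.

    ``rate`` is the expected recovered alternate molecules per unit exposure
    (haploid copies x VAF x sample scaling).  ``duplex_fraction`` splits the
    rate between the duplex and single-strand observation channels.
    """

    probe_id: str
    rate: float
    duplex_fraction: float = 0.5
    background_duplex: BackgroundPrior | None = None
    background_single: BackgroundPrior | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("probe rate must be non-negative")
        if not (0.0 <= self.duplex_fraction <= 1.0):
            raise ValueError("duplex_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class VariantCall:
    probe_id: str
    sample_id: str
    called: bool
    threshold: int
    vaf_mean: float
    vaf_interval: tuple[float, float]


def fpr_budget(n_samples: int = 160, n_variants: int = 2199) -> float:
    """Per-variant FPR bound giving < 1 expected false positive across a cohort.

    1 / (n_samples * n_variants): e.g. 160 samples x 2199 tracked variants
    gives 2.84e-6 per variant.
    """
    if n_samples < 1 or n_variants < 1:
        raise ValueError("n_samples and n_variants must be >= 1")
    return 1.0 / (n_samples * n_variants)


def _nb_params(prior: BackgroundPrior) -> tuple[float, float]:
    # Poisson(λ) with λ ~ Gamma(α, β)  =>  marginal NB(r=α, p=β/(β+1))
    return prior.alpha, prior.beta / (prior.beta + 1.0)


def call_threshold(prior: BackgroundPrior, fpr: float, k_max: int = 10_000) -> int:
    """Smallest count k* whose background tail P(X >= k*) <= fpr.

    The background count X marginalizes the Gamma rate prior exactly:
    X ~ NegativeBinomial(r=α, p=β/(β+1)).  Monotone non-increasing in fpr.
    """
    if not (0.0 < fpr < 1.0):
        raise ValueError(f"fpr must lie in (0, 1), got {fpr!r}")
    r, p = _nb_params(prior)
    k = np.arange(0, k_max + 1)
    tail = stats.nbinom.sf(k - 1, r, p)  # P(X >= k)
    ok = np.nonzero(tail <= fpr)[0]
    if ok.size == 0:
        raise RuntimeError("no threshold below k_max meets the FPR bound")
    return int(k[ok[0]])


def call_threshold_fixed_rate(lam: float, fpr: float, k_max: int = 10_000) -> int:
    """Threshold under a degenerate (point-mass) background rate λ."""
    if not (0.0 < fpr < 1.0):
        raise ValueError(f"fpr must lie in (0, 1), got {fpr!r}")
    if lam < 0:
        raise ValueError("rate must be non-negative")
    if lam == 0:
        return 1  # any signal exceeds a zero background
    k = np.arange(0, k_max + 1)
    tail = stats.poisson.sf(k - 1, lam)
    ok = np.nonzero(tail <= fpr)[0]
    if ok.size == 0:
        raise RuntimeError("no threshold below k_max meets the FPR bound")
    return int(k[ok[0]])


def calibrate_probe_performance(
    counts: np.ndarray | list[float],
    sample_scalings: np.ndarray | list[float],
    copies: float,
    vaf: float,
    probe_id: str = "",
    background: BackgroundPrior | None = None,
    duplex_fraction: float = 0.5,
    background_single: BackgroundPrior | None = None,
) -> ProbePerformance:
    """Maximum-likelihood Poisson rate from known-VAF calibration samples.

    r̂ = (Σ x_i - Σ background mean) / Σ (s_i * C * f), floored at zero.
    ``counts`` are total alternate molecules per calibration sample.
    """
    x = np.asarray(counts, dtype=float)
    s = np.asarray(sample_scalings, dtype=float)
    if x.size == 0 or x.size != s.size:
        raise ValueError("counts and sample_scalings must be equal-length, non-empty")
    exposure = float((s * copies * vaf).sum())
    if exposure <= 0:
        raise ValueError("total exposure is zero; cannot calibrate")
    bg = (background.mean + (background_single.mean if background_single else 0.0)) if background else 0.0
    rate = max(0.0, (float(x.sum()) - bg * x.size) / exposure)
    return ProbePerformance(
        probe_id=probe_id,
        rate=rate,
        duplex_fraction=duplex_fraction,
        background_duplex=background,
        background_single=background_single,
    )


def lod95(
    perf: ProbePerformance,
    fpr: float,
    copies: float,
    sample_scaling: float = 1.0,
    power: float = 0.95,
    tol: float = 1e-6,
) -> float:
    """Input VAF at which ``power`` of samples exceed the calling threshold.

    The threshold k* is set from the probe's background prior at the given
    per-variant FPR; detection power at VAF f is P(X >= k*) for
    X ~ Poisson(r s C f + background mean).  Solved by bisection on f to an
    absolute tolerance ``tol``; returns 1.0 when even pure tumour cannot
    reach the target power, and inf when the probe has zero rate.
    """
    if perf.rate <= 0:
        return math.inf  # LoD undefined: reported as > 100%
    if perf.background_duplex is None:
        k_star = 1
        bg_mean = 0.0
    else:
        k_star = call_threshold(perf.background_duplex, fpr)
        bg_mean = perf.background_duplex.mean

    def detection_power(f: float) -> float:
        mu = perf.rate * sample_scaling * copies * f + bg_mean
        return float(stats.poisson.sf(k_star - 1, mu))

    lo, hi = 0.0, 1.0
    if detection_power(hi) < power:
        return 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if detection_power(mid) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def _log_nb_poisson_mixture(x: int, prior: BackgroundPrior | None, mu: np.ndarray) -> np.ndarray:
    """log P(x | signal mean mu) with the background Gamma prior marginalized.

    X = B + S with B ~ NB(α, β/(β+1)) (Gamma-Poisson background) and
    S ~ Poisson(mu); evaluated by convolution over the background count.
    ``mu`` is a vector (grid of signal means); returns a same-shape vector.
    """
    mu = np.asarray(mu, dtype=float)
    if prior is None:
        return stats.poisson.logpmf(x, np.maximum(mu, 1e-300))
    r, p = _nb_params(prior)
    b = np.arange(0, x + 1)
    log_nb = stats.nbinom.logpmf(b, r, p)  # (x+1,)
    with np.errstate(divide="ignore"):
        log_pois = stats.poisson.logpmf(x - b[:, None], np.maximum(mu[None, :], 1e-300))
    from scipy.special import logsumexp

    return logsumexp(log_nb[:, None] + log_pois, axis=0)


def infer_vaf(
    duplex_count: int,
    single_count: int,
    perf: ProbePerformance,
    copies: float,
    sample_scaling: float = 1.0,
    grid: np.ndarray | None = None,
) -> tuple[float, tuple[float, float]]:
    """Grid posterior over the input VAF from one probe's channel counts.

    Duplex and single-strand counts enter as independent Poisson likelihood
    factors with channel rates r*d and r*(1-d) and their own Gamma background
    priors marginalized exactly.  The prior over f is flat on a log-spaced
    grid (1e-7..1, 500 points by default).  Returns the posterior mean and
    the central 95% credible interval.
    """
    g = _DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    exposure = perf.rate * sample_scaling * copies
    mu_dup = exposure * perf.duplex_fraction * g
    mu_ss = exposure * (1.0 - perf.duplex_fraction) * g
    loglik = _log_nb_poisson_mixture(int(duplex_count), perf.background_duplex, mu_dup)
    loglik = loglik + _log_nb_poisson_mixture(int(single_count), perf.background_single, mu_ss)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    mean = float((post * g).sum())
    cdf = np.cumsum(post)
    lo = float(g[np.searchsorted(cdf, 0.025)])
    hi = float(g[min(np.searchsorted(cdf, 0.975), g.size - 1)])
    return mean, (lo, hi)


def crossvalidate(
    cohort: pd.DataFrame,
    copies: float,
    folds: int = 4,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Held-out VAF predictions by K-fold cross-validation over samples.

    ``cohort`` needs columns sample_id, probe_id, duplex_alt,
    single_strand_alt, vaf, scaling.  For each outer fold, probe rates are
    calibrated on the training samples at their known VAFs; VAF is then
    inferred for each held-out (sample, probe) pair.  Fold assignment is a
    seeded permutation of samples, so results are reproducible.
    """
    samples = sorted(cohort["sample_id"].unique())
    if folds < 2 or folds > len(samples):
        raise ValueError("folds must be between 2 and the number of samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    assignment = {samples[i]: int(order[i] % folds) for i in range(len(samples))}
    rows = []
    for k in range(folds):
        test_samples = {s for s, fk in assignment.items() if fk == k}
        train = cohort[~cohort["sample_id"].isin(test_samples)]
        test = cohort[cohort["sample_id"].isin(test_samples)]
        for probe, ptrain in train.groupby("probe_id", sort=True):
            totals = (ptrain["duplex_alt"] + ptrain["single_strand_alt"]).to_numpy(float)
            exposure = (ptrain["scaling"] * copies * ptrain["vaf"]).to_numpy(float)
            if exposure.sum() <= 0:
                continue
            rate = max(0.0, totals.sum() / exposure.sum())
            dup = ptrain["duplex_alt"].sum()
            tot = totals.sum()
            dfrac = float(dup / tot) if tot > 0 else 0.5
            perf = ProbePerformance(probe_id=str(probe), rate=rate, duplex_fraction=dfrac)
            for _, row in test[test["probe_id"] == probe].iterrows():
                mean, (lo, hi) = infer_vaf(
                    int(row["duplex_alt"]), int(row["single_strand_alt"]),
                    perf, copies, float(row["scaling"]), grid=grid,
                )
                rows.append(
                    {"sample_id": row["sample_id"], "probe_id": probe, "fold": k,
                     "true_vaf": row["vaf"], "vaf_mean": mean,
                     "vaf_lo": lo, "vaf_hi": hi}
                )
    return pd.DataFrame(rows)
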