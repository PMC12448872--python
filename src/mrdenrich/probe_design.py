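"""Bait-probe design: candidate enumeration, features, scoring, panel sampling.

A bait probe hybridizes across a targeted variant; its 3' end sits close to
the variant so that enzymatic digestion of a perfectly matched probe-target
duplex releases only variant-carrying molecules.  Effective probes need a
melting temperature above a floor (default 65 °C), a GC content that is not
too low (< 35% probes barely work), no germline SNP within 25 bp of the 3'
end (a mismatch there blocks digestion entirely), and no microsatellite /
homopolymer context (slippage-driven errors).

The workflow: enumerate all (upstream, downstream) length combinations
around the variant, filter by Tm, compute sequence features, score each
candidate with a pluggable regressor, and keep the best design per variant.
``sample_panel`` then draws a clinically representative panel (90% SNV /
10% indel by default, indels split evenly across classes, indel length
<= 40) from a scored variant pool, optionally thresholding on per-type
median scores.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp, gc_fraction

__all__ = [
    "VariantTarget",
    "ProbeDesign",
    "enumerate_candidates",
    "melting_temperature",
    "compute_features",
    "score_probes",
    "select_best",
    "sample_panel",
    "train_default_scorer",
    "FEATURE_COLUMNS",
    "design_probe",
]

SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
INDEL_CLASSES = ("SDEL", "SINS", "MDEL", "MINS")

DEFAULT_TM_MIN = 65.0
LOW_GC_THRESHOLD = 0.35
SNP_3PRIME_WINDOW = 25
MAX_INDEL_LENGTH = 40

FEATURE_COLUMNS = (
    "tm", "length", "upstream_length", "downstream_length", "gc_content",
    "variant_offset_from_3prime", "snp_within_25bp_of_3prime",
    "ms_or_homopolymer_flag", "low_gc_flag",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantTarget:
    """A variant with its sequence context.

    ``pos`` is 1-based; ``context`` is the reference sequence surrounding the
    variant with ``context_offset`` the 0-based index of the variant's first
    reference base within it.  ``nearby_snps`` lists (offset_from_variant,
    alleles) for known germline SNPs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    context: str
    context_offset: int
    nearby_snps: tuple[tuple[int, str], ...] = ()
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.variant_class not in SNV_CLASSES + INDEL_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if not (0 <= self.context_offset < len(self.context)):
            raise ValueError("context_offset must index into the context sequence")


@dataclass(frozen=True)
class ProbeDesign:
    """One candidate bait probe for a variant."""

    probe_id: str
    sequence: str
    tm: float
    gc_content: float
    upstream_length: int
    downstream_length: int
    variant_offset_from_3prime: int
    snp_within_25bp_of_3prime: bool
    ms_or_homopolymer_flag: bool
    strand: str = "+"
    score: float = math.nan

    @property
    def length(self) -> int:
        return len(self.sequence)


def melting_temperature(
    sequence: str,
    na_mM: float = 50.0,
    oligo_nM: float = 250.0,
) -> float:
    """Nearest-neighbour duplex melting temperature in °C.

    Unified nearest-neighbour thermodynamics with 50 mM Na+ and 250 nM
    oligo by default; deterministic and symmetric under reverse complement.
    Ambiguity codes are rejected.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence must be at least 8 nt for a meaningful Tm")
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT characters: {sequence!r}")
    return float(
        MeltingTemp.Tm_NN(seq, Na=na_mM, dnac1=oligo_nM, dnac2=0.0)
    )


def _has_ms_or_homopolymer(seq: str, min_run: int = 6, min_tandem: int = 3) -> bool:
    """Homopolymer run >= min_run, or >= min_tandem tandem copies of a 2-6-mer."""
    if re.search(r"(A{%d}|C{%d}|G{%d}|T{%d})" % ((min_run,) * 4), seq):
        return True
    for unit in range(2, 7):
        pattern = re.compile(r"(.{%d})\1{%d,}" % (unit, min_tandem - 1))
        if pattern.search(seq):
            return True
    return False


def enumerate_candidates(
    target: VariantTarget,
    upstream_range: tuple[int, int] = (3, 12),
    downstream_range: tuple[int, int] = (15, 60),
    both_strands: bool = False,
) -> list[ProbeDesign]:
    """All (upstream, downstream) length combinations of probe around a variant.

    The probe covers ``downstream`` bases 5' of the variant, the variant
    itself (its alternate allele, so a matched duplex forms only on variant
    molecules), and ``upstream`` bases towards the probe 3' end; the variant
    offset from the 3' end therefore equals the upstream length.  Ranges are
    inclusive.  With ``both_strands`` the reverse-complement designs are
    added too.
    """
    lo_u, hi_u = upstream_range
    lo_d, hi_d = downstream_range
    need_left = hi_d
    need_right = hi_u
    i = target.context_offset
    var_len = max(len(target.ref), 1)
    if i - need_left < 0 or i + var_len + need_right > len(target.context):
        raise ValueError(
            f"context too short: need {need_left} bases upstream and "
            f"{need_right} past the variant, have {i} and "
            f"{len(target.context) - i - var_len}"
        )
    alt_insert = target.alt
    designs = []
    for up in range(lo_u, hi_u + 1):
        for down in range(lo_d, hi_d + 1):
            left = target.context[i - down : i]
            right = target.context[i + var_len : i + var_len + up]
            seq = left + alt_insert + right
            for strand in (("+", "-") if both_strands else ("+",)):
                s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
                designs.append(
                    _build_design(target, s, up, down, strand)
                )
    return designs


def _build_design(
    target: VariantTarget, seq: str, up: int, down: int, strand: str
) -> ProbeDesign:
    # the variant sits `up` bases from the 3' end; a SNP at signed offset o
    # from the variant sits up - o bases from the 3' end
    snp_near = False
    for offset, _ in target.nearby_snps:
        pos_from_3prime = up - offset
        within_probe = -down <= offset <= up
        if within_probe and 0 <= pos_from_3prime <= SNP_3PRIME_WINDOW:
            snp_near = True
            break
    return ProbeDesign(
        probe_id=f"{target.variant_id or target.chrom + ':' + str(target.pos)}"
        f":u{up}d{down}{strand}",
        sequence=seq,
        tm=melting_temperature(seq),
        gc_content=float(gc_fraction(seq)),
        upstream_length=up,
        downstream_length=down,
        variant_offset_from_3prime=up,
        snp_within_25bp_of_3prime=snp_near,
        ms_or_homopolymer_flag=_has_ms_or_homopolymer(seq),
        strand=strand,
    )


def compute_features(design: ProbeDesign) -> dict[str, float]:
    """Feature vector used by the probe scorer."""
    return {
        "tm": design.tm,
        "length": float(design.length),
        "upstream_length": float(design.upstream_length),
        "downstream_length": float(design.downstream_length),
        "gc_content": design.gc_content,
        "variant_offset_from_3prime": float(design.variant_offset_from_3prime),
        "snp_within_25bp_of_3prime": float(design.snp_within_25bp_of_3prime),
        "ms_or_homopolymer_flag": float(design.ms_or_homopolymer_flag),
        "low_gc_flag": float(design.gc_content < LOW_GC_THRESHOLD),
    }


class Scorer(Protocol):
    """Anything mapping a feature matrix (n, len(FEATURE_COLUMNS)) to scores."""

    def predict(self, X: np.ndarray) -> np.ndarray: ...


def _synthetic_recovery(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Generative link from features to observed probe recovery (score scale).

    Encodes the empirical structure of functional probes: recovery rises
    with GC up to a plateau, collapses below 35% GC, declines with length
    (synthesis yield), and is abolished by a SNP near the 3' end or a
    repetitive context.  Multiplicative noise keeps the fit honest.
    """
    tm, length, _, _, gc, _, snp, ms, low_gc = X.T
    base = 320.0 / (1.0 + np.exp(-(gc - 0.42) * 14.0))
    base *= np.exp(-np.maximum(length - 40.0, 0.0) / 120.0)
    base *= 1.0 / (1.0 + np.exp(-(tm - 63.0)))
    base *= np.where(low_gc > 0, 0.15, 1.0)
    base *= np.where(ms > 0, 0.2, 1.0)
    base *= np.where(snp > 0, 0.02, 1.0)
    return base * rng.lognormal(0.0, 0.25, size=base.shape)


def train_default_scorer(
    n_train: int = 3000, seed: int = 0, return_r2: bool = False
):
    """Train the shipped random-forest probe scorer on simulator-generated data.

    Draws random feature vectors, generates recovery targets through the
    synthetic feature-to-recovery link, and fits a RandomForestRegressor.
    With ``return_r2`` also returns the held-out r² on a 25% split.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.metrics import r2_score
    from sklearn.model_selection import train_test_split

    rng = np.random.default_rng(seed)
    n = n_train
    gc = rng.uniform(0.2, 0.8, n)
    length = rng.uniform(24, 138, n)
    up = rng.integers(3, 13, n).astype(float)
    down = length - up - 1
    tm = 40.0 + 55.0 * gc + 0.12 * length + rng.normal(0, 1.5, n)
    snp = (rng.random(n) < 0.05).astype(float)
    ms = (rng.random(n) < 0.05).astype(float)
    low = (gc < LOW_GC_THRESHOLD).astype(float)
    X = np.column_stack([tm, length, up, down, gc, up, snp, ms, low])
    y = _synthetic_recovery(X, rng)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.25, random_state=seed)
    model = RandomForestRegressor(n_estimators=120, random_state=seed, n_jobs=1)
    model.fit(X_tr, y_tr)
    if return_r2:
        return model, float(r2_score(y_te, model.predict(X_te)))
    return model


def score_probes(designs: Sequence[ProbeDesign], scorer: Scorer) -> list[ProbeDesign]:
    """Score every design with the given regressor; returns new instances."""
    if not designs:
        return []
    X = np.array([[compute_features(d)[c] for c in FEATURE_COLUMNS] for d in designs])
    scores = np.asarray(scorer.predict(X), dtype=float)
    if scores.shape != (len(designs),):
        raise ValueError("scorer returned a score vector of the wrong shape")
    return [
        ProbeDesign(**{**d.__dict__, "score": float(s)})
        for d, s in zip(designs, scores)
    ]


def select_best(designs: Sequence[ProbeDesign], tm_min: float = DEFAULT_TM_MIN) -> ProbeDesign:
    """Highest-scoring design passing the Tm filter.

    Ties break to the shorter design, then lexicographic sequence.  When no
    design passes the filter, the error names the best rejected Tm.
    """
    passing = [d for d in designs if d.tm >= tm_min]
    if not passing:
        best_tm = max((d.tm for d in designs), default=math.nan)
        raise ValueError(
            f"no design reaches Tm >= {tm_min} °C (best rejected Tm: {best_tm:.1f} °C)"
        )
    return min(passing, key=lambda d: (-d.score, d.length, d.sequence))


def design_probe(
    target: VariantTarget,
    scorer: Scorer,
    tm_min: float = DEFAULT_TM_MIN,
    upstream_range: tuple[int, int] = (3, 12),
    downstream_range: tuple[int, int] = (15, 60),
    both_strands: bool = False,
) -> ProbeDesign:
    """Enumerate, Tm-filter, score and select the best probe for one variant."""
    candidates = enumerate_candidates(target, upstream_range, downstream_range, both_strands)
    passing = [d for d in candidates if d.tm >= tm_min]
    if not passing:
        return select_best(candidates, tm_min)  # raises with the best rejected Tm
    return select_best(score_probes(passing, scorer), tm_min)


def sample_panel(
    pool: pd.DataFrame,
    panel_size: int = 1800,
    snv_fraction: float = 0.90,
    snv_mix: dict[str, float] | None = None,
    score_thresholds: dict[str, float] | None = None,
    median_threshold_mode: bool = False,
    max_indel_length: int = MAX_INDEL_LENGTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a clinically representative panel from a scored variant pool.

    ``pool`` needs columns variant_id, variant_class ("SNV"/"InDel"),
    substitution_type, score, indel_length.  The panel honours the
    SNV/indel split, the SNV substitution-type mix, equal counts of the four
    indel classes, and the indel length cap.  ``median_threshold_mode``
    restricts to variants scoring above their type's median score
    (the well-performing-probes panel mode); explicit ``score_thresholds``
    per class override the medians.  Sampling is seeded and raises naming
    the deficient stratum when the pool cannot satisfy a stratum.
    """
    rng = np.random.default_rng(seed)
    pool = pool[
        (pool["variant_class"] == "SNV")
        | (pool["indel_length"] <= max_indel_length)
    ].copy()

    thresholds: dict[str, float] = {}
    if median_threshold_mode:
        for klass, grp in pool.groupby("variant_class"):
            thresholds[str(klass)] = float(grp["score"].median())
    if score_thresholds:
        thresholds.update(score_thresholds)
    if thresholds:
        keep = np.ones(len(pool), dtype=bool)
        for klass, thr in thresholds.items():
            keep &= ~((pool["variant_class"] == klass) & (pool["score"] <= thr))
        pool = pool[keep]

    n_indel = round(panel_size * (1.0 - snv_fraction))
    n_snv = panel_size - n_indel
    mix = snv_mix or {t: 1.0 / 6.0 for t in SNV_CLASSES}
    total_mix = sum(mix.values())

    chosen = []
    snv_counts = {t: round(n_snv * mix[t] / total_mix) for t in mix}
    # fix rounding drift on the largest stratum
    drift = n_snv - sum(snv_counts.values())
    if drift:
        largest = max(snv_counts, key=snv_counts.get)
        snv_counts[largest] += drift
    for sub, want in snv_counts.items():
        stratum = pool[(pool["variant_class"] == "SNV") & (pool["substitution_type"] == sub)]
        if len(stratum) < want:
            raise ValueError(
                f"pool has {len(stratum)} {sub} SNVs but the panel needs {want}"
            )
        chosen.append(stratum.sample(n=want, random_state=int(rng.integers(2**31))))
    base, extra = divmod(n_indel, len(INDEL_CLASSES))
    for i, klass in enumerate(INDEL_CLASSES):
        want = base + (1 if i < extra else 0)
        stratum = pool[pool["substitution_type"] == klass]
        if len(stratum) < want:
            raise ValueError(
                f"pool has {len(stratum)} {klass} indels but the panel needs {want}"
            )
        chosen.append(stratum.sample(n=want, random_state=int(rng.integers(2**31))))
    panel = pd.concat(chosen, ignore_index=True)
    return panel.sort_values("variant_id", kind="stable").reset_index(drop=True)
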