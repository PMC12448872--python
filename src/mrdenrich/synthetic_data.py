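"""Synthetic assay generator: probe panels, dilution series and read records.

Emulates the data a variant-selective capture assay produces across a VAF
dilution series, with the statistical structure every downstream stage
assumes:

* a probe panel (default 90% SNV / 10% indel, indels split equally among
  single/multi insertion/deletion classes, indel length <= 40) whose design
  scores drive per-probe recovery rates through a logistic link,
* per-(probe, sample) duplex and single-strand molecule counts: recovered
  alternate molecules ~ Poisson(s_i * eps_p * C * f) and wild-type
  ~ Poisson(s_i * (eps_p / S_p) * C * (1 - f)), with substitution-type-
  dependent Gamma-distributed background error rates (single-strand rates a
  fixed multiple of duplex rates), per-sample log-normal scaling s_i,
  control probes, dropout samples and optional phased-SNP cross-
  contamination of blanks,
* optional read-level records (bundles with shared breakpoints, per-strand
  reads, UMI errors) feeding the molecule counter.

Every simulated table ships with its ground truth so estimators can be
validated.  All randomness flows from one seed through named per-stage
generators, so the panel, counts and reads can be regenerated independently.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molecule_counter import ReadRecord

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_panel",
    "simulate_counts",
    "simulate_reads",
    "score_to_step_efficiency",
    "SNV_TYPES",
    "INDEL_TYPES",
]

SNV_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
INDEL_TYPES = ("SDEL", "SINS", "MDEL", "MINS")

#: SNV substitution-type mix approximating the somatic spectrum of lung
#: cancers (C>A transversions from tobacco exposure dominate).
DEFAULT_SNV_MIX = {
    "C>A": 0.38, "C>G": 0.12, "C>T": 0.28,
    "T>A": 0.06, "T>C": 0.10, "T>G": 0.06,
}

#: Default Gamma(alpha, beta) priors on the per-probe duplex background error
#: rate (expected spurious alternate molecules per blank sample), by
#: substitution type.  C>T carries the classic deamination excess; multi-base
#: indel classes include a microsatellite-prone tail handled separately via
#: the ms flag.
DEFAULT_ERROR_PRIORS = {
    "C>A": (0.5, 600.0),
    "C>G": (0.5, 800.0),
    "C>T": (0.8, 300.0),
    "T>A": (0.5, 800.0),
    "T>C": (0.6, 500.0),
    "T>G": (0.5, 800.0),
    "SDEL": (0.5, 500.0),
    "SINS": (0.5, 500.0),
    "MDEL": (0.5, 400.0),
    "MINS": (0.5, 400.0),
}

#: Elevated error prior for microsatellite/homopolymer-flagged indel probes
#: (polymerase slippage).
MS_ERROR_PRIOR = (1.0, 20.0)

N_CONTROL_PROBES = 5

# Logistic link anchors: a probe scoring 200 achieves a 0.47 enrichment-step
# efficiency; the ceiling and midpoint are generator choices.
_LINK_MAX = 0.85
_LINK_MID = 150.0
_LINK_SLOPE = -math.log(_LINK_MAX / 0.47 - 1.0) / (200.0 - _LINK_MID)


def score_to_step_efficiency(score: np.ndarray | float) -> np.ndarray | float:
    """Logistic link from design score to enrichment-step recovery efficiency.

    Calibrated so a score of 200 maps to 0.47; saturates at 0.85.
    """
    return _LINK_MAX / (1.0 + np.exp(-_LINK_SLOPE * (np.asarray(score, float) - _LINK_MID)))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic assay.

    Defaults mirror a tumour-informed MRD dilution experiment: 20 ng
    (20 000 pg) of DNA into library preparation at 3.158 pg per haploid
    genome (~6333 haploid copies), a 90/10 SNV/indel panel, dilution levels
    from 10% VAF down to 1 ppm plus blanks, ~40% library-preparation
    efficiency, and a 12.5% sample dropout rate.
    """

    n_probes: int = 1800
    snv_fraction: float = 0.90
    indel_fraction: float = 0.10
    input_mass_pg: float = 20_000.0
    pg_per_haploid_genome: float = 3.158
    vaf_levels: tuple[float, ...] = (0.1, 0.01, 0.001, 1e-4, 1e-5, 1e-6, 0.0)
    replicates_per_level: int = 4
    library_efficiency: float = 0.40
    duplex_probability: float = 0.5
    sample_sd: float = 0.2
    error_prior_by_type: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_PRIORS)
    )
    ss_to_duplex_error_ratio: float = 10.0
    dropout_probability: float = 0.125
    contamination: tuple[float, bool] | None = None  # (fraction of blanks, phased-SNP flag)
    snv_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SNV_MIX))
    ms_fraction_multibase_indel: float = 0.25
    selectivity_log_mean: float = math.log(35.0)
    selectivity_log_sd: float = 0.9
    score_mean: float = 200.0
    score_sd: float = 60.0
    umi_length: int = 8
    reads_per_strand: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "snv_fraction": self.snv_fraction,
            "indel_fraction": self.indel_fraction,
            "library_efficiency": self.library_efficiency,
            "dropout_probability": self.dropout_probability,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if not math.isclose(self.snv_fraction + self.indel_fraction, 1.0):
            raise ValueError("snv_fraction + indel_fraction must equal 1")
        if not (0.0 < self.duplex_probability <= 1.0):
            raise ValueError("duplex_probability must lie in (0, 1]")
        if self.input_mass_pg <= 0 or self.pg_per_haploid_genome <= 0:
            raise ValueError("masses must be positive")
        if self.ss_to_duplex_error_ratio < 1.0:
            raise ValueError("single-strand error rates cannot be below duplex rates")
        if any(not (0.0 <= f <= 1.0) for f in self.vaf_levels):
            raise ValueError("vaf_levels must lie in [0, 1]")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def haploid_copies(self) -> float:
        return self.input_mass_pg / self.pg_per_haploid_genome

    def rng(self, stream: str) -> np.random.Generator:
        """Named per-stage generator derived from the single config seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(stream.encode()),))
        return np.random.default_rng(ss)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying every simulated table."""

    probes: pd.DataFrame   # probe_id, score, epsilon, selectivity, lambda_duplex, lambda_single, ...
    samples: pd.DataFrame | None = None  # sample_id, vaf, scaling, dropout, contaminated


def _indel_length(rng: np.random.Generator, klass: str) -> int:
    if klass in ("SDEL", "SINS"):
        return 1
    # multi-base: geometric-tailed lengths, capped at the short-read-resolvable 40 bp
    return int(min(40, 2 + rng.geometric(0.35)))


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a probe panel with design scores and per-probe ground truth.

    Substitution types follow ``config.snv_mix`` for SNVs; indels are split
    equally among SDEL/SINS/MDEL/MINS (remainders to the earlier classes).
    Each probe receives a design score, a recovery rate
    eps_p = library_efficiency x logistic(score), a true selectivity S_p
    (log-normal), and duplex/single-strand background error rates drawn from
    the substitution-type Gamma priors (microsatellite-flagged multi-base
    indel probes draw from an elevated prior).
    """
    rng = config.rng("panel")
    n_indel = round(config.n_probes * config.indel_fraction)
    n_snv = config.n_probes - n_indel

    types: list[str] = []
    mix_types = list(config.snv_mix)
    mix_p = np.array([config.snv_mix[t] for t in mix_types], float)
    mix_p /= mix_p.sum()
    types.extend(rng.choice(mix_types, size=n_snv, p=mix_p))
    base, extra = divmod(n_indel, len(INDEL_TYPES))
    for i, klass in enumerate(INDEL_TYPES):
        types.extend([klass] * (base + (1 if i < extra else 0)))

    rows = []
    for i, sub in enumerate(types):
        is_indel = sub in INDEL_TYPES
        score = float(np.clip(rng.normal(config.score_mean, config.score_sd), 1.0, 450.0))
        ms_flag = bool(
            is_indel and sub in ("MDEL", "MINS")
            and rng.random() < config.ms_fraction_multibase_indel
        )
        eps = config.library_efficiency * float(score_to_step_efficiency(score))
        sel = float(rng.lognormal(config.selectivity_log_mean, config.selectivity_log_sd))
        a, b = (MS_ERROR_PRIOR if ms_flag else config.error_prior_by_type[sub])
        lam_dup = float(rng.gamma(a, 1.0 / b))
        lam_ss = lam_dup * config.ss_to_duplex_error_ratio
        rows.append(
            {
                "probe_id": f"P{i:04d}",
                "substitution_type": sub,
                "variant_class": "InDel" if is_indel else "SNV",
                "indel_length": _indel_length(rng, sub) if is_indel else 0,
                "score": score,
                "ms_flag": ms_flag,
                "snp_flag": False,
                "is_control": False,
                "epsilon": eps,
                "selectivity": sel,
                "lambda_duplex": lam_dup,
                "lambda_single": lam_ss,
            }
        )
    for j in range(N_CONTROL_PROBES):
        rows.append(
            {
                "probe_id": f"CTRL{j}",
                "substitution_type": "C>T",
                "variant_class": "control",
                "indel_length": 0,
                "score": config.score_mean,
                "ms_flag": False,
                "snp_flag": False,
                "is_control": True,
                "epsilon": config.library_efficiency
                * float(score_to_step_efficiency(config.score_mean)),
                "selectivity": 1.0,
                "lambda_duplex": 0.0,
                "lambda_single": 0.0,
            }
        )
    panel = pd.DataFrame(rows)
    truth = SyntheticTruth(probes=panel.copy())
    return panel, truth


def _sample_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for f in config.vaf_levels:
        for _ in range(config.replicates_per_level):
            rows.append(
                {
                    "sample_id": f"S{idx:03d}",
                    "vaf": float(f),
                    "scaling": float(rng.lognormal(0.0, config.sample_sd)),
                    "dropout": bool(rng.random() < config.dropout_probability),
                    "contaminated": False,
                }
            )
            idx += 1
    samples = pd.DataFrame(rows)
    if config.contamination is not None:
        frac, _phased = config.contamination
        blanks = samples.index[samples["vaf"] == 0.0]
        for i in blanks:
            if rng.random() < frac:
                samples.loc[i, "contaminated"] = True
    return samples


def simulate_counts(
    panel: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate per-(probe, sample) molecule counts and control-probe counts.

    Returns ``(counts, control_counts, truth)`` where ``counts`` has one row
    per (probe, sample) with duplex/single-strand alternate and wild-type
    molecule counts plus phased-SNP columns used by contamination QC, and
    ``control_counts`` holds one row per (control probe, sample).  The
    returned truth extends the input truth with the sample table.
    """
    rng = config.rng("counts")
    samples = _sample_table(config, rng)
    probes = panel[~panel["is_control"]].reset_index(drop=True)
    controls = panel[panel["is_control"]].reset_index(drop=True)
    C = config.haploid_copies

    eps = probes["epsilon"].to_numpy(float)
    sel = probes["selectivity"].to_numpy(float)
    lam_d = probes["lambda_duplex"].to_numpy(float)
    lam_s = probes["lambda_single"].to_numpy(float)
    n_p = len(probes)

    count_frames = []
    control_rows = []
    for _, srow in samples.iterrows():
        f, s = float(srow["vaf"]), float(srow["scaling"])
        sid = srow["sample_id"]
        alt_true = rng.poisson(s * eps * C * f)
        wt_true = rng.poisson(s * (eps / sel) * C * (1.0 - f))
        alt_dup = rng.binomial(alt_true, config.duplex_probability)
        alt_ss = alt_true - alt_dup
        wt_dup = rng.binomial(wt_true, config.duplex_probability)
        wt_ss = wt_true - wt_dup
        err_dup = rng.poisson(lam_d)
        err_ss = rng.poisson(lam_s)

        contam_dup = np.zeros(n_p, dtype=int)
        phased_both = np.zeros(n_p, dtype=int)
        phased_denom = np.zeros(n_p, dtype=int)
        if bool(srow["contaminated"]):
            # a foreign DNA admixture carries the target variants together
            # with their phased germline SNPs
            contam_level = 0.003  # effective VAF of the contaminating DNA
            contam = rng.poisson(s * eps * C * contam_level * config.duplex_probability)
            contam_dup = contam
            phased_both = rng.binomial(contam, 0.9)  # most carry the linked SNP
            phased_denom = contam
        elif f == 0.0:
            # genuine background molecules do not carry the linked SNP
            phased_denom = err_dup

        frame = pd.DataFrame(
            {
                "probe_id": probes["probe_id"],
                "sample_id": sid,
                "vaf": f,
                "duplex_alt": alt_dup + err_dup + contam_dup,
                "single_strand_alt": alt_ss + err_ss,
                "duplex_wt": wt_dup,
                "single_strand_wt": wt_ss,
                "phased_both": phased_both,
                "phased_denominator": phased_denom,
            }
        )
        frame["total_alt"] = frame["duplex_alt"] + frame["single_strand_alt"]
        frame["total_wt"] = frame["duplex_wt"] + frame["single_strand_wt"]
        count_frames.append(frame)

        ctrl_counts = rng.poisson(
            s * controls["epsilon"].to_numpy(float) * C
        )
        if bool(srow["dropout"]):
            # failed samples return almost nothing for at least one control
            k = int(rng.integers(0, len(controls)))
            ctrl_counts[k] = int(rng.integers(0, 100))
        for probe_id, cnt in zip(controls["probe_id"], ctrl_counts):
            control_rows.append(
                {"probe_id": probe_id, "sample_id": sid, "count": int(cnt)}
            )

    counts = pd.concat(count_frames, ignore_index=True)
    control_counts = pd.DataFrame(control_rows)
    return counts, control_counts, SyntheticTruth(probes=truth.probes, samples=samples)


_BASES = np.array(list("ACGT"))


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_umi(rng: np.random.Generator, umi: str, n_edits: int) -> str:
    u = list(umi)
    for _ in range(n_edits):
        pos = int(rng.integers(0, len(u)))
        u[pos] = str(rng.choice(_BASES[_BASES != u[pos]]))
    return "".join(u)


def simulate_reads(
    counts: pd.DataFrame,
    config: SimConfig,
    umi_error_rate: float = 0.0,
    max_umi_edits: int = 2,
    base_error_rate: float = 0.0,
) -> list[ReadRecord]:
    """Expand a molecule-count table into aligned-read records.

    Every molecule becomes a read bundle: a fragment with shared breakpoints
    (a probe-specific locus with per-molecule start/end jitter), one UMI and
    ``config.reads_per_strand`` reads per present strand (both strands iff
    the molecule is duplex).  With probability ``umi_error_rate`` a read's
    UMI receives 1..``max_umi_edits`` substitutions; ``base_error_rate``
    flips a read's allele call.  With both rates at zero the molecule counter
    recovers the input counts exactly.
    """
    rng = config.rng("reads")
    reads: list[ReadRecord] = []
    probe_locus = {
        p: (f"chr{1 + i % 22}", 1_000_000 + 1000 * i)
        for i, p in enumerate(sorted(counts["probe_id"].unique()))
    }
    rid = 0
    for row in counts.itertuples(index=False):
        chrom, center = probe_locus[row.probe_id]
        molecules = (
            [("alt", True)] * int(row.duplex_alt)
            + [("alt", False)] * int(row.single_strand_alt)
            + [("ref", True)] * int(row.duplex_wt)
            + [("ref", False)] * int(row.single_strand_wt)
        )
        for mol_idx, (allele, is_duplex) in enumerate(molecules):
            # deterministic-unique breakpoints per molecule: distinct
            # molecules never share a fragment, so grouping is exact and
            # UMI collisions across molecules cannot occur
            start = center - 150 + (mol_idx % 140)
            end = center + 20 + (mol_idx // 140)
            umi = _random_umi(rng, config.umi_length)
            strands = STRANDS_BOTH if is_duplex else (rng.choice(["top", "bottom"]),)
            for strand in strands:
                for _ in range(config.reads_per_strand):
                    read_umi = umi
                    if umi_error_rate > 0 and rng.random() < umi_error_rate:
                        read_umi = _mutate_umi(
                            rng, umi, int(rng.integers(1, max_umi_edits + 1))
                        )
                    call = allele
                    if base_error_rate > 0 and rng.random() < base_error_rate:
                        call = "ref" if allele == "alt" else "alt"
                    reads.append(
                        ReadRecord(
                            read_id=f"r{rid:07d}",
                            chrom=chrom,
                            start=start,
                            end=end,
                            strand_of_origin=str(strand),
                            umi=read_umi,
                            base_call_at_target=call,
                            probe_id=str(row.probe_id),
                            sample_id=str(row.sample_id),
                        )
                    )
                    rid += 1
    return reads


STRANDS_BOTH = ("top", "bottom")
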