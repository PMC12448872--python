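"""Readers, writers and run configuration.

Count tables, panels and priors travel as TSV; results as TSV/JSON.  Aligned
reads are accepted either as minimal SAM (UMI in the RX tag and as a
``:UMI`` suffix on QNAME; strand of origin derived from the FLAG) or as a
native TSV dialect with explicit columns::

    read_id  chrom  start  end  strand  umi  base_at_target  probe_id  sample_id

Coordinates are 0-based half-open in the native dialect and converted from
SAM/VCF 1-based conventions on ingest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import pydantic

from .molecule_counter import ReadRecord
from .probe_design import VariantTarget

__all__ = [
    "PipelineConfig",
    "read_variants",
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "read_reads_tsv",
    "write_reads_tsv",
    "write_reads_sam",
    "read_reads_sam",
    "write_json",
]

COUNT_COLUMNS = [
    "probe_id", "sample_id", "duplex_alt", "single_strand_alt",
    "duplex_wt", "single_strand_wt", "total_alt", "total_wt",
]

READ_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand", "umi",
    "base_at_target", "probe_id", "sample_id",
]


class PipelineConfig(pydantic.BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = pydantic.ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    n_probes: int = 200
    vaf_levels: list[float] = [0.1, 0.01, 0.001, 1e-4, 0.0]
    replicates_per_level: int = 4
    input_mass_pg: float = 20_000.0
    pg_per_haploid_genome: float = 3.158
    library_efficiency: float = 0.40
    duplex_probability: float = 0.5
    sample_sd: float = 0.2
    dropout_probability: float = 0.125
    fpr_n_samples: int = 160
    fpr_n_variants: int = 2199
    min_vaf_for_selectivity: float = 0.001
    posterior_threshold: float = 0.99
    tm_min: float = 65.0
    max_edit_distance: int = 2
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _classify_variant(ref: str, alt: str) -> str:
    """Map a (ref, alt) pair onto a substitution class.

    SNVs use the pyrimidine-context convention (a purine reference base is
    complemented); indels split into single/multi deletion/insertion.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if len(ref) == 1 and len(alt) == 1:
        r, a = ref.upper(), alt.upper()
        if r in "AG":
            r, a = comp[r], comp[a]
        return f"{r}>{a}"
    if len(ref) > len(alt):
        return "SDEL" if len(ref) - len(alt) == 1 else "MDEL"
    return "SINS" if len(alt) - len(ref) == 1 else "MINS"


def read_variants(vcf_path: str | Path, context: dict[str, str] | None = None) -> list[VariantTarget]:
    """Read variant targets from a VCF; multi-allelic records are split.

    Symbolic alleles (``<DEL>`` etc.) are rejected.  ``context`` optionally
    maps variant id (chrom:pos) to a context sequence; without it a target
    gets an empty context (sufficient for counting, not for design).
    """
    import pysam

    targets = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for line_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, 1):
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt.startswith("<") or "[" in alt or "]" in alt:
                    raise ValueError(
                        f"record {line_no} ({rec.chrom}:{rec.pos}): symbolic or "
                        f"breakend allele {alt!r} is not supported"
                    )
                vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                ctx = (context or {}).get(f"{rec.chrom}:{rec.pos}", "")
                klass = _classify_variant(rec.ref, alt)
                targets.append(
                    VariantTarget(
                        chrom=rec.chrom,
                        pos=rec.pos,  # VCF 1-based, preserved
                        ref=rec.ref,
                        alt=alt,
                        variant_class=klass,
                        context=ctx or rec.ref,
                        context_offset=0,
                        variant_id=vid,
                    )
                )
    return targets


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV writer (stable column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    """Write a molecule-count table; core columns first, extras preserved."""
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table is missing required columns: {missing}")
    extras = [c for c in df.columns if c not in COUNT_COLUMNS]
    write_table(df[COUNT_COLUMNS + extras], path)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a molecule-count table.

    Missing required columns raise naming the column; extra columns are
    preserved; negative counts are rejected.
    """
    df = read_table(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table at {path} is missing columns: {missing}")
    numeric = [c for c in COUNT_COLUMNS if c not in ("probe_id", "sample_id")]
    if (df[numeric] < 0).any().any():
        raise ValueError(f"count table at {path} contains negative counts")
    return df


def write_reads_tsv(reads: Sequence[ReadRecord], path: str | Path) -> None:
    rows = [
        {
            "read_id": r.read_id, "chrom": r.chrom, "start": r.start,
            "end": r.end, "strand": r.strand_of_origin, "umi": r.umi,
            "base_at_target": r.base_call_at_target,
            "probe_id": r.probe_id, "sample_id": r.sample_id,
        }
        for r in reads
    ]
    write_table(pd.DataFrame(rows, columns=READ_COLUMNS), path)


def read_reads_tsv(path: str | Path) -> list[ReadRecord]:
    df = read_table(path)
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table at {path} is missing columns: {missing}")
    return [
        ReadRecord(
            read_id=str(r.read_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), strand_of_origin=str(r.strand), umi=str(r.umi),
            base_call_at_target=str(r.base_at_target),
            probe_id=str(r.probe_id), sample_id=str(r.sample_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_reads_sam(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Write reads as minimal SAM.

    QNAME carries the UMI as a ``:UMI`` suffix; the RX tag holds it too.
    Strand of origin maps to the reverse FLAG bit (top = forward); the base
    call, probe and sample ride in XB/XP/XS tags.  Sequence and qualities
    are omitted (``*``) — only breakpoints and tags matter downstream.
    """
    import pysam

    chroms = sorted({r.chrom for r in reads})
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": 300_000_000} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = f"{r.read_id}:{r.umi}"
            a.flag = 16 if r.strand_of_origin == "bottom" else 0
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{r.end - r.start}M"
            a.set_tag("RX", r.umi)
            a.set_tag("XB", r.base_call_at_target)
            a.set_tag("XP", r.probe_id)
            a.set_tag("XS", r.sample_id)
            out.write(a)


def read_reads_sam(path: str | Path) -> list[ReadRecord]:
    """Read the minimal SAM dialect back into read records."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            umi = a.get_tag("RX") if a.has_tag("RX") else a.query_name.rsplit(":", 1)[-1]
            reads.append(
                ReadRecord(
                    read_id=a.query_name.rsplit(":", 1)[0],
                    chrom=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    strand_of_origin="bottom" if a.is_reverse else "top",
                    umi=str(umi),
                    base_call_at_target=str(a.get_tag("XB")) if a.has_tag("XB") else "missing",
                    probe_id=str(a.get_tag("XP")) if a.has_tag("XP") else "",
                    sample_id=str(a.get_tag("XS")) if a.has_tag("XS") else "",
                )
            )
    return reads


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
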