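"""UMI read-bundle grouping and duplex-consensus molecule counting.

Reads deriving from the same original DNA fragment share their alignment
breakpoints and a unique molecular identifier (UMI), up to sequencing errors
in the UMI itself.  Reads are therefore grouped into *read bundles*: within
each identical-breakpoint group, UMIs whose Levenshtein distance is within a
collapse threshold (default <= 2) belong to the same bundle.  Each bundle
represents one input molecule.

A bundle whose consensus allele is supported by reads from **both** original
strands is a duplex molecule; support from only one strand makes it a
single-strand molecule.  Duplex confirmation corrects strand-asymmetric
errors, so duplex counts carry far lower background error rates than
single-strand counts and the two are tallied separately for both the
alternate and wild-type allele.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

__all__ = [
    "ReadRecord",
    "ReadBundle",
    "MoleculeCountRecord",
    "group_read_bundles",
    "consensus_by_strand",
    "count_molecules",
    "count_reads",
]

STRANDS = ("top", "bottom")
ALLELES = ("ref", "alt", "other", "missing")

#: Majority fraction a strand's reads must reach for a consensus call.
CONSENSUS_MAJORITY = 2.0 / 3.0


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read with its UMI and the base call at the targeted position.

    Coordinates are 0-based half-open.  ``base_call_at_target`` is the allele
    observation: "ref", "alt", "other" or "missing".
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand_of_origin: str
    umi: str
    base_call_at_target: str
    probe_id: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id!r}: start must be < end "
                f"(got {self.start} >= {self.end})"
            )
        if not self.umi or set(self.umi) - set("ACGTN"):
            raise ValueError(f"read {self.read_id!r}: invalid UMI {self.umi!r}")
        if self.strand_of_origin not in STRANDS:
            raise ValueError(
                f"read {self.read_id!r}: strand must be one of {STRANDS}"
            )
        if self.base_call_at_target not in ALLELES:
            raise ValueError(
                f"read {self.read_id!r}: allele must be one of {ALLELES}"
            )


@dataclass
class ReadBundle:
    """A cluster of reads sharing breakpoints and a UMI family: one molecule."""

    bundle_id: str
    member_read_ids: list[str]
    chrom: str
    start: int
    end: int
    canonical_umi: str
    strands_present: frozenset[str]
    probe_id: str
    sample_id: str
    reads: list[ReadRecord] = field(repr=False, default_factory=list)


@dataclass
class MoleculeCountRecord:
    """Per (probe, sample) duplex and single-strand molecule counts."""

    probe_id: str
    sample_id: str
    duplex_alt: int = 0
    single_strand_alt: int = 0
    duplex_wt: int = 0
    single_strand_wt: int = 0
    ambiguous: int = 0

    @property
    def total_alt(self) -> int:
        return self.duplex_alt + self.single_strand_alt

    @property
    def total_wt(self) -> int:
        return self.duplex_wt + self.single_strand_wt


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _cluster_umis(umi_counts: Counter, max_edit_distance: int) -> list[list[str]]:
    """Partition UMIs into clusters by edit-distance adjacency.

    Seeds are taken in descending read count (ties: lexicographic) and absorb
    every UMI reachable through a chain of pairwise distances <=
    ``max_edit_distance``; absorption follows chains, so the resulting
    partition equals the transitive closure of the pairwise adjacency
    relation.  The seed (highest-count UMI) is the canonical UMI.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: set[str] = set()
    clusters: list[list[str]] = []
    for seed in order:
        if seed in assigned:
            continue
        cluster = [seed]
        assigned.add(seed)
        frontier = [seed]
        while frontier:
            current = frontier.pop()
            for other in order:
                if other in assigned:
                    continue
                if levenshtein(current, other) <= max_edit_distance:
                    cluster.append(other)
                    assigned.add(other)
                    frontier.append(other)
        clusters.append(cluster)
    return clusters


def group_read_bundles(
    reads: Sequence[ReadRecord] | Iterable[ReadRecord],
    max_edit_distance: int = 2,
) -> list[ReadBundle]:
    """Group reads into molecule bundles by breakpoints and UMI similarity.

    Reads first split on (sample, probe, chrom, start, end); within each
    group UMIs are clustered with Levenshtein distance <= ``max_edit_distance``
    and each cluster becomes one bundle.  Read order never affects the
    result.
    """
    groups: dict[tuple, list[ReadRecord]] = defaultdict(list)
    for read in reads:
        key = (read.sample_id, read.probe_id, read.chrom, read.start, read.end)
        groups[key].append(read)

    bundles: list[ReadBundle] = []
    for key in sorted(groups):
        members = groups[key]
        umi_counts = Counter(r.umi for r in members)
        for cluster in _cluster_umis(umi_counts, max_edit_distance):
            umis = set(cluster)
            cluster_reads = sorted(
                (r for r in members if r.umi in umis), key=lambda r: r.read_id
            )
            sample_id, probe_id, chrom, start, end = key
            bundles.append(
                ReadBundle(
                    bundle_id=f"{probe_id}:{sample_id}:{chrom}:{start}-{end}:{cluster[0]}",
                    member_read_ids=[r.read_id for r in cluster_reads],
                    chrom=chrom,
                    start=start,
                    end=end,
                    canonical_umi=cluster[0],
                    strands_present=frozenset(r.strand_of_origin for r in cluster_reads),
                    probe_id=probe_id,
                    sample_id=sample_id,
                    reads=cluster_reads,
                )
            )
    return bundles


def consensus_by_strand(bundle: ReadBundle) -> dict[str, str]:
    """Per-strand majority consensus allele of a bundle.

    A strand's consensus is the allele held by at least 2/3 of that strand's
    informative reads ("missing" calls are uninformative); ties or weaker
    majorities yield "ambiguous".
    """
    if not bundle.reads:
        raise ValueError(f"bundle {bundle.bundle_id!r} has no member reads")
    consensus: dict[str, str] = {}
    for strand in STRANDS:
        calls = [
            r.base_call_at_target
            for r in bundle.reads
            if r.strand_of_origin == strand and r.base_call_at_target != "missing"
        ]
        if not calls:
            continue
        counts = Counter(calls)
        allele, top = counts.most_common(1)[0]
        if sum(1 for v in counts.values() if v == top) > 1:
            consensus[strand] = "ambiguous"
        elif top / len(calls) >= CONSENSUS_MAJORITY:
            consensus[strand] = allele
        else:
            consensus[strand] = "ambiguous"
    return consensus


def count_molecules(
    bundles: Sequence[ReadBundle],
    targets: set[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Tally bundles into per-(probe, sample) molecule counts.

    A bundle increments ``duplex_alt``/``duplex_wt`` when both strands are
    present and both consensuses agree on alt/ref, and
    ``single_strand_alt``/``single_strand_wt`` when exactly one strand has a
    consensus.  Discordant or ambiguous bundles are tallied in ``ambiguous``;
    bundles whose probe is not in ``targets`` (when given) go to an off-target
    tally.  Returns ``(count table, off_target_count)``; the table preserves
    the conservation identity duplex + single-strand + ambiguous per cell.
    """
    records: dict[tuple[str, str], MoleculeCountRecord] = {}
    off_target = 0
    for bundle in bundles:
        if targets is not None and bundle.probe_id not in targets:
            off_target += 1
            continue
        key = (bundle.probe_id, bundle.sample_id)
        rec = records.setdefault(key, MoleculeCountRecord(*key))
        cons = consensus_by_strand(bundle)
        calls = {s: a for s, a in cons.items() if a != "ambiguous"}
        if len(cons) == 2 and len(set(cons.values())) == 1 and "ambiguous" not in cons.values():
            allele = next(iter(calls.values()))
            if allele == "alt":
                rec.duplex_alt += 1
            elif allele == "ref":
                rec.duplex_wt += 1
            else:
                rec.ambiguous += 1
        elif len(cons) == 1 and len(calls) == 1:
            allele = next(iter(calls.values()))
            if allele == "alt":
                rec.single_strand_alt += 1
            elif allele == "ref":
                rec.single_strand_wt += 1
            else:
                rec.ambiguous += 1
        else:
            rec.ambiguous += 1

    rows = []
    for (probe_id, sample_id) in sorted(records):
        rec = records[(probe_id, sample_id)]
        rows.append(
            {
                "probe_id": probe_id,
                "sample_id": sample_id,
                "duplex_alt": rec.duplex_alt,
                "single_strand_alt": rec.single_strand_alt,
                "duplex_wt": rec.duplex_wt,
                "single_strand_wt": rec.single_strand_wt,
                "total_alt": rec.total_alt,
                "total_wt": rec.total_wt,
                "ambiguous": rec.ambiguous,
            }
        )
    columns = [
        "probe_id", "sample_id", "duplex_alt", "single_strand_alt",
        "duplex_wt", "single_strand_wt", "total_alt", "total_wt", "ambiguous",
    ]
    return pd.DataFrame(rows, columns=columns), off_target


def count_reads(
    reads: Sequence[ReadRecord],
    targets: set[str] | None = None,
    max_edit_distance: int = 2,
) -> tuple[pd.DataFrame, int]:
    """Convenience: bundle reads and count molecules in one call."""
    return count_molecules(group_read_bundles(reads, max_edit_distance), targets)
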