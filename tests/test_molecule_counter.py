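"""UMI bundle grouping, strand consensus and duplex/single-strand counting."""

import itertools

import numpy as np
import pytest

from mrdenrich.molecule_counter import (
    ReadBundle,
    ReadRecord,
    consensus_by_strand,
    count_molecules,
    count_reads,
    group_read_bundles,
)


def make_read(read_id, umi="AAAAAAAA", start=100, end=200, strand="top",
              call="alt", probe="p1", sample="s1", chrom="chr1"):
    return ReadRecord(
        read_id=read_id, chrom=chrom, start=start, end=end,
        strand_of_origin=strand, umi=umi, base_call_at_target=call,
        probe_id=probe, sample_id=sample,
    )


def brute_force_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_clusters(umis, max_d=2):
    """Transitive closure of pairwise edit-distance adjacency (union-find)."""
    parent = {u: u for u in umis}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in itertools.combinations(umis, 2):
        if brute_force_levenshtein(a, b) <= max_d:
            parent[find(a)] = find(b)
    groups = {}
    for u in umis:
        groups.setdefault(find(u), set()).add(u)
    return {frozenset(g) for g in groups.values()}


class TestBundleGrouping:
    def test_identical_umis_one_bundle(self):
        reads = [make_read("r1"), make_read("r2")]
        assert len(group_read_bundles(reads)) == 1

    def test_distance_three_gives_two_bundles(self):
        reads = [make_read("r1", umi="AAAAAAAA"), make_read("r2", umi="AAAAATTT")]
        assert len(group_read_bundles(reads)) == 2

    def test_distance_two_merges(self):
        reads = [make_read("r1", umi="AAAAAAAA"), make_read("r2", umi="AAAAAATT")]
        bundles = group_read_bundles(reads)
        assert len(bundles) == 1
        assert bundles[0].canonical_umi in {"AAAAAAAA", "AAAAAATT"}

    def test_different_breakpoints_never_merge(self):
        reads = [make_read("r1"), make_read("r2", start=101)]
        assert len(group_read_bundles(reads)) == 2

    def test_canonical_umi_is_highest_read_count(self):
        reads = [
            make_read("r1", umi="AAAAAAAA"),
            make_read("r2", umi="AAAAAATT"),
            make_read("r3", umi="AAAAAATT"),
        ]
        (bundle,) = group_read_bundles(reads)
        assert bundle.canonical_umi == "AAAAAATT"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        reads = [
            make_read(f"r{i}", umi="".join(rng.choice(list("ACGT"), 6)),
                      start=int(rng.choice([100, 150])))
            for i in range(20)
        ]
        base = {frozenset(b.member_read_ids) for b in group_read_bundles(reads)}
        for _ in range(5):
            rng.shuffle(reads)
            again = {frozenset(b.member_read_ids) for b in group_read_bundles(reads)}
            assert again == base

    def test_invalid_coordinates_name_the_read(self):
        with pytest.raises(ValueError, match="rbad"):
            make_read("rbad", start=200, end=100)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_transitive_oracle(self, seed):
        """Clustering equals enumerate-all-pairs transitive merging (<=50 reads)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        # short UMIs from a biased alphabet force frequent near-collisions
        umis = ["".join(rng.choice(list("AC"), 5)) for _ in range(n)]
        reads = [make_read(f"r{i}", umi=u) for i, u in enumerate(umis)]
        got = {frozenset(r.umi for r in b.reads) for b in group_read_bundles(reads)}
        expected = brute_force_clusters(set(umis))
        assert got == expected


class TestConsensus:
    def _bundle(self, calls_by_strand):
        reads = []
        i = 0
        for strand, calls in calls_by_strand.items():
            for call in calls:
                reads.append(make_read(f"r{i}", strand=strand, call=call))
                i += 1
        (bundle,) = group_read_bundles(reads)
        return bundle

    def test_unanimity(self):
        cons = consensus_by_strand(self._bundle({"top": ["alt", "alt", "alt"]}))
        assert cons == {"top": "alt"}

    def test_tie_is_ambiguous(self):
        cons = consensus_by_strand(self._bundle({"top": ["alt", "ref"]}))
        assert cons["top"] == "ambiguous"

    def test_three_quarters_majority_passes(self):
        cons = consensus_by_strand(
            self._bundle({"top": ["alt", "alt", "alt", "ref"]})
        )
        assert cons["top"] == "alt"

    def test_below_two_thirds_is_ambiguous(self):
        cons = consensus_by_strand(
            self._bundle({"top": ["alt", "alt", "ref", "ref", "ref"]})
        )
        assert cons["top"] == "ambiguous"

    def test_missing_calls_are_uninformative(self):
        cons = consensus_by_strand(self._bundle({"top": ["alt", "missing"]}))
        assert cons["top"] == "alt"


class TestCounting:
    def test_duplex_requires_both_strands_concordant(self):
        reads = [
            make_read("r1", strand="top", call="alt"),
            make_read("r2", strand="bottom", call="alt"),
        ]
        table, _ = count_reads(reads)
        assert table.iloc[0]["duplex_alt"] == 1
        assert table.iloc[0]["single_strand_alt"] == 0

    def test_one_strand_counts_single_strand(self):
        table, _ = count_reads([make_read("r1", strand="top", call="alt")])
        assert table.iloc[0]["single_strand_alt"] == 1

    def test_discordant_strands_are_ambiguous(self):
        reads = [
            make_read("r1", strand="top", call="alt"),
            make_read("r2", strand="bottom", call="ref"),
        ]
        table, _ = count_reads(reads)
        row = table.iloc[0]
        assert row["duplex_alt"] == 0 and row["ambiguous"] == 1

    def test_hand_enumerated_fixture(self):
        """2 duplex-alt, 1 single-strand-alt, 2 duplex-wt molecules."""
        reads = []
        specs = [
            ("alt", True), ("alt", True), ("alt", False),
            ("ref", True), ("ref", True),
        ]
        for i, (call, duplex) in enumerate(specs):
            start = 100 + i  # one molecule per breakpoint
            reads.append(make_read(f"m{i}t", start=start, strand="top", call=call))
            if duplex:
                reads.append(make_read(f"m{i}b", start=start, strand="bottom", call=call))
        table, off = count_reads(reads)
        row = table.iloc[0]
        assert (
            row["duplex_alt"], row["single_strand_alt"],
            row["duplex_wt"], row["single_strand_wt"],
        ) == (2, 1, 2, 0)
        assert row["total_alt"] == 3 and row["total_wt"] == 2
        assert off == 0

    def test_off_target_tally(self):
        reads = [make_read("r1", probe="unknown")]
        table, off = count_reads(reads, targets={"p1"})
        assert off == 1 and table.empty

    def test_conservation_of_bundles(self):
        rng = np.random.default_rng(9)
        reads = []
        for i in range(30):
            strand = rng.choice(["top", "bottom"])
            call = rng.choice(["alt", "ref", "other"])
            reads.append(
                make_read(f"r{i}", start=100 + int(rng.integers(0, 10)),
                          strand=str(strand), call=str(call),
                          umi="".join(rng.choice(list("ACGT"), 6)))
            )
        bundles = group_read_bundles(reads)
        table, off = count_molecules(bundles)
        counted = int(
            table[["duplex_alt", "single_strand_alt", "duplex_wt",
                   "single_strand_wt", "ambiguous"]].sum().sum()
        )
        assert counted + off == len(bundles)
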