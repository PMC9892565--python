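"""Split-site counting, enrichment, t-tests, amplicon classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rendr import simulate as sim
from rendr.facs_seq import (
    SplitJunctionIndex,
    SplitSiteCountTable,
    classify_amplicons,
    count_split_sites,
    flag_lost_sites,
    locate_split_junction,
    relative_enrichment,
    site_ttest,
)
from rendr.sequences import NucSeq, reverse_complement


@pytest.fixture(scope="module")
def guide1(input_rna):
    from rendr.sequences import design_guides

    return design_guides(input_rna, (1, 82), (82, 164)).guide1


@pytest.fixture(scope="module")
def upstream():
    return str(sim.synthetic_input(length=40, seed=9, name="upstream"))


def brute_force_assign(read, ribozyme, guide1, upstream="", k=12, max_mm=0):
    """Independent oracle: naive hamming scan of every junction at every offset.

    Implements the same assignment rule as the pipeline — exact junction
    match first, mismatch-tolerant fallback, unique site required — but by
    exhaustive scanning with no indexing.
    """
    rib, g1 = str(ribozyme), str(guide1)
    junctions = {}
    for s in range(1, len(rib)):
        prefix = upstream + rib[:s]
        if len(prefix) >= k:
            junctions[s] = prefix[-k:] + g1[:k]

    def scan(tolerance):
        hits = set()
        for r in (read, reverse_complement(read)):
            for s, j in junctions.items():
                for i in range(len(r) - 2 * k + 1):
                    if sum(a != b for a, b in zip(r[i : i + 2 * k], j)) <= tolerance:
                        hits.add(s)
                        break
        return hits

    hits = scan(0)
    if not hits and max_mm > 0:
        hits = scan(max_mm)
    return hits.pop() if len(hits) == 1 else None


class TestJunctionLocation:
    def test_error_free_read_at_site_153(self, ribozyme, guide1, upstream):
        amplicon = upstream + ribozyme.residues[:153] + guide1.residues
        read = amplicon[153 + 40 - 60 : 153 + 40 + 60]
        s, reason = locate_split_junction(read, ribozyme, guide1, upstream=upstream)
        assert (s, reason) == (153, "ok")

    def test_reverse_complement_read_found(self, ribozyme, guide1, upstream):
        amplicon = upstream + ribozyme.residues[:153] + guide1.residues
        read = reverse_complement(amplicon[133:213])
        s, _ = locate_split_junction(read, ribozyme, guide1, upstream=upstream)
        assert s == 153

    def test_pure_guide_read_unassigned(self, ribozyme, guide1):
        s, reason = locate_split_junction(guide1.residues, ribozyme, guide1)
        assert s is None and reason == "no_junction"

    def test_single_substitution_tolerated(self, ribozyme, guide1, upstream):
        amplicon = upstream + ribozyme.residues[:153] + guide1.residues
        read = list(amplicon[133:213])
        pos = 55  # inside the 24-nt junction window of this read (48..71)
        read[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[read[pos]]
        read = "".join(read)
        assert locate_split_junction(read, ribozyme, guide1, upstream=upstream)[0] == 153
        assert (
            locate_split_junction(
                read, ribozyme, guide1, upstream=upstream, max_mismatches=0
            )[0]
            is None
        )

    def test_homopolymer_junctions_are_ambiguous(self, guide1):
        rib = NucSeq("A" * 40)
        read = "A" * 12 + guide1.residues[:12]
        s, reason = locate_split_junction(read, rib, guide1)
        assert s is None and reason == "ambiguous"

    def test_short_read_reported(self, ribozyme, guide1):
        s, reason = locate_split_junction("ACGU", ribozyme, guide1)
        assert s is None and reason == "read_too_short"

    def test_guide_shorter_than_anchor_rejected(self, ribozyme):
        with pytest.raises(ValueError, match="min_anchor"):
            SplitJunctionIndex(ribozyme, "ACGUA", min_anchor=12)


class TestCounting:
    def test_counts_equal_bruteforce_on_error_free_reads(self, guide1, upstream):
        rib = sim.synthetic_ribozyme(length=80, seed=3, name="small_rib")
        rng = np.random.default_rng(5)
        counts = sim.sequencing_counts(np.full(79, 1 / 79), 2000, rng)
        records = sim.simulate_reads(
            counts, rib, guide1, upstream=upstream, read_len=60, error_rate=0.0, seed=6
        )
        reads = [r[1] for r in records]
        table = count_split_sites(
            {}, rib, guide1, upstream=upstream, reads_by_library={"lib": reads}
        )
        expected = pd.Series(0, index=table.counts.index)
        n_unassigned = 0
        for read in reads:
            s = brute_force_assign(read, rib, guide1, upstream=upstream)
            if s is None:
                n_unassigned += 1
            else:
                expected[s] += 1
        assert table.counts["lib"].equals(expected)
        assert table.total_reads("lib") == len(reads)
        assert int(table.unassigned["count"].sum()) == n_unassigned

    def test_counts_equal_bruteforce_with_sequencing_errors(self, guide1, upstream):
        rib = sim.synthetic_ribozyme(length=60, seed=4, name="tiny_rib")
        rng = np.random.default_rng(8)
        counts = sim.sequencing_counts(np.full(59, 1 / 59), 400, rng)
        records = sim.simulate_reads(
            counts, rib, guide1, upstream=upstream, read_len=60, error_rate=0.01, seed=9
        )
        reads = [r[1] for r in records]
        table = count_split_sites(
            {}, rib, guide1, upstream=upstream, reads_by_library={"lib": reads}
        )
        expected = pd.Series(0, index=table.counts.index)
        for read in reads:
            s = brute_force_assign(read, rib, guide1, upstream=upstream, max_mm=1)
            if s is not None:
                expected[s] += 1
        assert table.counts["lib"].equals(expected)

    def test_empty_fastq_gives_zero_table(self, tmp_path, ribozyme, guide1):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table = count_split_sites({"lib": path}, ribozyme, guide1)
        assert table.totals["lib"] == 0
        assert table.coverage["lib"] == 0.0

    def test_fastq_parsing_matches_in_memory_reads(self, tmp_path, guide1, upstream):
        rib = sim.synthetic_ribozyme(length=80, seed=3, name="small_rib")
        rng = np.random.default_rng(15)
        counts = sim.sequencing_counts(np.full(79, 1 / 79), 300, rng)
        path = sim.simulate_reads(
            counts, rib, guide1, upstream=upstream, read_len=60,
            error_rate=0.0, seed=16, path=tmp_path / "lib.fastq",
        )
        reads = [r[1] for r in sim.simulate_reads(
            counts, rib, guide1, upstream=upstream, read_len=60, error_rate=0.0, seed=16
        )]
        from_file = count_split_sites({"lib": path}, rib, guide1, upstream=upstream)
        in_memory = count_split_sites({}, rib, guide1, upstream=upstream,
                                      reads_by_library={"lib": reads})
        assert from_file.counts.equals(in_memory.counts)

    def test_counts_invariant_to_read_order(self, guide1, upstream):
        rib = sim.synthetic_ribozyme(length=80, seed=3, name="small_rib")
        rng = np.random.default_rng(10)
        counts = sim.sequencing_counts(np.full(79, 1 / 79), 500, rng)
        reads = [r[1] for r in sim.simulate_reads(
            counts, rib, guide1, upstream=upstream, read_len=60, error_rate=0.0, seed=11
        )]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        t1 = count_split_sites({}, rib, guide1, upstream=upstream,
                               reads_by_library={"lib": reads})
        t2 = count_split_sites({}, rib, guide1, upstream=upstream,
                               reads_by_library={"lib": shuffled})
        assert t1.counts.equals(t2.counts)

    def test_uniform_library_coverage_near_complete(self, ribozyme, guide1, upstream):
        rng = np.random.default_rng(21)
        counts = sim.sequencing_counts(np.full(419, 1 / 419), 50_000, rng)
        reads = [r[1] for r in sim.simulate_reads(
            counts, ribozyme, guide1, upstream=upstream, read_len=60,
            error_rate=0.0, seed=22,
        )]
        table = count_split_sites({}, ribozyme, guide1, upstream=upstream,
                                  reads_by_library={"lib": reads})
        assert table.coverage["lib"] >= 0.99
        assert table.frequencies["lib"].sum() == pytest.approx(1.0, abs=1e-9)


def _table_from_counts(**columns):
    sites = pd.RangeIndex(1, len(next(iter(columns.values()))) + 1, name="split_index")
    counts = pd.DataFrame({k: np.asarray(v) for k, v in columns.items()}, index=sites)
    return SplitSiteCountTable(counts, pd.DataFrame(columns=["library", "reason", "count"]),
                               n_possible_sites=len(sites))


class TestEnrichment:
    def test_enrichment_is_frequency_ratio(self):
        table = _table_from_counts(sorted_r1=[100, 900], unsorted_r1=[50, 950])
        enr = relative_enrichment(table, ["sorted_r1"], ["unsorted_r1"], pseudocount=1e-9)
        assert enr.loc[1, "enrichment"] == pytest.approx(2.0, rel=1e-6)
        assert enr.loc[1, "log2_enrichment"] == pytest.approx(1.0, rel=1e-6)

    def test_null_selection_enrichment_near_unity(self):
        rng = np.random.default_rng(30)
        p = rng.dirichlet(np.full(100, 5.0))
        table = _table_from_counts(
            sorted_r1=rng.multinomial(200_000, p), unsorted_r1=rng.multinomial(200_000, p)
        )
        enr = relative_enrichment(table, ["sorted_r1"], ["unsorted_r1"])
        assert enr["enrichment"].mean() == pytest.approx(1.0, abs=0.05)

    def test_zero_sorted_reads_flags_lost(self):
        table = _table_from_counts(sorted_r1=[0, 1000], unsorted_r1=[500, 500])
        enr = relative_enrichment(table, ["sorted_r1"], ["unsorted_r1"])
        assert bool(enr.loc[1, "lost"]) and enr.loc[1, "enrichment"] < 1
        assert not enr.loc[2, "lost"]

    def test_zero_pseudocount_with_absent_site_errors(self):
        table = _table_from_counts(sorted_r1=[10, 10], unsorted_r1=[0, 20])
        with pytest.raises(ZeroDivisionError):
            relative_enrichment(table, ["sorted_r1"], ["unsorted_r1"], pseudocount=0.0)

    def test_unknown_library_label_rejected(self):
        table = _table_from_counts(sorted_r1=[1, 2])
        with pytest.raises(KeyError):
            relative_enrichment(table, ["sorted_r1"], ["unsorted_r1"])

    def test_lost_count_monotone_in_threshold(self):
        rng = np.random.default_rng(31)
        table = _table_from_counts(
            sorted_r1=rng.multinomial(5000, rng.dirichlet(np.full(50, 0.3))),
            unsorted_r1=rng.multinomial(5000, np.full(50, 1 / 50)),
        )
        enr = relative_enrichment(table, ["sorted_r1"], ["unsorted_r1"])
        n_lost = [
            int(flag_lost_sites(enr, threshold=t)["lost"].sum())
            for t in (1e-6, 1e-4, 1e-3, 1e-2, 0.1)
        ]
        assert n_lost == sorted(n_lost)


class TestSiteTTest:
    def test_identical_groups_give_p_one(self):
        assert site_ttest([0.1, 0.1], [0.1, 0.1]) == 1.0

    def test_clearly_separated_groups_significant(self):
        p = site_ttest([0.1001, 0.0999], [0.2001, 0.1999])
        assert p < 0.05

    def test_matches_textbook_formula_on_3v3(self):
        a = np.array([0.12, 0.15, 0.11])
        b = np.array([0.08, 0.07, 0.09])
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t), df=4)
        assert site_ttest(a, b) == pytest.approx(expected, rel=1e-12)

    def test_vectorised_over_sites(self):
        a = np.array([[0.1, 0.1], [0.1, 0.3]])
        b = np.array([[0.1, 0.1], [0.1, 0.3]])
        p = site_ttest(a, b)
        assert p.shape == (2,) and np.all(p == 1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            site_ttest([0.1], [0.2, 0.3])


class TestAmpliconClassification:
    @pytest.fixture()
    def junctions(self, cds, ribozyme):
        p = 196
        exon1, exon2 = cds.residues[:p], cds.residues[p:]
        rib = ribozyme.residues
        spliced = exon1[-30:] + exon2[:30]
        unspliced5 = exon1[-30:] + rib[:30]
        unspliced3 = rib[-30:] + exon2[:30]
        return spliced, unspliced5, unspliced3

    def test_assigns_by_junction_with_precedence(self, junctions):
        spliced, unspliced5, unspliced3 = junctions
        fractions = classify_amplicons(
            [spliced, unspliced5, unspliced3, "ACGU" * 20],
            spliced, unspliced5, unspliced3,
        )
        assert fractions == {"spliced": 0.25, "unspliced": 0.5, "other": 0.25}
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_mixture_fractions_within_binomial_error(self, junctions):
        spliced, unspliced5, unspliced3 = junctions
        rng = np.random.default_rng(33)
        n = 2000
        reads = [spliced if rng.random() < 0.9 else unspliced5 for _ in range(n)]
        fractions = classify_amplicons(reads, spliced, unspliced5, unspliced3)
        se3 = 3 * math.sqrt(0.9 * 0.1 / n)
        assert abs(fractions["spliced"] - 0.9) < se3

    def test_probe_longer_than_read_rejected(self, junctions):
        spliced, unspliced5, unspliced3 = junctions
        with pytest.raises(ValueError, match="shorter than probe"):
            classify_amplicons(["ACGUACGU"], spliced, unspliced5, unspliced3, k=12)

    def test_no_reads_gives_zero_fractions(self, junctions):
        spliced, unspliced5, unspliced3 = junctions
        assert classify_amplicons([], spliced, unspliced5, unspliced3) == {
            "spliced": 0.0, "unspliced": 0.0, "other": 0.0,
        }
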