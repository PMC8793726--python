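import numpy as np
import pytest

from retrolink.genetic_distance import validate_map
from retrolink.genome_io import GeneLocus, RegulatoryNetwork, RetrocopyRecord, RetrocopyTable, ValidationError
from retrolink.retrostats import (
    candidate_sets,
    filter_out_of_x,
    mean_parent_distance,
    nearest_partner_mean,
    out_of_x_count,
    parent_weighted_mean,
)

from conftest import make_table, point
from naive_oracles import naive_x1, naive_x2, naive_x3, naive_x4


class TestOutOfXCount:
    def test_counts_x_parent_autosomal_copy_pairs(self, toy_assembly):
        table = make_table(
            [
                ("chrX", 100, "chr2", 100, "retrogene"),  # counted
                ("chrX", 100, "chrX", 900, "retrogene"),  # parent and copy both X
                ("chr2", 100, "chrX", 100, "retrogene"),  # into the X, not out
                ("chr1", 100, "chr1", 900, "retrogene"),
            ]
        )
        assert out_of_x_count(table, toy_assembly).value == 1

    def test_empty_table_counts_zero(self, toy_assembly):
        table = RetrocopyTable(records=[], parents={})
        assert out_of_x_count(table, toy_assembly).value == 0

    def test_all_pairs_out_of_x(self, toy_assembly):
        table = make_table([("chrX", 100, "chr1", i * 100, "retrogene") for i in range(1, 6)])
        assert out_of_x_count(table, toy_assembly).value == 5

    def test_pseudogenes_excluded_by_default_scope(self, toy_assembly):
        table = make_table(
            [("chrX", 100, "chr1", 100, "pseudogene"), ("chrX", 100, "chr1", 200, "retrogene")]
        )
        assert out_of_x_count(table, toy_assembly).value == 1
        assert out_of_x_count(table, toy_assembly, scope="all").value == 2

    def test_no_x_designated_is_an_error(self, toy_assembly):
        from retrolink.genome_io import GenomeAssembly

        no_x = GenomeAssembly(chromosomes=toy_assembly.chromosomes, x_name=None)
        with pytest.raises(ValidationError):
            out_of_x_count(make_table([]), no_x)


class TestFilterOutOfX:
    def test_whole_x_parent_groups_removed(self, toy_assembly):
        parents = {
            "pa": point("pa", "chrX", 100),
            "pb": point("pb", "chrX", 900),
            "pc": point("pc", "chr1", 100),
        }
        records = [
            RetrocopyRecord("r1", "pa", point("r1", "chr1", 1), "retrogene"),
            RetrocopyRecord("r2", "pa", point("r2", "chrX", 5), "retrogene"),
            RetrocopyRecord("r3", "pb", point("r3", "chr2", 1), "retrogene"),
        ] + [RetrocopyRecord(f"a{i}", "pc", point(f"a{i}", "chr2", i), "retrogene") for i in range(4)]
        table = RetrocopyTable(records=records, parents=parents)
        filtered = filter_out_of_x(table, toy_assembly)
        assert filtered.n == 4
        assert set(filtered.parents) == {"pc"}

    def test_identity_without_x_parents(self, toy_assembly):
        table = make_table([("chr1", 100, "chr2", 100, "retrogene")])
        filtered = filter_out_of_x(table, toy_assembly)
        assert filtered.records == table.records

    def test_all_x_parents_gives_empty_table(self, toy_assembly):
        table = make_table([("chrX", 100, "chr1", 100, "retrogene")])
        assert filter_out_of_x(table, toy_assembly).n == 0

    def test_filter_then_count_is_zero(self, toy_assembly):
        table = make_table(
            [("chrX", 100, "chr1", 100, "retrogene"), ("chr1", 100, "chr2", 100, "retrogene")]
        )
        assert out_of_x_count(filter_out_of_x(table, toy_assembly), toy_assembly).value == 0


class TestMeanParentDistance:
    def test_average_of_inter_and_intrachromosomal(self, toy_marey, toy_assembly):
        # one interchromosomal pair (0.5) and one pair 0.01 M apart on chr1 (2 cM/Mb)
        table = make_table(
            [("chr1", 0, "chr2", 0, "retrogene"), ("chr1", 0, "chr1", 500_000, "retrogene")]
        )
        assert mean_parent_distance(table, toy_marey).value == pytest.approx((0.5 + 0.01) / 2)

    def test_colocated_pair_is_zero(self, toy_marey):
        table = make_table([("chr1", 777, "chr1", 777, "retrogene")])
        assert mean_parent_distance(table, toy_marey).value == 0.0

    def test_constant_interchromosomal_average(self, toy_marey):
        table = make_table([("chr1", 0, "chr2", i, "retrogene") for i in range(3)])
        assert mean_parent_distance(table, toy_marey).value == 0.5

    def test_empty_scope_is_an_error(self, toy_marey):
        table = make_table([("chr1", 0, "chr2", 0, "pseudogene")])
        with pytest.raises(ValidationError, match="no retrogenes"):
            mean_parent_distance(table, toy_marey)


class TestParentWeightedMean:
    def test_two_level_average(self, toy_marey):
        # parent A: distances 0.5 (interchromosomal) and 0.1 (5 Mb won't fit chr1 at 2cM/Mb;
        # use 0.05 M = 2.5 Mb) -> redo with distances 0.5 and 0.1 via a 2 cM/Mb map point
        parents = {"A": point("A", "chr1", 0), "B": point("B", "chr1", 0)}
        records = [
            RetrocopyRecord("r1", "A", point("r1", "chr2", 0), "retrogene"),  # 0.5
            RetrocopyRecord("r2", "A", point("r2", "chr1", 2_500_000), "retrogene"),  # 0.05
            RetrocopyRecord("r3", "B", point("r3", "chr1", 1_000_000), "retrogene"),  # 0.02
        ]
        table = RetrocopyTable(records=records, parents=parents)
        expected = ((0.5 + 0.05) / 2 + 0.02) / 2
        assert parent_weighted_mean(table, toy_marey).value == pytest.approx(expected)

    def test_singleton_groups_coincide_with_x2(self, toy_marey):
        table = make_table(
            [
                ("chr1", 0, "chr2", 0, "retrogene"),
                ("chr1", 0, "chr1", 500_000, "retrogene"),
                ("chr2", 0, "chr2", 1_000_000, "retrogene"),
            ]
        )
        x2 = mean_parent_distance(table, toy_marey).value
        assert parent_weighted_mean(table, toy_marey).value == pytest.approx(x2)

    def test_single_parent_single_copy(self, toy_marey):
        table = make_table([("chr1", 0, "chr1", 500_000, "retrogene")])
        assert parent_weighted_mean(table, toy_marey).value == pytest.approx(0.01)

    def test_include_pseudogenes_widens_the_set(self, toy_marey):
        parents = {"A": point("A", "chr1", 0)}
        records = [
            RetrocopyRecord("r1", "A", point("r1", "chr1", 500_000), "retrogene"),  # 0.01
            RetrocopyRecord("r2", "A", point("r2", "chr2", 0), "pseudogene"),  # 0.5
        ]
        table = RetrocopyTable(records=records, parents=parents)
        assert parent_weighted_mean(table, toy_marey).value == pytest.approx(0.01)
        assert parent_weighted_mean(table, toy_marey, include_pseudogenes=True).value == pytest.approx(0.255)

    def test_no_nonempty_group_is_an_error(self, toy_marey):
        table = make_table([("chr1", 0, "chr2", 0, "pseudogene")])
        with pytest.raises(ValidationError):
            parent_weighted_mean(table, toy_marey)


class TestNearestPartnerMean:
    def test_min_over_parent_and_partner(self, toy_marey):
        parents = {"A": point("A", "chr2", 0)}
        records = [RetrocopyRecord("r1", "A", point("r1", "chr1", 0), "retrogene")]
        table = RetrocopyTable(records=records, parents=parents)
        network = RegulatoryNetwork.from_pairs([("A", "q")])
        loci = {"q": point("q", "chr1", 1_500_000)}  # 0.03 M from the retrogene
        stat = nearest_partner_mean(table, network, loci, toy_marey)
        assert stat.value == pytest.approx(0.03)

    def test_no_partners_falls_back_to_parent(self, toy_marey):
        parents = {"A": point("A", "chr1", 0)}
        records = [RetrocopyRecord("r1", "A", point("r1", "chr1", 500_000), "retrogene")]
        table = RetrocopyTable(records=records, parents=parents)
        stat = nearest_partner_mean(table, RegulatoryNetwork(), {}, toy_marey)
        assert stat.value == pytest.approx(0.01)

    def test_colocated_partner_gives_zero(self, toy_marey):
        parents = {"A": point("A", "chr2", 0)}
        records = [RetrocopyRecord("r1", "A", point("r1", "chr1", 42), "retrogene")]
        table = RetrocopyTable(records=records, parents=parents)
        network = RegulatoryNetwork.from_pairs([("A", "q")])
        loci = {"q": point("q", "chr1", 42)}
        assert nearest_partner_mean(table, network, loci, toy_marey).value == 0.0

    def test_unlocated_partner_excluded(self, toy_marey):
        parents = {"A": point("A", "chr1", 0)}
        records = [RetrocopyRecord("r1", "A", point("r1", "chr1", 500_000), "retrogene")]
        table = RetrocopyTable(records=records, parents=parents)
        network = RegulatoryNetwork.from_pairs([("A", "ghost")])
        assert nearest_partner_mean(table, network, {}, toy_marey).value == pytest.approx(0.01)

    def test_x4_never_exceeds_parent_distance(self, toy_marey, toy_assembly):
        """The min runs over a superset containing the parent."""
        rng = np.random.default_rng(11)
        parents = {}
        records = []
        edges = []
        loci = {}
        names = toy_assembly.names
        for i in range(20):
            pid = f"p{i}"
            parents[pid] = point(pid, names[rng.integers(3)], int(rng.integers(0, 900_000)))
            records.append(
                RetrocopyRecord(f"r{i}", pid, point(f"r{i}", names[rng.integers(3)], int(rng.integers(0, 900_000))), "retrogene")
            )
            for j in range(rng.integers(0, 3)):
                qid = f"q{i}_{j}"
                loci[qid] = point(qid, names[rng.integers(3)], int(rng.integers(0, 900_000)))
                edges.append((pid, qid))
        table = RetrocopyTable(records=records, parents=parents)
        network = RegulatoryNetwork.from_pairs(edges)
        from retrolink.genetic_distance import dist

        for rec, cands in zip(table.retrogenes(), candidate_sets(table, network, loci)):
            x4 = min(dist(rec.locus, c, toy_marey) for c in cands)
            assert x4 <= dist(rec.locus, parents[rec.parent_id], toy_marey) + 1e-15


def _random_case(rng):
    """A random toy dataset in both package and plain-Python form."""
    n_chrom = int(rng.integers(2, 5))
    names = [f"c{i}" for i in range(n_chrom)]
    x_name = names[int(rng.integers(n_chrom))]
    length = 1_000_000
    raw = {}
    for name in names:
        k = int(rng.integers(1, 6))  # may be unmapped (k == 1)
        bp = np.sort(rng.choice(np.arange(1, length), size=k, replace=False))
        cm = np.sort(rng.uniform(0, 10, size=k))
        raw[name] = (bp, cm)
    mm = validate_map(raw)
    maps = {name: list(zip(bp.tolist(), cm.tolist())) for name, (bp, cm) in raw.items()}

    n_parents = int(rng.integers(1, 6))
    parents, groups, rows, edges, loci = {}, [], [], [], {}
    records = []
    for i in range(n_parents):
        pid = f"p{i}"
        parents[pid] = point(pid, names[int(rng.integers(n_chrom))], int(rng.integers(0, length)))
        group = []
        for j in range(int(rng.integers(0, 5))):
            rc = names[int(rng.integers(n_chrom))]
            rp = int(rng.integers(0, length))
            status = "retrogene" if rng.random() < 0.7 else "pseudogene"
            records.append(RetrocopyRecord(f"r{i}_{j}", pid, point(f"r{i}_{j}", rc, rp), status))
            p = parents[pid]
            group.append((p.chrom, p.point_bp, rc, rp, status))
        groups.append(group)
        rows.extend(group)
        for j in range(int(rng.integers(0, 3))):
            qid = f"q{i}_{j}"
            edges.append((pid, qid))
            if rng.random() < 0.8:  # sometimes a partner lacks coordinates
                loci[qid] = point(qid, names[int(rng.integers(n_chrom))], int(rng.integers(0, length)))
    table = RetrocopyTable(records=records, parents=parents)
    network = RegulatoryNetwork.from_pairs(edges)
    return table, network, loci, mm, maps, rows, groups, x_name


def test_statistics_match_brute_force_on_random_tables(toy_assembly):
    """X1-X4 agree with independent naive recomputations over 120 random tables."""
    from retrolink.genome_io import GenomeAssembly

    rng = np.random.default_rng(2024)
    checked = {"x1": 0, "x2": 0, "x3": 0, "x4": 0}
    for _ in range(120):
        table, network, loci, mm, maps, rows, groups, x_name = _random_case(rng)
        names = sorted({r[0] for r in rows} | {r[2] for r in rows} | set(maps))
        assembly = GenomeAssembly(
            chromosomes=tuple((n, 1_000_000) for n in names), x_name=x_name if x_name in names else None
        )
        if assembly.x_name is not None:
            got = out_of_x_count(table, assembly).value
            assert got == naive_x1(rows, x_name)
            checked["x1"] += 1
        if any(r[4] == "retrogene" for r in rows):
            assert mean_parent_distance(table, mm).value == pytest.approx(naive_x2(rows, maps), abs=1e-12)
            assert parent_weighted_mean(table, mm).value == pytest.approx(naive_x3(groups, maps), abs=1e-12)
            checked["x2"] += 1
            checked["x3"] += 1
            # nearest-partner statistic against the naive min-then-mean
            retro_rows = [(r.locus.chrom, r.locus.point_bp) for r in table.retrogenes()]
            cand_plain = [
                [(c.chrom, c.point_bp) for c in cands]
                for cands in candidate_sets(table, network, loci)
            ]
            assert nearest_partner_mean(table, network, loci, mm).value == pytest.approx(
                naive_x4(retro_rows, cand_plain, maps), abs=1e-12
            )
            checked["x4"] += 1
    assert all(v >= 100 for v in checked.values()), checked
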