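"""BLAST filtering, gene flagging and operon calling."""

import numpy as np
import pytest

from mdmnet.operons import (
    BlastHit,
    GeneFlags,
    GeneRecord,
    call_putative_adaptation_operons,
    cluster_operons,
    default_keywords,
    filter_hits,
    filter_scaffolds,
    flag_genes,
    load_keywords,
    mine_scaffolds,
    parse_blast_tabular,
    read_gene_table,
    read_gff3,
    write_blast_tabular,
    write_gene_table,
)

from _oracles import bruteforce_operons, bruteforce_putative


def _hit(identity=99.0, coverage=99.0, **kw):
    base = dict(
        query_id="q", subject_id="s", percent_identity=identity,
        alignment_length=1000, mismatches=5, gap_opens=0, qstart=1, qend=1000,
        sstart=1, send=1000, e_value=1e-30, bitscore=1800.0,
        query_coverage=coverage,
    )
    base.update(kw)
    return BlastHit(**base)


def _gene(gene_id, start, end, strand="+", product="x", scaffold="scf"):
    return GeneRecord(scaffold, gene_id, start, end, strand, product)


# ---------------------------------------------------------------------------
# BLAST parsing


def test_parse_12_column_coverage_from_query_length(tmp_path):
    line = "q1\ts1\t97.5\t1510\t30\t2\t1\t1510\t5000\t6509\t1e-50\t2500"
    path = tmp_path / "b.tsv"
    path.write_text(line + "\n")
    hits = parse_blast_tabular(path, query_lengths={"q1": 1510})
    assert hits[0].query_coverage == pytest.approx(100.0)
    with pytest.raises(ValueError, match="no coverage column"):
        parse_blast_tabular(path)


def test_parse_13_column_coverage_verbatim_and_reversed_span(tmp_path):
    lines = [
        "q1\ts1\t97.5\t800\t5\t0\t1\t800\t1\t800\t1e-30\t1500\t88.4",
        "q1\ts1\t97.5\t800\t5\t0\t800\t1\t800\t1\t1e-30\t1500",  # minus strand
    ]
    path = tmp_path / "b.tsv"
    path.write_text("\n".join(lines) + "\n")
    hits = parse_blast_tabular(path, query_lengths={"q1": 1000})
    assert hits[0].query_coverage == pytest.approx(88.4)
    assert hits[1].query_coverage == pytest.approx(80.0)  # |1-800|+1 span


def test_parse_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "b.tsv"
    path.write_text("q1\ts1\tnot_a_number\t1\t1\t1\t1\t1\t1\t1\t1\t1\t99\n")
    with pytest.raises(ValueError, match="line 1"):
        parse_blast_tabular(path)
    path.write_text("q1\ts1\t90\n")
    with pytest.raises(ValueError, match="12 or 13"):
        parse_blast_tabular(path)


def test_blast_roundtrip(tmp_path):
    hits = [_hit(97.123, 96.456), _hit(80.0, 50.0, query_id="q2")]
    path = tmp_path / "out.tsv"
    write_blast_tabular(hits, path)
    back = parse_blast_tabular(path)
    assert [h.query_id for h in back] == ["q", "q2"]
    assert back[0].percent_identity == pytest.approx(97.123)
    assert back[0].query_coverage == pytest.approx(96.456)


# ---------------------------------------------------------------------------
# Filters


@pytest.mark.parametrize(
    "identity, coverage, kept",
    [(97.0, 98.0, True), (94.9, 99.0, False), (95.0, 95.0, True), (99.0, 94.99, False)],
)
def test_hit_filter_inclusive_boundaries(identity, coverage, kept):
    out = filter_hits([_hit(identity, coverage)])
    assert bool(out) is kept


@pytest.mark.parametrize("n_genes, kept", [(98, True), (49, False), (50, True)])
def test_scaffold_filter_inclusive_boundary(n_genes, kept):
    genes = [_gene(f"g{i}", 100 * i + 1, 100 * i + 50) for i in range(n_genes)]
    out = filter_scaffolds({"scf": genes})
    assert ("scf" in out) is kept


# ---------------------------------------------------------------------------
# Flagging


def test_flag_genes_keywords_and_case():
    genes = [
        _gene("g1", 1, 10, product="hypothetical protein"),
        _gene("g2", 20, 30, product="rubrerythrin"),
        _gene("g3", 40, 50, product="Ferritin-Like Protein"),
        _gene("g4", 60, 70, product="50S ribosomal protein"),
        _gene("g5", 80, 90, product="DUF3501 domain protein, peroxide stress"),
    ]
    flags = flag_genes(genes, ["rubrerythrin", "ferritin", "peroxide"])
    assert flags["g1"] == GeneFlags(True, False)
    assert flags["g2"] == GeneFlags(False, True)
    assert flags["g3"] == GeneFlags(False, True)
    assert flags["g4"] == GeneFlags(False, False)
    assert flags["g5"] == GeneFlags(True, True)  # a gene may carry both flags
    with pytest.raises(ValueError):
        flag_genes(genes, [])


def test_packaged_keyword_list_loads():
    terms = default_keywords()
    assert "rubrerythrin" in terms and len(terms) > 20


# ---------------------------------------------------------------------------
# Operon clustering


def test_gap_boundaries():
    a = _gene("a", 1, 1000)
    close = _gene("b", 6000, 7000)  # gap 4999
    at_cut = _gene("c", 12001, 13000)  # gap to b: 5000
    ops = cluster_operons([a, close, at_cut])
    assert len(ops) == 1  # all chained at <= 5000
    far = _gene("d", 1000 + 5002, 20000)  # gap 5001 from a
    ops = cluster_operons([a, far])
    assert len(ops) == 2


def test_opposite_strands_never_merge():
    a = _gene("a", 1, 1000, strand="+")
    b = _gene("b", 1100, 2000, strand="-")
    ops = cluster_operons([a, b])
    assert len(ops) == 2
    assert all(len(op.members) == 1 for op in ops)


def test_overlapping_genes_merge_with_warning():
    a = _gene("a", 1, 1000)
    b = _gene("b", 500, 1500)
    with pytest.warns(UserWarning, match="overlap"):
        ops = cluster_operons([a, b])
    assert len(ops) == 1


def test_size_cap_splits_runs():
    genes = [_gene(f"g{i}", 1000 * i + 1, 1000 * i + 500) for i in range(12)]
    ops = cluster_operons(genes, size_cap=10)
    assert sorted(len(o.members) for o in ops) == [2, 10]


def test_multi_scaffold_input_rejected():
    with pytest.raises(ValueError, match="multiple scaffolds"):
        cluster_operons([_gene("a", 1, 10, scaffold="s1"), _gene("b", 1, 10, scaffold="s2")])


def _random_scaffold(rng, n_genes=25):
    genes = []
    pos = {"+": 1, "-": 1}
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.choice([50, 800, 4999, 5000, 5001, 9000]))
        length = int(rng.integers(100, 2000))
        start = pos[strand] + gap
        genes.append(_gene(f"g{i}", start, start + length - 1, strand=strand))
        pos[strand] = start + length
    return genes


def test_cluster_operons_matches_bruteforce_single_linkage(rng):
    for _ in range(50):
        genes = _random_scaffold(rng)
        ours = {frozenset(op.gene_ids) for op in cluster_operons(genes)}
        assert ours == bruteforce_operons(genes)


def test_window_cap_blocks_distant_adaptation_gene():
    # a chain of 13 genes in one operon: hypothetical at one end, the only
    # adaptation gene 12 positions away - outside the 10-gene window
    genes = [_gene(f"g{i}", 400 * i + 1, 400 * i + 200) for i in range(13)]
    flags = {g.gene_id: GeneFlags(False, False) for g in genes}
    flags["g0"] = GeneFlags(True, False)
    flags["g12"] = GeneFlags(False, True)
    ops = cluster_operons(genes)
    assert len(ops) == 1
    called = call_putative_adaptation_operons(ops, flags)
    assert not called[0].is_putative_adaptation
    assert bruteforce_putative(ops[0].members, flags) is False
    # bringing the adaptation gene into the window flips the call
    flags["g5"] = GeneFlags(False, True)
    called = call_putative_adaptation_operons(ops, flags)
    assert called[0].is_putative_adaptation


def test_hypothetical_only_operon_not_flagged():
    genes = [_gene(f"g{i}", 300 * i + 1, 300 * i + 100) for i in range(4)]
    flags = {g.gene_id: GeneFlags(True, False) for g in genes}
    called = call_putative_adaptation_operons(cluster_operons(genes), flags)
    assert not called[0].is_putative_adaptation
    assert called[0].n_hypothetical == 4 and called[0].n_adaptation == 0


def test_oxidative_stress_neighborhood_is_flagged():
    products = ["hypothetical protein", "Fe-S oxidoreductase", "rubrerythrin",
                "DNA-binding ferritin-like protein DPS"]
    genes = [_gene(f"g{i}", 500 * i + 1, 500 * i + 400, product=p)
             for i, p in enumerate(products)]
    flags = flag_genes(genes, default_keywords())
    called = call_putative_adaptation_operons(cluster_operons(genes), flags)
    assert called[0].is_putative_adaptation


def test_monotonicity_in_gap_and_window(rng):
    for _ in range(20):
        genes = _random_scaffold(rng, n_genes=20)
        flags = {
            g.gene_id: GeneFlags(rng.random() < 0.4, rng.random() < 0.3)
            for g in genes
        }
        n_small = len(cluster_operons(genes, max_gap=2000))
        n_large = len(cluster_operons(genes, max_gap=8000))
        assert n_large <= n_small
        ops = cluster_operons(genes)
        flagged = [
            sum(op.is_putative_adaptation
                for op in call_putative_adaptation_operons(ops, flags, window_genes=w))
            for w in (2, 5, 10)
        ]
        assert flagged == sorted(flagged)


def test_operon_membership_partitions_genes(rng):
    genes = _random_scaffold(rng)
    ops = cluster_operons(genes)
    all_ids = [g for op in ops for g in op.gene_ids]
    assert sorted(all_ids) == sorted(g.gene_id for g in genes)


# ---------------------------------------------------------------------------
# I/O and end-to-end mining


def test_gene_table_roundtrip_and_gff(tmp_path):
    genes = {"scf": [_gene("g1", 1, 500, product="hypothetical protein"),
                     _gene("g2", 700, 1200, strand="-", product="rubrerythrin")]}
    path = tmp_path / "genes.tsv"
    write_gene_table(genes, path)
    back = read_gene_table(path)
    assert back["scf"] == genes["scf"]

    gff = tmp_path / "genes.gff"
    gff.write_text(
        "##gff-version 3\n"
        "scf\tsrc\tCDS\t1\t500\t.\t+\t0\tID=g1;product=hypothetical protein\n"
        "scf\tsrc\tCDS\t700\t1200\t.\t-\t0\tID=g2;product=rubrerythrin\n"
    )
    assert read_gff3(gff)["scf"] == genes["scf"]


def test_mine_scaffolds_summary():
    genes = []
    for i in range(60):
        product = "hypothetical protein" if i % 3 == 0 else (
            "rubrerythrin" if i % 7 == 0 else "elongation factor Tu")
        genes.append(_gene(f"g{i}", 600 * i + 1, 600 * i + 400, product=product))
    calls, summary = mine_scaffolds({"scf": genes, "tiny": genes[:5]},
                                    default_keywords())
    assert summary["scaffold_id"].tolist() == ["scf"]  # tiny dropped (<50 genes)
    row = summary.iloc[0]
    assert row["n_genes"] == 60
    assert row["n_hypothetical"] == 20
    assert row["n_putative_adaptation_operons"] >= 1
    assert row["n_operons"] == sum(1 for c in calls if c.scaffold_id == "scf")
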