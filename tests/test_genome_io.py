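"""Genome/annotation/expression ingestion, windows, labels and folds."""

import numpy as np
import pandas as pd
import pytest

from mtmixg.config import FlankSpec
from mtmixg.genome_io import (
    GeneRecord,
    assign_labels,
    encode_dataset,
    extract_gene_window,
    load_dataset,
    make_chromosome_folds,
    one_hot,
    read_annotations,
    read_expression,
    read_fasta,
    reverse_complement,
    save_dataset,
)


# -- FASTA -------------------------------------------------------------------


def test_read_fasta_normalizes_case_and_joins_lines(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nacgt\nACGT\n")
    assert read_fasta(p) == {"chr1": "ACGTACGT"}


def test_read_fasta_maps_iupac_codes_to_n(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c1\nACRT\n")
    assert read_fasta(p) == {"c1": "ACNT"}


def test_read_fasta_multiple_records(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">a\nAA\n>b\nCC\n")
    genome = read_fasta(p)
    assert set(genome) == {"a", "b"}
    assert {len(s) for s in genome.values()} == {2}


def test_read_fasta_rejects_duplicates_and_empty_records(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">a\nAA\n>a\nCC\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_fasta(p)
    q = tmp_path / "empty.fa"
    q.write_text(">good\nAC\n>bad\n")
    with pytest.raises(ValueError, match="bad"):
        read_fasta(q)
    with pytest.raises(FileNotFoundError):
        read_fasta(tmp_path / "missing.fa")


# -- GFF3 --------------------------------------------------------------------


GFF_HEADER = "##gff-version 3\n"


def _gff(tmp_path, rows):
    p = tmp_path / "a.gff3"
    p.write_text(GFF_HEADER + "".join("\t".join(r) + "\n" for r in rows))
    return p


def test_read_annotations_converts_coordinates(tmp_path):
    p = _gff(tmp_path, [
        ("chr1", ".", "gene", "101", "200", ".", "+", ".", "ID=g1"),
        ("chr1", ".", "gene", "101", "200", ".", "-", ".", "ID=g2"),
    ])
    recs = {r.gene_id: r for r in read_annotations(p)}
    assert (recs["g1"].tss, recs["g1"].tts) == (100, 199)
    assert (recs["g2"].tss, recs["g2"].tts) == (199, 100)
    assert recs["g1"].strand == "+" and recs["g2"].strand == "-"


def test_read_annotations_filters_feature_type(tmp_path):
    rows = [("chr1", ".", "gene", str(10 * i + 1), str(10 * i + 5), ".", "+",
             ".", f"ID=g{i}") for i in range(3)]
    rows += [("chr1", ".", "mRNA", str(10 * i + 1), str(10 * i + 5), ".", "+",
              ".", f"ID=m{i}") for i in range(5)]
    recs = read_annotations(_gff(tmp_path, rows), feature_type="gene")
    assert len(recs) == 3


def test_read_annotations_skips_unstranded_with_warning(tmp_path, caplog):
    p = _gff(tmp_path, [
        ("chr1", ".", "gene", "1", "9", ".", ".", ".", "ID=gdot"),
        ("chr1", ".", "gene", "21", "29", ".", "+", ".", "ID=gok"),
    ])
    with caplog.at_level("WARNING"):
        recs = read_annotations(p)
    assert [r.gene_id for r in recs] == ["gok"]
    assert any("gdot" in m for m in caplog.messages)


def test_read_annotations_requires_id(tmp_path):
    p = _gff(tmp_path, [("chr1", ".", "gene", "1", "9", ".", "+", ".",
                         "Name=anon")])
    with pytest.raises(ValueError, match="ID"):
        read_annotations(p)


# -- windows -----------------------------------------------------------------


def test_window_plus_strand_toy_example(toy_genome):
    spec = FlankSpec(2, 2, 1, 2)
    g = GeneRecord("g", "chr1", "+", tss=8, tts=11)
    assert extract_gene_window(g, toy_genome, spec) == "CCGGGGT"


def test_window_minus_strand_equals_revcomp_oracle(toy_genome):
    spec = FlankSpec(2, 2, 1, 2)
    g = GeneRecord("g", "chr1", "-", tss=11, tts=8)
    got = extract_gene_window(g, toy_genome, spec)
    # independent oracle: extract on the reverse-complemented chromosome
    # with mirrored coordinates as a plus-strand gene
    rc = {"chr1": reverse_complement(toy_genome["chr1"])}
    L = len(toy_genome["chr1"])
    g_rc = GeneRecord("g", "chr1", "+", tss=L - 1 - 11, tts=L - 1 - 8)
    assert got == extract_gene_window(g_rc, rc, spec)


def test_window_pads_out_of_bounds_with_n(toy_genome):
    g = GeneRecord("g", "chr1", "+", tss=0, tts=2)
    w = extract_gene_window(g, toy_genome, FlankSpec(3, 1, 0, 0))
    assert w[:3] == "NNN" and len(w) == 4


@pytest.mark.parametrize("strand,tss,tts", [
    ("+", 0, 3), ("+", 13, 15), ("-", 15, 12), ("-", 3, 0), ("+", 7, 8),
])
def test_window_length_is_always_spec_total(toy_genome, strand, tss, tts):
    spec = FlankSpec(5, 4, 3, 6)
    g = GeneRecord("g", "chr1", strand, tss, tts)
    assert len(extract_gene_window(g, toy_genome, spec)) == spec.total_length


def test_window_strand_symmetry_on_palindromic_chromosome():
    # chromosome equal to its own reverse complement
    half = "ACGTTGCAAGCT"
    genome = {"p": half + reverse_complement(half)}
    L = len(genome["p"])
    spec = FlankSpec(3, 3, 2, 2)
    fwd = GeneRecord("f", "p", "+", tss=5, tts=8)
    rev = GeneRecord("r", "p", "-", tss=L - 1 - 5, tts=L - 1 - 8)
    assert (extract_gene_window(fwd, genome, spec)
            == extract_gene_window(rev, genome, spec))


def test_window_unknown_chromosome_raises(toy_genome):
    g = GeneRecord("g", "chrX", "+", 1, 2)
    with pytest.raises(KeyError):
        extract_gene_window(g, toy_genome, FlankSpec(1, 1, 1, 1))


# -- one-hot -----------------------------------------------------------------


def test_one_hot_column_order_and_ambiguity():
    assert one_hot("A").tolist() == [[1, 0, 0, 0]]
    assert one_hot("N").tolist() == [[0, 0, 0, 0]]
    np.testing.assert_array_equal(one_hot("ATCG"), np.eye(4, dtype=np.uint8))


def test_one_hot_row_sums_and_error_position(rng):
    seq = "".join(rng.choice(list("ACGTN"), size=200))
    X = one_hot(seq)
    sums = X.sum(axis=1)
    assert set(sums.tolist()) <= {0, 1}
    assert X.sum() == sum(c != "N" for c in seq)
    with pytest.raises(ValueError, match="position 2"):
        one_hot("ACXT")


# -- labels ------------------------------------------------------------------


def _table(values):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(values))],
                         "maxTPM": values})


def test_labels_hand_computed_quantiles():
    # log_fn = identity so the quantiles act on {1,2,3,4} directly:
    # type-7 gives Q25 = 1.75 and Q75 = 3.25
    labels = assign_labels(_table([1, 2, 3, 4]), log_fn=lambda x: x)
    assert [labels[f"g{i}"] for i in range(4)] == [-1, 0, 0, 1]


def test_labels_quartile_counts_match_sort_oracle(rng):
    vals = rng.permutation(np.arange(1000) + 1.0)
    labels = assign_labels(_table(vals), log_fn=lambda x: x)
    arr = np.array([labels[f"g{i}"] for i in range(1000)])
    # brute-force oracle: sort and count
    order = np.argsort(vals)
    assert (arr == -1).sum() == 250
    assert set(arr[order[:250]]) == {-1}
    assert (arr == 1).sum() == 250
    assert (arr == 0).sum() == 500


def test_labels_degenerate_all_identical_goes_low():
    with pytest.warns(UserWarning, match="degenerate"):
        labels = assign_labels(_table([5.0] * 8))
    assert set(labels.values()) == {-1}


def test_labels_class_proportions_property(rng):
    n = 777
    vals = rng.permutation(np.linspace(0.1, 50, n))
    labels = assign_labels(_table(vals))
    arr = np.array(list(labels.values()))
    # each boundary class is within 1/n of its quantile mass; the middle
    # class picks up both boundary errors, hence 2/n
    for cls, frac, slack in ((-1, 0.25, 1), (0, 0.50, 2), (1, 0.25, 1)):
        assert abs((arr == cls).mean() - frac) <= slack / n + 1e-12


def test_labels_empty_table_raises():
    with pytest.raises(ValueError):
        assign_labels(_table([]))


# -- expression table --------------------------------------------------------


def test_read_expression_roundtrip(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("gene_id\tmaxTPM\ng1\t0.0\ng2\t7.0\n")
    df = read_expression(p)
    assert df["logMaxTPM"].tolist() == [0.0, 3.0]  # log2(tpm + 1)
    p.write_text("gene_id\tmaxTPM\ng1\t1.0\ng1\t2.0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_expression(p)


# -- folds -------------------------------------------------------------------


def _genes_on(chrom_sizes):
    genes = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            genes.append(GeneRecord(f"{chrom}_g{i}", chrom, "+", 0, 10))
    return genes


def test_folds_one_per_chromosome():
    plan = make_chromosome_folds(_genes_on({f"chr{i}": 4 for i in range(1, 6)}))
    assert plan.k == 5
    for fold in range(5):
        chroms = {g.split("_")[0] for g in plan.test_genes(fold)}
        assert len(chroms) == 1


def test_folds_grouping_and_partition():
    genes = _genes_on({"c1": 3, "c2": 2})
    plan = make_chromosome_folds(genes)
    assert plan.k == 2
    assert len(plan.test_genes(plan.chromosome_fold["c1"])) == 3
    all_ids = [g for f in range(plan.k) for g in plan.test_genes(f)]
    assert sorted(all_ids) == sorted(g.gene_id for g in genes)
    assert len(all_ids) == len(set(all_ids))


def test_folds_single_chromosome_rejected():
    with pytest.raises(ValueError):
        make_chromosome_folds(_genes_on({"c1": 5}))


# -- dataset directory -------------------------------------------------------


def test_dataset_save_load_roundtrip(encoded_tiny, tmp_path):
    save_dataset(encoded_tiny, tmp_path / "ds")
    back = load_dataset(tmp_path / "ds")
    assert back.gene_ids == encoded_tiny.gene_ids
    np.testing.assert_array_equal(back.X, encoded_tiny.X)
    np.testing.assert_array_equal(back.labels, encoded_tiny.labels)
    y = back.targets()
    assert y.shape == (len(back), 3)
    assert (y.sum(axis=1) == 1).all()


def test_encode_dataset_drops_unlabelled_genes(sim_tiny):
    cfg, data = sim_tiny
    labels = {g.gene_id: 0 for g in data.genes[:5]}
    ds = encode_dataset(data.genome, data.genes, labels, cfg.flank)
    assert len(ds) == 5
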