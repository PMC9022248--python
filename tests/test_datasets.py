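"""Tests for encoding, tiling, labels and the train/test split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pyfaidx import Fasta

from spliceml.datasets import (FULL_GEOMETRY, MINI_GEOMETRY, BlockGeometry,
                               GeneCoords, annotated_splice_sites,
                               build_labels, decode_one_hot,
                               extract_gene_sequence, gene_coords,
                               load_annotation, one_hot_encode, pad_and_tile,
                               split_train_test)
from spliceml.errors import DataError
from spliceml.junctions import TISSUES

DNA = st.text(alphabet="ACGTN", min_size=1, max_size=300)


class TestOneHot:
    def test_exact_mapping(self):
        m = one_hot_encode("ACGT")
        assert m.tolist() == [[1, 0, 0, 0], [0, 1, 0, 0],
                              [0, 0, 1, 0], [0, 0, 0, 1]]

    def test_n_and_u(self):
        assert one_hot_encode("N").tolist() == [[0, 0, 0, 0]]
        assert one_hot_encode("U").tolist() == one_hot_encode("T").tolist()
        assert one_hot_encode("acgu").tolist() == one_hot_encode("ACGT").tolist()

    def test_empty(self):
        assert one_hot_encode("").shape == (0, 4)

    def test_invalid_base_named(self):
        with pytest.raises(DataError, match="'X'"):
            one_hot_encode("ACXGT")

    @given(DNA)
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, seq):
        assert decode_one_hot(one_hot_encode(seq)) == seq


class TestPadAndTile:
    def test_single_block_full_scale(self):
        blocks = pad_and_tile("A" * 5000, FULL_GEOMETRY)
        assert len(blocks) == 1
        assert blocks[0].x.shape == (15000, 4)

    def test_three_blocks_full_scale(self):
        blocks = pad_and_tile("A" * 15000, FULL_GEOMETRY)
        assert [b.local_start for b in blocks] == [0, 5000, 10000]

    @given(st.integers(1, 8000))
    @settings(max_examples=50, deadline=None)
    def test_block_count_is_ceil(self, L):
        g = MINI_GEOMETRY
        blocks = pad_and_tile("A" * L, g)
        assert len(blocks) == -(-L // g.step)
        assert all(b.x.shape == (g.block, 4) for b in blocks)

    @given(st.integers(1, 5000))
    @settings(max_examples=30, deadline=None)
    def test_middles_reconstruct_gene_exactly_once(self, L):
        rng = np.random.default_rng(L)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
        g = MINI_GEOMETRY
        middles = []
        for b in pad_and_tile(seq, g):
            middles.append(decode_one_hot(b.x[g.flank: g.flank + g.step]))
        assert "".join(middles)[:L] == seq
        # beyond the gene everything is padding
        assert set("".join(middles)[L:]) <= {"N"}

    def test_empty_sequence_errors(self):
        with pytest.raises(DataError):
            pad_and_tile("", MINI_GEOMETRY)

    def test_geometry_invariant(self):
        g = BlockGeometry(flank=100, step=400)
        assert g.block == 400 + 2 * 100


class TestBuildLabels:
    def make_sites(self, **over):
        row = dict(chrom="chr1", position=10, strand="+", side="donor",
                   gene_id="g")
        for t in TISSUES:
            row[f"spliced_{t}"] = True
            row[f"usage_{t}"] = 0.7
            row[f"mask_{t}"] = True
        row.update(over)
        return pd.DataFrame([row])

    def test_spliced_site_layout(self):
        coords = GeneCoords("g", "chr1", 0, 50, "+")
        labels = build_labels(self.make_sites(), coords)
        assert labels[10, 0:3].tolist() == pytest.approx([0.0, 1.0, 0.7])

    def test_unspliced_default(self):
        coords = GeneCoords("g", "chr1", 0, 50, "+")
        labels = build_labels(self.make_sites(), coords)
        assert labels[5].tolist() == [1, 0, 0] * 4

    def test_masked_site_is_all_zero(self):
        coords = GeneCoords("g", "chr1", 0, 50, "+")
        labels = build_labels(self.make_sites(mask_heart=False), coords)
        assert labels[10, 0:3].tolist() == [0, 0, 0]
        assert labels[10, 3:6].tolist() == pytest.approx([0, 1, 0.7])

    def test_minus_strand_mapping(self):
        coords = GeneCoords("g", "chr1", 0, 50, "-")
        labels = build_labels(self.make_sites(), coords)
        assert labels[coords.genomic_to_local(10), 1] == 1.0
        assert labels[49 - 10, 1] == 1.0

    def test_site_outside_gene_errors(self):
        coords = GeneCoords("g", "chr1", 0, 50, "+")
        with pytest.raises(DataError):
            build_labels(self.make_sites(position=60), coords)

    def test_usage_values_within_unit_interval(self, tiny_genome):
        truth = tiny_genome["truth"]
        assert ((truth.filter(like="usage_") >= 0).all().all()
                and (truth.filter(like="usage_") <= 1).all().all())


class TestGeneSequence:
    def test_plus_strand_extraction(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\nACGTACGTCCTTGGAA\n")
        genome = Fasta(str(fa))
        coords = GeneCoords("g", "c", 4, 12, "+")
        assert extract_gene_sequence(genome, coords) == "ACGTCCTT"
        assert coords.local_to_genomic(0) == 4

    def test_minus_strand_reverse_complements(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\nAAACGGGG\n")
        genome = Fasta(str(fa))
        coords = GeneCoords("g", "c", 0, 4, "-")
        assert extract_gene_sequence(genome, coords) == "GTTT"
        # map is invertible
        for i in range(4):
            assert coords.genomic_to_local(coords.local_to_genomic(i)) == i

    def test_out_of_bounds_errors(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\nAAAA\n")
        genome = Fasta(str(fa))
        with pytest.raises(DataError):
            extract_gene_sequence(genome, GeneCoords("g", "c", 0, 10, "+"))
        with pytest.raises(DataError):
            extract_gene_sequence(genome, GeneCoords("g", "zz", 0, 2, "+"))


class TestSplit:
    def make_genes(self):
        return pd.DataFrame([
            {"gene_id": "gA", "chrom": "chr1", "species": "ref"},
            {"gene_id": "gB", "chrom": "chr2", "species": "ref"},
            {"gene_id": "gC", "chrom": "chr2", "species": "ref"},
            {"gene_id": "gM", "chrom": "m3", "species": "mouse"},
        ])

    def test_partition_is_disjoint_cover(self):
        genes = self.make_genes()
        train, test, dropped = split_train_test(genes, ["chr1"])
        assert set(train) | set(test) | set(dropped) == set(genes.gene_id)
        assert not (set(train) & set(test))

    def test_test_chromosome_assignment(self):
        train, test, _ = split_train_test(self.make_genes(), ["chr1"])
        assert test == ["gA"] and "gB" in train

    def test_ortholog_exclusion(self):
        orth = pd.DataFrame([{"gene_id": "gM", "test_gene_id": "gA",
                              "confidence": "low"},
                             {"gene_id": "gC", "test_gene_id": "gA",
                              "confidence": "high"}])
        train, test, dropped = split_train_test(self.make_genes(), ["chr1"],
                                                orthologs=orth)
        assert set(dropped) == {"gM", "gC"}
        assert train == ["gB"]

    def test_unknown_chromosome_warns_and_drops(self):
        genes = self.make_genes()
        with pytest.warns(UserWarning):
            train, test, dropped = split_train_test(
                genes, ["chr1"], known_chroms=["chr2"])
        assert "gM" in dropped


class TestAnnotation:
    def test_annotated_sites_carry_canonical_dinucleotides(self, tiny_genome):
        """Donor sites start GT and acceptor sites end AG on the
        transcribed strand -- annotation, FASTA and coordinate map agree."""
        genome = Fasta(str(tiny_genome["fasta"]))
        db = load_annotation(tiny_genome["gff"])
        checked = 0
        for gid in tiny_genome["genes"]["gene_id"][:6]:
            sites, coords = annotated_splice_sites(db, gid)
            seq = extract_gene_sequence(genome, coords)
            for s in sites:
                if s.side == "donor":
                    assert seq[s.local: s.local + 2] == "GT"
                else:
                    assert seq[s.local - 1: s.local + 1] == "AG"
                checked += 1
        assert checked >= 20

    def test_annotated_sites_match_truth_table(self, tiny_genome):
        db = load_annotation(tiny_genome["gff"])
        truth = tiny_genome["truth"]
        for gid in tiny_genome["genes"]["gene_id"][:6]:
            sites, _ = annotated_splice_sites(db, gid)
            expected = truth[(truth.gene_id == gid) & ~truth.is_decoy]
            assert {s.position for s in sites} == set(expected.position)

    def test_missing_gene_errors(self, tiny_genome):
        db = load_annotation(tiny_genome["gff"])
        with pytest.raises(DataError):
            gene_coords(db, "NOPE")
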