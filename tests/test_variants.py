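"""Variant scoring contracts on small constructed genomes."""

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from spliceml.datasets import AnnotatedSite, GeneCoords
from spliceml.errors import DataError
from spliceml.variants import (VariantRecord, apply_variant,
                               delta_score_site, filter_variants,
                               rank_candidate_snps, read_vcf,
                               score_exon_variant,
                               score_variant_near_annotation, signed_max)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def toy_genome(tmp_path_factory):
    rng = np.random.default_rng(99)
    seq = random_dna(rng, 400)
    path = tmp_path_factory.mktemp("toy") / "toy.fa"
    path.write_text(">chrT\n" + seq + "\n")
    return Fasta(str(path)), seq


class TestSignedMax:
    def test_example(self):
        assert signed_max([0.1, -0.3, 0.2, 0.05]) == -0.3

    def test_first_wins_on_tie(self):
        assert signed_max([0.3, -0.3]) == 0.3

    def test_bounds(self, rng):
        d = rng.uniform(-1, 1, 4)
        assert signed_max(d) in d


class TestApplyVariant:
    def test_substitution_plus_strand(self, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 100, seq[100], "A" if seq[100] != "A" else "C")
        alt, shift = apply_variant(seq, coords, var)
        assert shift == 0 and alt[100] == var.alt and alt[:100] == seq[:100]

    def test_substitution_minus_strand_is_complemented(self, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "-")
        from spliceml.datasets import reverse_complement
        gene_seq = reverse_complement(seq)
        var = VariantRecord("chrT", 100, seq[100], "A" if seq[100] != "A" else "C")
        alt, shift = apply_variant(gene_seq, coords, var)
        local = coords.genomic_to_local(100)
        assert alt[local] == reverse_complement(var.alt)

    def test_deletion_shifts_downstream(self, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 50, seq[50:54], seq[50])  # 3-bp deletion
        alt, shift = apply_variant(seq, coords, var)
        assert shift == -3 and len(alt) == 397
        assert alt[51:] == seq[54:]

    def test_reference_mismatch_errors(self, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        wrong = "A" if seq[10] != "A" else "C"
        with pytest.raises(DataError, match="mismatch"):
            apply_variant(seq, coords, VariantRecord("chrT", 10, wrong, "G"))


class TestDeltaScore:
    def test_identity_variant_gives_zero(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 200, seq[200], seq[200])
        ds = delta_score_site([tiny_net], genome, var, 205, coords)
        assert np.allclose(ds.deltas, 0.0)

    def test_antisymmetry_under_allele_swap(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        alt = "A" if seq[200] != "A" else "G"
        fwd = delta_score_site([tiny_net], genome,
                               VariantRecord("chrT", 200, seq[200], alt),
                               205, coords)
        # score the reverse mutation on the mutated genome sequence
        mutated = seq[:200] + alt + seq[201:]
        from spliceml.variants import apply_variant as _  # noqa: F401
        import tempfile, pathlib
        with tempfile.TemporaryDirectory() as d:
            fa = pathlib.Path(d) / "mut.fa"
            fa.write_text(">chrT\n" + mutated + "\n")
            genome_mut = Fasta(str(fa))
            rev = delta_score_site([tiny_net], genome_mut,
                                   VariantRecord("chrT", 200, alt, seq[200]),
                                   205, coords)
        assert np.allclose(fwd.deltas, -rev.deltas, atol=1e-6)

    def test_distant_substitution_changes_nothing(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        c = tiny_net.config.context
        site = 300
        pos = site - c - 5  # strictly beyond the receptive half-width
        var = VariantRecord("chrT", pos, seq[pos],
                            "A" if seq[pos] != "A" else "G")
        ds = delta_score_site([tiny_net], genome, var, site, coords)
        assert np.all(ds.deltas == 0.0)

    def test_exon_score_is_mean_of_sites(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 200, seq[200],
                            "A" if seq[200] != "A" else "G")
        s1 = delta_score_site([tiny_net], genome, var, 195, coords).signed_max
        s2 = delta_score_site([tiny_net], genome, var, 210, coords).signed_max
        combined = score_exon_variant([tiny_net], genome, var, (195, 210),
                                      coords)
        assert combined == pytest.approx((s1 + s2) / 2)

    def test_missing_exon_site_errors(self, tiny_net, toy_genome):
        genome, _ = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        with pytest.raises(DataError):
            score_exon_variant([tiny_net], genome,
                               VariantRecord("chrT", 200, "A", "C"),
                               (None, 210), coords)


class TestNearAnnotation:
    def make_sites(self, coords, positions_sides_partners):
        return [AnnotatedSite("g", "chrT", p, coords.genomic_to_local(p),
                              side, partner)
                for p, side, partner in positions_sides_partners]

    def test_no_site_in_window_returns_none(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 200, seq[200], "A" if seq[200] != "A" else "C")
        sites = self.make_sites(coords, [(300, "donor", None)])
        assert score_variant_near_annotation([tiny_net], genome, var, sites,
                                             coords) is None

    def test_paired_sites_average(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 200, seq[200], "A" if seq[200] != "A" else "C")
        near, partner = 205, 285  # partner within pair_window of the site
        sites = self.make_sites(
            coords, [(near, "acceptor", coords.genomic_to_local(partner))])
        d1 = delta_score_site([tiny_net], genome, var, near, coords).max_decrease
        d2 = delta_score_site([tiny_net], genome, var, partner, coords).max_decrease
        got = score_variant_near_annotation([tiny_net], genome, var, sites,
                                            coords)
        assert got == pytest.approx((d1 + d2) / 2)

    def test_annotation_order_invariance(self, tiny_net, toy_genome):
        genome, seq = toy_genome
        coords = GeneCoords("g", "chrT", 0, 400, "+")
        var = VariantRecord("chrT", 200, seq[200], "A" if seq[200] != "A" else "C")
        sites = self.make_sites(coords, [(205, "donor", None),
                                         (230, "acceptor", None),
                                         (180, "donor", None)])
        a = score_variant_near_annotation([tiny_net], genome, var, sites, coords)
        b = score_variant_near_annotation([tiny_net], genome, var,
                                          sites[::-1], coords)
        assert a == b


class TestFilterVariants:
    def make_inputs(self, tmp_path):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 12000)
        fa = tmp_path / "f.fa"
        fa.write_text(">chrF\n" + seq + "\n")
        genome = Fasta(str(fa))
        bounds = pd.DataFrame([
            {"chrom": "chrF", "start": 5200, "end": 6800},
            {"chrom": "chrF", "start": 6500, "end": 6900},  # overlap region
        ])
        return genome, bounds, seq

    def test_printed_criteria(self, tmp_path):
        genome, bounds, seq = self.make_inputs(tmp_path)
        records = [
            VariantRecord("chrF", 5500, seq[5500:5651], seq[5500]),  # 150bp del
            VariantRecord("chrF", 3000, seq[3000], "A" if seq[3000] != "A" else "C"),
            VariantRecord("chrF", 5600, seq[5600], "A" if seq[5600] != "A" else "C"),
            VariantRecord("chrF", 6950, seq[6950], "A" if seq[6950] != "A" else "C"),
            VariantRecord("chrF", 6600, seq[6600], "A" if seq[6600] != "A" else "C"),
            VariantRecord("chrF", 5601, "AT", "GC"),  # not simple
        ]
        retained, reasons = filter_variants(records, genome, bounds)
        keys = {f"{r.chrom}:{r.position}:{r.ref}>{r.alt}" for r in retained}
        assert keys == {f"chrF:5600:{records[2].ref}>{records[2].alt}"}
        assert "deletion larger" in reasons[
            f"chrF:5500:{records[0].ref}>{records[0].alt}"]
        assert "chromosome ends" in reasons[
            f"chrF:3000:{records[1].ref}>{records[1].alt}"]
        assert "gene body" in reasons[
            f"chrF:6950:{records[3].ref}>{records[3].alt}"]
        assert "multiple genes" in reasons[
            f"chrF:6600:{records[4].ref}>{records[4].alt}"]
        # partition: every input is retained or has exactly one reason
        assert len(retained) + len(reasons) == len(records)

    def test_site_window_criterion(self, tmp_path):
        genome, bounds, seq = self.make_inputs(tmp_path)
        coords = GeneCoords("g", "chrF", 5200, 6800, "+")
        sites = [AnnotatedSite("g", "chrF", 5610, 410, "donor", None)]
        near = VariantRecord("chrF", 5600, seq[5600],
                             "A" if seq[5600] != "A" else "C")
        far = VariantRecord("chrF", 5700, seq[5700],
                            "A" if seq[5700] != "A" else "C")
        retained, reasons = filter_variants([near, far], genome, bounds,
                                            annotated_sites=sites)
        assert len(retained) == 1 and retained[0].position == 5600

    def test_malformed_record_errors(self, tmp_path):
        genome, bounds, _ = self.make_inputs(tmp_path)
        with pytest.raises(DataError, match="malformed"):
            filter_variants([VariantRecord("chrF", 10, "", "A")], genome, bounds)


class TestVCF:
    def test_read_round_trip(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\trs1\tA\tG\t.\t.\t.\n"
            "chr1\t201\t.\tAT\tA\t.\t.\t.\n")
        records = read_vcf(vcf)
        assert records[0] == VariantRecord("chr1", 100, "A", "G", "rs1")
        assert records[1].is_simple_indel
        assert records[1].deletion_length == 1


class TestRankCandidates:
    def make_candidates(self):
        return pd.DataFrame([
            {"snp_id": "snpA", "position": 150, "effect": 0.6, "pvalue": 1e-4},
            {"snp_id": "snpB", "position": 120, "effect": 0.2, "pvalue": 1e-9},
            {"snp_id": "snpC", "position": 180, "effect": 0.1, "pvalue": 1e-3},
        ])

    def test_argmax_effect_and_ratio(self):
        res = rank_candidate_snps(self.make_candidates(), [100])
        assert res.predicted_causal == "snpA" and res.lead == "snpB"
        assert res.p_ratio == pytest.approx(1e-4 / 1e-9)

    def test_lead_is_max_effect_gives_ratio_one(self):
        df = self.make_candidates()
        df.loc[0, "pvalue"] = 1e-12
        res = rank_candidate_snps(df, [100])
        assert res.predicted_causal == "snpA" == res.lead
        assert res.p_ratio == 1.0

    def test_tie_broken_by_distance_then_position(self):
        df = pd.DataFrame([
            {"snp_id": "far", "position": 300, "effect": 0.5, "pvalue": 0.5},
            {"snp_id": "near", "position": 110, "effect": 0.5, "pvalue": 0.9},
        ])
        res = rank_candidate_snps(df, [100])
        assert res.predicted_causal == "near"

    def test_empty_errors(self):
        with pytest.raises(DataError):
            rank_candidate_snps(pd.DataFrame(columns=["snp_id", "position",
                                                      "effect", "pvalue"]),
                                [1])
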