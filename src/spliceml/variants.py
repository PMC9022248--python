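"""Variant-level scoring: per-tissue delta scores and protocol wrappers.

The delta score of a variant at a splice site is the vector of per-tissue
differences in predicted spliced probability between the mutated and the
reference sequence context,

    dScores = [P_alt,t - P_ref,t  for t in (heart, liver, brain, testis)]

summarized as the signed element of largest magnitude,
``dScores[argmax |dScores|]``.  On top of this primitive the module
implements:

* exon-level scoring (mean of the signed site scores of the exon's 5' and
  3' sites), used for minigene-style exon-disruption datasets;
* clinical annotation-window scoring: the maximum across-tissue *decrease*
  in spliced probability at the annotated splice site nearest the variant
  within a +/-50-base window, averaged with the exon's partner site when
  that partner lies within 100 bases;
* variant filtering with per-record exclusion reasons;
* candidate ranking for splicing-QTL loci.

Indels are handled by applying the edit to the reference gene sequence and
re-extracting the window centered on the (shifted) site, so reference and
alternate predictions stay positionally comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .datasets import (AnnotatedSite, GeneCoords, extract_gene_sequence,
                       reverse_complement)
from .errors import DataError
from .junctions import TISSUES
from .model import SpliceNet, predict_site

SPLICED = {t: 3 * i + 1 for i, t in enumerate(TISSUES)}


@dataclass(frozen=True)
class VariantRecord:
    """A substitution or simple insertion/deletion, VCF-style.

    ``position`` is 0-based; ``ref``/``alt`` are plus-strand alleles; a
    simple indel has a single base in either the ref or the alt field.
    """

    chrom: str
    position: int
    ref: str
    alt: str
    variant_id: str = "."

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_simple_indel(self) -> bool:
        return not self.is_substitution and (len(self.ref) == 1 or len(self.alt) == 1)

    @property
    def deletion_length(self) -> int:
        return max(0, len(self.ref) - len(self.alt))


@dataclass
class DeltaScore:
    """Per-tissue reference/alternate probabilities and their differences."""

    site_position: int
    p_ref: dict
    p_alt: dict
    deltas: np.ndarray

    @property
    def signed_max(self) -> float:
        return signed_max(self.deltas)

    @property
    def max_decrease(self) -> float:
        """Largest across-tissue decrease in spliced probability, floored at 0."""
        return float(max(0.0, -self.deltas.min()))


def signed_max(deltas) -> float:
    """The element of largest magnitude, keeping its sign (first on ties)."""
    deltas = np.asarray(deltas, dtype=float)
    return float(deltas[int(np.argmax(np.abs(deltas)))])


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a VCF into records (first ALT allele only)."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            records.append(VariantRecord(rec.chrom, rec.pos - 1, rec.ref,
                                         rec.alts[0], rec.id or "."))
    return records


def _local_allele(allele: str, strand: str) -> str:
    return allele if strand == "+" else reverse_complement(allele)


def apply_variant(gene_seq: str, coords: GeneCoords,
                  variant: VariantRecord) -> tuple[str, int]:
    """Apply the edit on the transcribed strand.

    Returns ``(alt_sequence, shift)`` where positions at or downstream
    (in local orientation) of the edited segment move by ``shift`` bases.
    """
    local = coords.genomic_to_local(variant.position)
    ref_l = _local_allele(variant.ref, coords.strand)
    alt_l = _local_allele(variant.alt, coords.strand)
    if coords.strand == "-":
        # a plus-strand allele starting at `position` ends at the local
        # coordinate of its last base
        local = local - (len(variant.ref) - 1)
    if local < 0 or local + len(ref_l) > len(gene_seq):
        raise DataError(f"variant {variant.chrom}:{variant.position} outside gene")
    if gene_seq[local: local + len(ref_l)] != ref_l:
        raise DataError(
            f"reference mismatch at {variant.chrom}:{variant.position}: "
            f"genome has {gene_seq[local: local + len(ref_l)]!r}, "
            f"variant claims {ref_l!r}")
    alt_seq = gene_seq[:local] + alt_l + gene_seq[local + len(ref_l):]
    return alt_seq, len(alt_l) - len(ref_l)


def _site_window(seq: str, local: int, context: int) -> str:
    lo, hi = local - context, local + context + 1
    pad_left = max(0, -lo)
    pad_right = max(0, hi - len(seq))
    return "N" * pad_left + seq[max(lo, 0): min(hi, len(seq))] + "N" * pad_right


def delta_score_site(ensemble: Sequence[SpliceNet], genome: Fasta,
                     variant: VariantRecord, site_position: int,
                     coords: GeneCoords) -> DeltaScore:
    """Per-tissue delta scores at a splice site.

    ``site_position`` is genomic (intron-terminal base).  The reference and
    alternate inputs are the +/-context windows around the site before and
    after applying the edit; for indels the alternate window is re-anchored
    on the shifted site position.
    """
    context = ensemble[0].config.context
    gene_seq = extract_gene_sequence(genome, coords)
    site_local = coords.genomic_to_local(site_position)
    if not 0 <= site_local < len(gene_seq):
        raise DataError("site outside gene body")
    alt_seq, shift = apply_variant(gene_seq, coords, variant)
    var_local = coords.genomic_to_local(variant.position)
    if coords.strand == "-":
        var_local -= len(variant.ref) - 1
    alt_site_local = site_local + (shift if var_local <= site_local else 0)
    ref_out = predict_site(ensemble, _site_window(gene_seq, site_local, context))
    alt_out = predict_site(ensemble, _site_window(alt_seq, alt_site_local, context))
    p_ref = {t: float(ref_out[SPLICED[t]]) for t in TISSUES}
    p_alt = {t: float(alt_out[SPLICED[t]]) for t in TISSUES}
    deltas = np.array([p_alt[t] - p_ref[t] for t in TISSUES])
    return DeltaScore(site_position, p_ref, p_alt, deltas)


def score_exon_variant(ensemble: Sequence[SpliceNet], genome: Fasta,
                       variant: VariantRecord,
                       exon_sites: tuple[int, int],
                       coords: GeneCoords) -> float:
    """Mean of the signed site scores for the exon's two splice sites."""
    if exon_sites[0] is None or exon_sites[1] is None:
        raise DataError("exon must have both splice sites defined")
    scores = [delta_score_site(ensemble, genome, variant, p, coords).signed_max
              for p in exon_sites]
    return float(np.mean(scores))


def score_variant_near_annotation(ensemble: Sequence[SpliceNet], genome: Fasta,
                                  variant: VariantRecord,
                                  sites: Sequence[AnnotatedSite],
                                  coords: GeneCoords,
                                  window: int = 50,
                                  pair_window: int = 100) -> float | None:
    """Maximum decrease in spliced probability at the nearest annotated site.

    Returns None when no annotated splice site lies within ``window`` bases
    of the variant.  When the exon's partner site lies within
    ``pair_window`` bases of the scored site, the mean decrease across both
    sites is returned.
    """
    in_window = [s for s in sites if abs(s.position - variant.position) <= window]
    if not in_window:
        return None
    nearest = min(in_window,
                  key=lambda s: (abs(s.position - variant.position), s.position))
    dec = delta_score_site(ensemble, genome, variant, nearest.position,
                           coords).max_decrease
    if nearest.partner_local is not None:
        partner_gpos = coords.local_to_genomic(nearest.partner_local)
        if abs(partner_gpos - nearest.position) <= pair_window:
            dec2 = delta_score_site(ensemble, genome, variant, partner_gpos,
                                    coords).max_decrease
            dec = float((dec + dec2) / 2.0)
    return float(dec)


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def filter_variants(records: Sequence[VariantRecord], genome: Fasta,
                    gene_bounds: pd.DataFrame,
                    end_margin: int = 5000, max_deletion: int = 100,
                    annotated_sites: Sequence[AnnotatedSite] | None = None,
                    site_window: int = 15,
                    ) -> tuple[list[VariantRecord], dict[str, str]]:
    """Apply the clinical-scoring eligibility criteria.

    ``gene_bounds`` needs columns chrom/start/end (0-based half-open).
    Returns the retained records and a map variant key -> exclusion reason.
    Criteria: substitution or simple indel; inside exactly one gene body;
    at least ``end_margin`` bases from the contig ends; deletions no longer
    than ``max_deletion``; and, when ``annotated_sites`` is given, within
    ``site_window`` bases of an annotated splice site.
    """
    retained, reasons = [], {}
    site_positions = (np.array([s.position for s in annotated_sites])
                      if annotated_sites else None)
    for rec in records:
        key = f"{rec.chrom}:{rec.position}:{rec.ref}>{rec.alt}"
        if not rec.ref or not rec.alt or \
                any(b not in "ACGTN" for b in (rec.ref + rec.alt).upper()):
            raise DataError(f"malformed record {key}")
        if rec.chrom not in genome:
            raise DataError(f"unknown contig in record {key}")
        if not (rec.is_substitution or rec.is_simple_indel):
            reasons[key] = "not a substitution or simple indel"
            continue
        contig_len = len(genome[rec.chrom])
        if rec.position < end_margin or rec.position >= contig_len - end_margin:
            reasons[key] = "within 5000 bases of the chromosome ends"
            continue
        if rec.deletion_length > max_deletion:
            reasons[key] = f"deletion larger than {max_deletion} bp"
            continue
        hits = gene_bounds[(gene_bounds["chrom"] == rec.chrom)
                           & (gene_bounds["start"] <= rec.position)
                           & (gene_bounds["end"] > rec.position)]
        if len(hits) == 0:
            reasons[key] = "not contained in a gene body"
            continue
        if len(hits) > 1:
            reasons[key] = "contained in multiple genes"
            continue
        if site_positions is not None and (
                np.abs(site_positions - rec.position).min() > site_window):
            reasons[key] = f"no annotated splice site within {site_window} bp"
            continue
        retained.append(rec)
    return retained, reasons


# ---------------------------------------------------------------------------
# sQTL candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedCandidates:
    predicted_causal: str
    lead: str
    p_ratio: float


def rank_candidate_snps(candidates: pd.DataFrame,
                        site_positions: Sequence[int]) -> RankedCandidates:
    """Pick the SNP with the largest predicted effect and compare p-values.

    ``candidates`` needs columns ``snp_id``, ``position``, ``effect``
    (|signed-max delta|, already averaged over both sites when the SNP lies
    within range of both) and ``pvalue``.  The lead SNP is the one with the
    smallest association p-value; the returned ratio is
    p(predicted causal) / p(lead).  Effect ties are broken by distance to
    the nearest splice site, then by coordinate.
    """
    if len(candidates) == 0:
        raise DataError("empty candidate set")
    site_positions = np.asarray(list(site_positions))
    df = candidates.copy()
    if len(site_positions):
        df["_dist"] = [int(np.abs(site_positions - p).min()) for p in df["position"]]
    else:
        df["_dist"] = 0
    df = df.sort_values(["effect", "_dist", "position"],
                        ascending=[False, True, True], kind="stable")
    best = df.iloc[0]
    lead = candidates.loc[candidates["pvalue"].idxmin()]
    return RankedCandidates(str(best["snp_id"]), str(lead["snp_id"]),
                            float(best["pvalue"] / lead["pvalue"]))
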