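"""Turn genome + annotation + site table into one-hot training blocks.

Genes are processed on their transcribed strand: the sequence between the
gene's annotated bounds is extracted (reverse-complemented for minus-strand
genes), padded with ``flank`` unknown bases (N) on both sides, and tiled
into overlapping blocks of ``block = step + 2*flank`` bases advancing by
``step``.  The middle ``step`` positions of each block are the positions the
model is trained on, so every gene-body position is the middle of exactly
one block.  The full-scale geometry is 15,000-base blocks with a 5,000-base
step and flank; the miniature geometry used throughout the test fixtures is
1,500/1,000/250.

Per-position labels are 12-dimensional: for each tissue (heart, liver,
brain, testis in that order) a spliced/unspliced probability pair and a
usage value.  Unspliced positions are ``[1, 0, 0]``, spliced sites with
usage ``u`` are ``[0, 1, u]`` and padding / masked positions are
``[0, 0, 0]`` -- the all-zero pair marks the position as excluded from both
the probability and the usage loss.

Internal coordinates are 0-based half-open; GFF3's 1-based closed intervals
are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import DataError
from .junctions import TISSUES

N_TISSUES = len(TISSUES)
LABEL_DIM = 3 * N_TISSUES

_ONE_HOT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate("ACGT"):
    _ONE_HOT[ord(_b)] = _ONE_HOT[ord(_b.lower())] = np.eye(4, dtype=np.float32)[_i]
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGTUNacgtun":
    _VALID[ord(_b)] = True
_ONE_HOT[ord("U")] = _ONE_HOT[ord("u")] = _ONE_HOT[ord("T")]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode A,C,G,T/U as unit vectors and N as the zero vector.

    Any other character raises :class:`DataError` naming the offender.
    """
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    bad = ~_VALID[codes]
    if bad.any():
        idx = int(np.argmax(bad))
        raise DataError(f"invalid base {sequence[idx]!r} at position {idx}")
    return _ONE_HOT[codes].copy() if len(codes) else np.zeros((0, 4), np.float32)


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; zero rows decode to N."""
    out = np.full(len(matrix), "N")
    hot = matrix.sum(axis=1) > 0
    out[hot] = np.array(list("ACGT"))[matrix[hot].argmax(axis=1)]
    return "".join(out)


@dataclass(frozen=True)
class BlockGeometry:
    """Tiling geometry; ``block = step + 2*flank``."""

    flank: int = 5000
    step: int = 5000

    @property
    def block(self) -> int:
        return self.step + 2 * self.flank


FULL_GEOMETRY = BlockGeometry(flank=5000, step=5000)
MINI_GEOMETRY = BlockGeometry(flank=250, step=1000)


@dataclass(frozen=True)
class GeneCoords:
    """Invertible map between gene-local (transcribed) and genomic coords."""

    gene_id: str
    chrom: str
    start: int  # genomic 0-based half-open
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def local_to_genomic(self, local: int) -> int:
        return self.start + local if self.strand == "+" else self.end - 1 - local

    def genomic_to_local(self, genomic: int) -> int:
        return genomic - self.start if self.strand == "+" else self.end - 1 - genomic


@dataclass
class EncodedBlock:
    """One tiled training block: one-hot sequence + per-position labels.

    ``x`` has shape (block, 4); ``y`` (step, 12) covers the block's middle
    ``step`` positions, which map to gene-local positions
    ``local_start .. local_start + step``.
    """

    gene_id: str
    block_index: int
    x: np.ndarray
    y: np.ndarray
    local_start: int


def extract_gene_sequence(genome: Fasta, coords: GeneCoords) -> str:
    """Gene-body sequence on the transcribed strand, uppercase."""
    if coords.chrom not in genome:
        raise DataError(f"contig {coords.chrom} absent from FASTA")
    contig = genome[coords.chrom]
    if coords.end > len(contig) or coords.start < 0:
        raise DataError(f"gene {coords.gene_id} outside contig bounds")
    seq = str(contig[coords.start:coords.end]).upper()
    return reverse_complement(seq) if coords.strand == "-" else seq


def pad_and_tile(sequence: str, geometry: BlockGeometry,
                 labels: np.ndarray | None = None,
                 gene_id: str = "", ) -> list[EncodedBlock]:
    """Pad with flank Ns and tile into overlapping encoded blocks.

    ``ceil(len(sequence)/step)`` blocks are produced; the last is
    right-padded with Ns.  When ``labels`` (len(sequence) x 12) is given,
    each block carries the labels of its middle ``step`` positions,
    zero-padded (masked) past the end of the gene.
    """
    L = len(sequence)
    if L == 0:
        raise DataError("cannot tile an empty sequence")
    g = geometry
    n_blocks = -(-L // g.step)
    padded = "N" * g.flank + sequence + "N" * (g.flank + n_blocks * g.step - L)
    x_all = one_hot_encode(padded)
    if labels is not None:
        if labels.shape != (L, LABEL_DIM):
            raise DataError(f"labels shape {labels.shape} != ({L}, {LABEL_DIM})")
        y_all = np.zeros((n_blocks * g.step, LABEL_DIM), dtype=np.float32)
        y_all[:L] = labels
    blocks = []
    for i in range(n_blocks):
        x = x_all[i * g.step: i * g.step + g.block]
        y = (y_all[i * g.step: (i + 1) * g.step] if labels is not None
             else np.zeros((g.step, LABEL_DIM), np.float32))
        blocks.append(EncodedBlock(gene_id, i, x, y, i * g.step))
    return blocks


def build_labels(sites: pd.DataFrame, coords: GeneCoords,
                 tissues: Sequence[str] = TISSUES) -> np.ndarray:
    """Per-position label matrix (gene length x 12) from a site table.

    ``sites`` holds this gene's rows of the quantified site table (columns
    ``position`` genomic, plus per-tissue ``spliced_*``, ``usage_*`` and
    ``mask_*``).  Positions not listed are unspliced gene-body positions.
    """
    L = coords.length
    labels = np.zeros((L, LABEL_DIM), dtype=np.float32)
    labels[:, 0::3] = 1.0  # default: unspliced [1,0,0] for every tissue
    for site in sites.itertuples():
        local = coords.genomic_to_local(int(site.position))
        if not 0 <= local < L:
            raise DataError(
                f"site {site.chrom}:{site.position} outside gene {coords.gene_id}")
        for t_i, t in enumerate(tissues):
            spliced = bool(getattr(site, f"spliced_{t}"))
            mask = bool(getattr(site, f"mask_{t}"))
            base = 3 * t_i
            if spliced and mask:
                labels[local, base:base + 3] = (0.0, 1.0,
                                                float(getattr(site, f"usage_{t}")))
            elif spliced:  # spliced but unquantifiable: exclude from all losses
                labels[local, base:base + 3] = 0.0
            # else: keep the unspliced default
    return labels


def split_train_test(genes: pd.DataFrame, test_chroms: Iterable[str],
                     orthologs: pd.DataFrame | None = None,
                     known_chroms: Iterable[str] | None = None,
                     reference_species: str = "ref",
                     ) -> tuple[list[str], list[str], list[str]]:
    """Chromosome-held-out partition with ortholog exclusion.

    Reference-species genes on ``test_chroms`` form the test set; other
    reference genes flagged in ``orthologs`` (columns ``gene_id``,
    ``test_gene_id``, ``confidence`` -- any confidence level excludes) or
    non-reference genes orthologous to a test gene are dropped; the rest
    train.  Returns ``(train_ids, test_ids, dropped_ids)``.
    """
    test_chroms = set(test_chroms)
    test_ids = set()
    species = genes["species"] if "species" in genes.columns else pd.Series(
        reference_species, index=genes.index)
    if known_chroms is not None:
        known = set(known_chroms) | test_chroms
        unknown = genes.loc[~genes["chrom"].isin(known), "gene_id"]
        if len(unknown):
            warnings.warn(f"dropping {len(unknown)} genes on unknown chromosomes")
    else:
        known = None
    for g, sp in zip(genes.itertuples(), species):
        if sp == reference_species and g.chrom in test_chroms:
            test_ids.add(g.gene_id)
    flagged = set()
    if orthologs is not None and len(orthologs):
        hits = orthologs[orthologs["test_gene_id"].isin(test_ids)]
        flagged = set(hits["gene_id"])
    train, dropped = [], []
    for g in genes.itertuples():
        if g.gene_id in test_ids:
            continue
        if known is not None and g.chrom not in known:
            dropped.append(g.gene_id)
        elif g.gene_id in flagged:
            dropped.append(g.gene_id)
        else:
            train.append(g.gene_id)
    return train, sorted(test_ids), dropped


# ---------------------------------------------------------------------------
# Annotation access
# ---------------------------------------------------------------------------

def load_annotation(gff_path: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(str(gff_path), ":memory:",
                              merge_strategy="create_unique", keep_order=True)


def gene_table(db: gffutils.FeatureDB) -> pd.DataFrame:
    rows = [{"gene_id": g.id, "chrom": g.seqid, "start": g.start - 1,
             "end": g.end, "strand": g.strand}
            for g in db.features_of_type("gene")]
    return pd.DataFrame(rows)


def gene_coords(db: gffutils.FeatureDB, gene_id: str) -> GeneCoords:
    try:
        g = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise DataError(f"gene {gene_id} absent from annotation") from exc
    return GeneCoords(gene_id, g.seqid, g.start - 1, g.end, g.strand)


def canonical_transcript(db: gffutils.FeatureDB, gene_id: str):
    """The Ensembl_canonical-tagged transcript, else the longest."""
    transcripts = list(db.children(gene_id, featuretype=("mRNA", "transcript")))
    if not transcripts:
        raise DataError(f"gene {gene_id} has no transcripts")
    for t in transcripts:
        if "Ensembl_canonical" in t.attributes.get("tag", []):
            return t
    return max(transcripts, key=lambda t: t.end - t.start)


@dataclass(frozen=True)
class AnnotatedSite:
    """An annotated splice site with its exon partner, in local coords.

    ``partner_local`` is the local position of the other splice site of the
    exon this site delimits (None at transcript termini).
    """

    gene_id: str
    chrom: str
    position: int       # genomic, intron-terminal base
    local: int          # gene-local
    side: str           # donor | acceptor
    partner_local: int | None


def annotated_splice_sites(db: gffutils.FeatureDB, gene_id: str,
                           ) -> tuple[list[AnnotatedSite], GeneCoords]:
    """Splice sites of the canonical transcript, in transcript order.

    The start of the first exon and the end of the last exon are not splice
    sites and are excluded.  Donor = first intronic base after an exon;
    acceptor = last intronic base before an exon.
    """
    coords = gene_coords(db, gene_id)
    t = canonical_transcript(db, gene_id)
    exons = sorted(db.children(t.id, featuretype="exon"),
                   key=lambda e: e.start)
    bounds = [(e.start - 1, e.end) for e in exons]  # genomic half-open
    local = sorted(tuple(sorted((coords.genomic_to_local(s),
                                 coords.genomic_to_local(e - 1))))
                   for s, e in bounds)
    sites: list[AnnotatedSite] = []
    for i in range(len(local) - 1):
        exon_end = local[i][1]          # last exonic base of exon i
        next_start = local[i + 1][0]    # first exonic base of exon i+1
        donor = exon_end + 1            # first intronic base
        acceptor = next_start - 1       # last intronic base
        # donor's exon partner: the acceptor upstream of exon i (if any)
        donor_partner = local[i][0] - 1 if i > 0 else None
        acceptor_partner = local[i + 1][1] + 1 if i + 1 < len(local) - 1 else None
        sites.append(AnnotatedSite(gene_id, coords.chrom,
                                   coords.local_to_genomic(donor), donor,
                                   "donor", donor_partner))
        sites.append(AnnotatedSite(gene_id, coords.chrom,
                                   coords.local_to_genomic(acceptor), acceptor,
                                   "acceptor", acceptor_partner))
    return sites, coords


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_gene_blocks(genome: Fasta, coords: GeneCoords,
                      sites: pd.DataFrame,
                      geometry: BlockGeometry) -> list[EncodedBlock]:
    seq = extract_gene_sequence(genome, coords)
    labels = build_labels(sites, coords)
    return pad_and_tile(seq, geometry, labels, coords.gene_id)


def build_dataset(genome: Fasta, db: gffutils.FeatureDB,
                  site_table: pd.DataFrame, gene_ids: Sequence[str],
                  geometry: BlockGeometry) -> list[EncodedBlock]:
    """Encoded blocks for the given genes, gene order preserved."""
    by_gene = dict(tuple(site_table.groupby("gene_id"))) if "gene_id" in \
        site_table.columns else None
    blocks: list[EncodedBlock] = []
    for gid in gene_ids:
        coords = gene_coords(db, gid)
        if by_gene is not None:
            sites = by_gene.get(gid, site_table.iloc[0:0])
        else:
            sites = site_table[
                (site_table["chrom"] == coords.chrom)
                & (site_table["position"] >= coords.start)
                & (site_table["position"] < coords.end)]
        blocks.extend(build_gene_blocks(genome, coords, sites, geometry))
    return blocks
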