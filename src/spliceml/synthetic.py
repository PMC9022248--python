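"""Synthetic splice-grammar genomes with known per-tissue usage truth.

The generator emits a miniature genome (FASTA), gene annotation (GFF3) and a
truth table of planted splice sites whose usage is a deterministic function
of local motif strength -- the statistical structure a sequence-to-splicing
model has to learn:

* every planted donor starts its intron with ``GT`` and every acceptor ends
  it with ``AG``;
* extended donor context follows the mammalian U1 consensus (CAG|GTAAGT),
  with per-site partial matches drawn at random;
* acceptors carry a polypyrimidine tract of variable length and pyrimidine
  content upstream of the ``AG``;
* a logistic link maps motif strength to baseline usage, so strong sites
  approach constitutive usage and weak sites are skipped most of the time;
* tissue-specific modulation: an intronic enhancer hexamer raises usage in
  brain and a silencer hexamer lowers it in testis (logit-additive), so the
  four tissue tracks differ only where a modulator is planted.

Junction read evidence is simulated per sample by binomial sampling around
the true usage, with the non-supporting reads split between non-split
(beta1), direct contradicting (beta2-simple) and partner-mediated cryptic
counter-evidence in a configurable mix.

Background sequence is uniform random, so decoy GT/AG dinucleotides occur at
the expected ~1/16 rate and the classifier must rely on extended context.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .junctions import TISSUES, format_partners

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# Donor extended motif: offsets relative to the first intronic base (the G
# of GT), consensus base and weight. The GT core itself is always planted.
DONOR_MOTIF = {-3: ("C", 0.5), -2: ("A", 1.0), -1: ("G", 1.5),
               2: ("A", 1.5), 3: ("A", 1.0), 4: ("G", 1.0), 5: ("T", 0.5)}
# Acceptor non-tract motif: offsets relative to the last intronic base (the
# G of AG). -2 is the Y of the YAG box; +1 is the first exonic base.
ACCEPTOR_MOTIF = {-2: ("Y", 1.0), 1: ("G", 0.5)}
ACCEPTOR_TRACT_WEIGHT = 6.0  # full-strength tract contribution
ACCEPTOR_TRACT_REF_LEN = 16  # tract length at which the weight saturates


@dataclass
class GrammarSpec:
    """Parameters of the planted splice grammar."""

    n_exons: tuple[int, int] = (3, 6)          # inclusive range per gene
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (250, 450)
    modulator_reach: int = 230                 # max distance motif <-> either site
    spacer_len: tuple[int, int] = (300, 800)   # intergenic background
    tract_len: tuple[int, int] = (8, 16)       # polypyrimidine tract
    tract_pyr: tuple[float, float] = (0.6, 0.95)
    motif_match_prob: tuple[float, float] = (0.5, 1.0)  # per-site match rate
    usage_slope: float = 1.0                   # logistic link on motif score
    donor_midpoint: float = 6.3                # motif score of half-maximal usage
    acceptor_midpoint: float = 5.0
    brain_enhancer: str = "TGCATG"
    testis_silencer: str = "CCAGCA"
    modulator_prob: float = 0.35               # per site, per modulator
    modulator_effect: float = 1.5              # logit shift in the target tissue
    n_chroms: int = 10
    decoys_per_gene: int = 2                   # unspliced positions with evidence
    tissue_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intron_len[0] < 25 + self.tract_len[1] + max(len(self.brain_enhancer),
                                                             len(self.testis_silencer)):
            raise DataError("intron length range too short for the planted motifs")
        if not self.tissue_effects:
            self.tissue_effects = {
                "brain": (self.brain_enhancer, +self.modulator_effect),
                "testis": (self.testis_silencer, -self.modulator_effect),
            }


def _logistic(x: float | np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n)


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _stamp(arr: np.ndarray, pos: int, motif: str) -> None:
    for i, b in enumerate(motif):
        arr[pos + i] = _BASE_IDX[b]


def _plant_motif(arr: np.ndarray, rng: np.random.Generator, anchor: int,
                 motif: dict, match_prob: float) -> float:
    """Write a partial consensus match around ``anchor``; return its score."""
    score = 0.0
    for off, (base, w) in motif.items():
        if base == "Y":
            choice = "CT"[rng.integers(2)]
        else:
            choice = base
        if rng.random() < match_prob:
            arr[anchor + off] = _BASE_IDX[choice]
            if base == "Y" or arr[anchor + off] == _BASE_IDX[base]:
                score += w
        else:  # leave the random background base; score it if it matches anyway
            cur = BASES[arr[anchor + off]]
            if (base == "Y" and cur in "CT") or cur == base:
                score += w
    return score


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int   # genomic, 0-based half-open
    end: int
    strand: str
    exon_bounds: list[tuple[int, int]]  # local (transcribed) coordinates


def _build_gene(rng: np.random.Generator, grammar: GrammarSpec,
                gene_id: str) -> tuple[np.ndarray, list[dict], list[tuple[int, int]]]:
    """Return (local base indices, site records in local coords, exon bounds)."""
    n_ex = int(rng.integers(grammar.n_exons[0], grammar.n_exons[1] + 1))
    exon_lens = rng.integers(grammar.exon_len[0], grammar.exon_len[1] + 1, n_ex)
    intron_lens = rng.integers(grammar.intron_len[0], grammar.intron_len[1] + 1,
                               n_ex - 1)
    length = int(exon_lens.sum() + intron_lens.sum())
    arr = _random_seq(rng, length)

    sites: list[dict] = []
    exon_bounds: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_ex):
        exon_bounds.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i == n_ex - 1:
            break
        intron_start, intron_len = pos, int(intron_lens[i])
        intron_end = pos + intron_len  # exclusive; last intronic base at end-1

        # --- donor: first intronic base; plant GT core + extended motif
        donor = intron_start
        _stamp(arr, donor, "GT")
        match_prob = rng.uniform(*grammar.motif_match_prob)
        d_score = 2.0 + _plant_motif(arr, rng, donor, DONOR_MOTIF, match_prob)

        # --- acceptor: last intronic base; plant AG + YAG box + tract
        acceptor = intron_end - 1
        _stamp(arr, acceptor - 1, "AG")
        match_prob = rng.uniform(*grammar.motif_match_prob)
        a_score = 2.0 + _plant_motif(arr, rng, acceptor, ACCEPTOR_MOTIF, match_prob)
        tract_len = int(rng.integers(grammar.tract_len[0], grammar.tract_len[1] + 1))
        pyr = rng.uniform(*grammar.tract_pyr)
        n_pyr = 0
        for k in range(tract_len):
            p = acceptor - 4 - k
            if rng.random() < pyr:
                arr[p] = _BASE_IDX["CT"[rng.integers(2)]]
            if BASES[arr[p]] in "CT":
                n_pyr += 1
        a_score += ACCEPTOR_TRACT_WEIGHT * n_pyr / ACCEPTOR_TRACT_REF_LEN

        # --- intron-level tissue modulators, planted mid-intron within the
        # modulator reach of both sites (so a local model can see them) and
        # clear of the tract/core motif windows
        effects = dict.fromkeys(TISSUES, 0.0)
        planted = dict.fromkeys(grammar.tissue_effects, False)
        lo = max(donor + 10, acceptor - grammar.modulator_reach)
        for tissue, (motif, eff) in grammar.tissue_effects.items():
            hi = min(donor + grammar.modulator_reach - len(motif),
                     acceptor - 4 - grammar.tract_len[1] - len(motif) - 1)
            if rng.random() < grammar.modulator_prob and hi > lo:
                _stamp(arr, int(rng.integers(lo, hi)), motif)
                effects[tissue] = eff
                planted[tissue] = True

        for side_pos, side, score, mid in (
                (donor, "donor", d_score, grammar.donor_midpoint),
                (acceptor, "acceptor", a_score, grammar.acceptor_midpoint)):
            base_logit = grammar.usage_slope * (score - mid)
            usages = {t: float(_logistic(base_logit + effects[t])) for t in TISSUES}
            sites.append({
                "local_pos": side_pos, "side": side, "score": score,
                "is_decoy": False,
                **{f"usage_{t}": usages[t] for t in TISSUES},
                **{f"modulated_{t}": planted.get(t, False) for t in TISSUES},
            })
        pos = intron_end

    # decoy positions: mid-exon bases that are not splice sites (usage 0)
    for _ in range(grammar.decoys_per_gene):
        ex = exon_bounds[int(rng.integers(len(exon_bounds)))]
        if ex[1] - ex[0] < 40:
            continue
        p = int(rng.integers(ex[0] + 10, ex[1] - 10))
        sites.append({
            "local_pos": p, "side": "donor" if rng.random() < 0.5 else "acceptor",
            "score": 0.0, "is_decoy": True,
            **{f"usage_{t}": 0.0 for t in TISSUES},
            **{f"modulated_{t}": False for t in TISSUES},
        })
    return arr, sites, exon_bounds


def generate_genome(n_genes: int, grammar: GrammarSpec, seed: int,
                    out_dir: str | Path | None = None,
                    ) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate a genome with planted splice grammar.

    Returns ``(chromosomes, genes, truth)`` where ``chromosomes`` maps
    chromosome name to sequence, ``genes`` is a gene table (gene_id, chrom,
    start, end, strand, exon coordinates serialized as a string) and
    ``truth`` lists every planted site with its genomic coordinate, side and
    per-tissue true usage.  Deterministic given ``seed``.  When ``out_dir``
    is given, writes ``genome.fa``, ``genes.gff3`` and ``truth_sites.tsv``.
    """
    rng = np.random.default_rng(seed)
    chrom_parts: dict[str, list[np.ndarray]] = {
        f"chr{i + 1}": [] for i in range(grammar.n_chroms)}
    chrom_pos = dict.fromkeys(chrom_parts, 0)
    gene_rows, truth_rows = [], []

    for g in range(n_genes):
        gene_id = f"G{g + 1:04d}"
        chrom = f"chr{g % grammar.n_chroms + 1}"
        arr, sites, exon_bounds = _build_gene(rng, grammar, gene_id)
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = _random_seq(rng, int(rng.integers(*grammar.spacer_len)))
        start = chrom_pos[chrom] + len(spacer)
        end = start + len(arr)

        local_seq = "".join(BASES[arr])
        genomic_seq = local_seq if strand == "+" else reverse_complement(local_seq)
        chrom_parts[chrom].append(spacer)
        chrom_parts[chrom].append(
            np.fromiter((_BASE_IDX[b] for b in genomic_seq), dtype=np.int64))
        chrom_pos[chrom] = end

        def to_genomic(local: int) -> int:
            return start + local if strand == "+" else end - 1 - local

        for s in sites:
            truth_rows.append({
                "chrom": chrom, "position": to_genomic(s["local_pos"]),
                "strand": strand, "side": s["side"], "gene_id": gene_id,
                "score": s["score"], "is_decoy": s["is_decoy"],
                **{k: s[k] for k in s if k.startswith(("usage_", "modulated_"))},
            })
        gene_rows.append({
            "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
            "strand": strand,
            "exons_local": ";".join(f"{a}-{b}" for a, b in exon_bounds),
        })

    chromosomes = {c: "".join(BASES[np.concatenate(parts)]) if parts else ""
                   for c, parts in chrom_parts.items()}
    genes = pd.DataFrame(gene_rows)
    truth = pd.DataFrame(truth_rows).sort_values(
        ["chrom", "position"]).reset_index(drop=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(chromosomes, out / "genome.fa")
        write_gff3(genes, out / "genes.gff3")
        truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    return chromosomes, genes, truth


def write_fasta(chromosomes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, 60) + "\n")


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene/mRNA/exon records; mRNAs carry the Ensembl_canonical tag."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            start1, end1 = g.start + 1, g.end  # 1-based closed
            fh.write(f"{g.chrom}\tspliceml\tgene\t{start1}\t{end1}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tspliceml\tmRNA\t{start1}\t{end1}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={g.gene_id};"
                     f"tag=Ensembl_canonical\n")
            bounds = [tuple(map(int, b.split("-"))) for b in g.exons_local.split(";")]
            for i, (a, b) in enumerate(bounds):
                if g.strand == "+":
                    es, ee = g.start + a + 1, g.start + b
                else:
                    es, ee = g.end - b + 1, g.end - a
                fh.write(f"{g.chrom}\tspliceml\texon\t{es}\t{ee}\t.\t{g.strand}"
                         f"\t.\tID={tid}.e{i + 1};Parent={tid}\n")


def simulate_junction_counts(truth: pd.DataFrame, depth: int, n_samples: int,
                             seed: int,
                             counter_mix: tuple[float, float, float] = (0.8, 0.15, 0.05),
                             tissues=TISSUES,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample junction evidence tables from true usage.

    For each site, tissue and sample: ``alpha ~ Binomial(depth, usage)`` and
    the remaining ``depth - alpha`` reads are split multinomially between
    beta1, beta2-simple and a single cryptic partner according to
    ``counter_mix``.  The partner's own split support is reported as the
    site's alpha so that, pooled across samples, the cryptic term
    contributes exactly the total cryptic read count to the SSE denominator.

    Returns ``(evidence, samples)`` in the dialects consumed by
    :mod:`spliceml.junctions`.
    """
    if depth < 1:
        raise DataError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    mix = np.asarray(counter_mix, dtype=float)
    mix = mix / mix.sum()
    ev_rows, sample_rows = [], []
    sample_ids = {t: [f"{t}_s{i + 1}" for i in range(n_samples)] for t in tissues}
    for t in tissues:
        sample_rows += [{"sample_id": s, "tissue": t} for s in sample_ids[t]]

    for site in truth.itertuples():
        for t in tissues:
            u = getattr(site, f"usage_{t}")
            alphas = rng.binomial(depth, u, n_samples)
            for k in range(n_samples):
                a = int(alphas[k])
                rest = depth - a
                b1, b2s, cryptic = (int(x) for x in rng.multinomial(rest, mix))
                partners = [(a, cryptic)] if cryptic and a else []
                if cryptic and not a:
                    b1 += cryptic  # no junction support: fold into non-split
                ev_rows.append({
                    "chrom": site.chrom, "position": site.position,
                    "strand": site.strand, "side": site.side,
                    "sample_id": sample_ids[t][k],
                    "alpha": a, "beta1": b1, "beta2_simple": b2s,
                    "partner_alpha_beta2c": format_partners(partners),
                })
    evidence = pd.DataFrame(ev_rows)
    samples = pd.DataFrame(sample_rows)
    return evidence, samples
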