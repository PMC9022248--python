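"""End-to-end orchestration of the desk-scale study.

The pipeline mirrors the full-scale workflow at miniature geometry:

1. simulate a synthetic splice-grammar genome and junction read evidence;
2. quantify per-tissue splice-site usage from the evidence;
3. build one-hot training blocks with a chromosome-held-out split;
4. run the three-phase training protocol for the probability and usage
   models;
5. evaluate splice-site prediction (top-1 / top-0.5 / AUPRC), usage
   recovery and tissue specificity on the held-out genes;
6. saturation-mutagenesis sanity checks on the held-out sites.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawns, so a run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import datasets, evaluation, junctions, mutagenesis, synthetic
from .errors import DataError, InsufficientDataError
from .junctions import TISSUES
from .model import MINI_CONFIG, ModelConfig, SpliceNet
from .model import predict_sequence
from .training import MINI_SCHEDULE, ModelBundle, TrainingSchedule, train_protocol

TEST_CHROMS = ("chr1", "chr3")


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31))


@dataclass
class PipelineData:
    genome_path: Path
    gff_path: Path
    genes: pd.DataFrame
    truth: pd.DataFrame
    site_table: pd.DataFrame
    train_ids: list
    test_ids: list


def simulate_and_quantify(out_dir: Path, seed: int, n_genes: int = 250,
                          depth: int = 100, n_samples: int = 8,
                          grammar: synthetic.GrammarSpec | None = None,
                          test_chroms=TEST_CHROMS) -> PipelineData:
    """Steps 1-3 of the pipeline (through the train/test split)."""
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    grammar = grammar or synthetic.GrammarSpec()
    _, genes, truth = synthetic.generate_genome(
        n_genes, grammar, _child_seed(rng), out_dir=out_dir)
    evidence, samples = synthetic.simulate_junction_counts(
        truth, depth=depth, n_samples=n_samples, seed=_child_seed(rng))
    evidence.to_csv(out_dir / "evidence.tsv", sep="\t", index=False)
    samples.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    site_table = junctions.quantify_sites(
        evidence, dict(zip(samples["sample_id"], samples["tissue"])))
    # attach gene ids for label building
    pos_to_gene = {(r.chrom, r.position): r.gene_id for r in truth.itertuples()}
    site_table["gene_id"] = [
        pos_to_gene.get((r.chrom, r.position)) for r in site_table.itertuples()]
    junctions.write_site_table(site_table, out_dir / "site_table.tsv")
    train_ids, test_ids, _ = datasets.split_train_test(genes, test_chroms)
    return PipelineData(out_dir / "genome.fa", out_dir / "genes.gff3",
                        genes, truth, site_table, train_ids, test_ids)


def prepare_blocks(data: PipelineData,
                   geometry: datasets.BlockGeometry = datasets.MINI_GEOMETRY):
    genome = Fasta(str(data.genome_path))
    db = datasets.load_annotation(data.gff_path)
    blocks = datasets.build_dataset(genome, db, data.site_table,
                                    data.train_ids, geometry)
    return blocks, genome, db


def train_models(blocks, seed: int, config: ModelConfig = MINI_CONFIG,
                 schedule: TrainingSchedule = MINI_SCHEDULE) -> ModelBundle:
    return train_protocol(blocks, config, schedule, seed=seed)


# ---------------------------------------------------------------------------
# Evaluation on held-out genes
# ---------------------------------------------------------------------------

def _gene_tracks(bundle: ModelBundle, genome: Fasta, db, gene_ids,
                 label_type: str) -> dict[str, dict[str, np.ndarray]]:
    """Per-gene, per-tissue predicted tracks (P_spliced or usage)."""
    col = {"probability": 1, "usage": 2}[label_type]
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for gid in gene_ids:
        coords = datasets.gene_coords(db, gid)
        seq = datasets.extract_gene_sequence(genome, coords)
        tracks[gid] = {}
        for t_i, tissue in enumerate(TISSUES):
            track = predict_sequence(bundle.ensemble(tissue, label_type), seq)
            tracks[gid][tissue] = track[:, 3 * t_i + col]
    return tracks


def evaluate_probability(bundle: ModelBundle, genome: Fasta, db,
                         data: PipelineData) -> dict:
    """Top-1, top-0.5 and AUPRC per tissue on held-out genes.

    Labels are the pipeline's own spliced calls from the quantified site
    table; per-gene accuracies are averaged over genes, AUPRC is pooled
    over all held-out positions per tissue.
    """
    tracks = _gene_tracks(bundle, genome, db, data.test_ids, "probability")
    site_by_gene = dict(tuple(data.site_table.groupby("gene_id")))
    out: dict = {"per_tissue": {}}
    for tissue in TISSUES:
        gene_scores, gene_labels = {}, {}
        pooled_s, pooled_y = [], []
        for gid in data.test_ids:
            coords = datasets.gene_coords(db, gid)
            labels = np.zeros(coords.length, dtype=int)
            valid = np.ones(coords.length, dtype=bool)
            sites = site_by_gene.get(gid)
            if sites is not None:
                for s in sites.itertuples():
                    local = coords.genomic_to_local(int(s.position))
                    if getattr(s, f"spliced_{tissue}"):
                        if getattr(s, f"mask_{tissue}"):
                            labels[local] = 1
                        else:
                            valid[local] = False  # excluded from evaluation
            scores = tracks[gid][tissue][valid]
            labels = labels[valid]
            if labels.sum():
                gene_scores[gid], gene_labels[gid] = scores, labels
            pooled_s.append(scores)
            pooled_y.append(labels)
        pooled_s = np.concatenate(pooled_s)
        pooled_y = np.concatenate(pooled_y)
        out["per_tissue"][tissue] = {
            "top1": evaluation.per_gene_top_k(gene_scores, gene_labels, 1.0),
            "top05": evaluation.per_gene_top_k(gene_scores, gene_labels, 0.5),
            "auprc": evaluation.auprc(pooled_s, pooled_y),
            "n_sites": int(pooled_y.sum()),
        }
    for m in ("top1", "top05", "auprc"):
        out[m] = float(np.mean([out["per_tissue"][t][m] for t in TISSUES]))
    return out


def evaluate_usage(bundle: ModelBundle, genome: Fasta, db,
                   data: PipelineData) -> dict:
    """Usage recovery and tissue specificity against the planted truth."""
    truth = data.truth
    test_set = set(data.test_ids)
    rows = truth[truth["gene_id"].isin(test_set) & ~truth["is_decoy"]]
    tracks = _gene_tracks(bundle, genome, db, sorted({r.gene_id for r in
                                                      rows.itertuples()}),
                          "usage")
    pred = np.zeros((len(rows), len(TISSUES)))
    obs = np.zeros_like(pred)
    coords_cache = {gid: datasets.gene_coords(db, gid)
                    for gid in {r.gene_id for r in rows.itertuples()}}
    for i, site in enumerate(rows.itertuples()):
        local = coords_cache[site.gene_id].genomic_to_local(int(site.position))
        for t_i, tissue in enumerate(TISSUES):
            pred[i, t_i] = tracks[site.gene_id][tissue][local]
            obs[i, t_i] = getattr(site, f"usage_{tissue}")
    result = {
        "spearman_pooled": evaluation.spearman(pred.ravel(), obs.ravel()),
        "n_sites": len(rows),
    }
    try:
        ts = evaluation.tissue_specificity_eval(pred, obs)
        result["tissue_specificity"] = ts.per_tissue
        result["tissue_specificity_n"] = ts.n_sites
    except InsufficientDataError as exc:
        result["tissue_specificity"] = None
        result["tissue_specificity_note"] = str(exc)
    return result


def evaluate_mutagenesis(bundle: ModelBundle, genome: Fasta, db,
                         data: PipelineData, threshold: float = 0.2,
                         max_sites: int | None = None, seed: int = 0) -> dict:
    """Core GT/AG disruption effects at held-out true sites."""
    truth = data.truth
    rows = truth[truth["gene_id"].isin(set(data.test_ids)) & ~truth["is_decoy"]]
    if max_sites is not None and len(rows) > max_sites:
        rows = rows.sample(n=max_sites, random_state=seed)
    seqs = {}
    decreases, n_deltas = [], []
    for site in rows.itertuples():
        gid = site.gene_id
        if gid not in seqs:
            coords = datasets.gene_coords(db, gid)
            seqs[gid] = (datasets.extract_gene_sequence(genome, coords), coords)
        seq, coords = seqs[gid]
        local = coords.genomic_to_local(int(site.position))
        try:
            res = _saturate_multi_tissue(bundle, seq, local, site.side)
        except DataError:
            continue  # window leaves the gene body; skip
        decreases.append(-mutagenesis.core_disruption_effects(res))
        n_deltas.append(len(res.effects))
    decreases = np.asarray(decreases)
    return {
        "n_sites": int(len(decreases)),
        "frac_core_decrease_ge_threshold": float((decreases >= threshold).mean()),
        "mean_core_decrease": float(decreases.mean()),
        "deltas_per_donor": 36, "deltas_per_acceptor": 54,
    }


def _saturate_multi_tissue(bundle: ModelBundle, seq: str, local: int,
                           side: str) -> mutagenesis.MutagenesisResult:
    """Saturation scan averaging across tissues, each tissue read out from
    its own fine-tuned usage ensemble."""
    per_tissue = [_single_tissue_deltas(bundle.usage(t), seq, local, side, t)
                  for t in TISSUES]
    merged = per_tissue[0].copy()
    merged["delta"] = np.mean([df["delta"].to_numpy() for df in per_tissue],
                              axis=0)
    return mutagenesis.MutagenesisResult(local, side, merged)


def _single_tissue_deltas(models, seq, local, side, tissue) -> pd.DataFrame:
    from .datasets import one_hot_encode
    from .model import ensemble_predict

    context = models[0].config.context
    offsets = mutagenesis.site_window_offsets(side)
    windows = [seq[local - context: local + context + 1]]
    rows = []
    for off in offsets:
        pos = local + off
        if pos - 0 < 0 or pos >= len(seq):
            raise DataError("mutagenesis window extends past the sequence")
        ref_base = seq[pos]
        for alt in "ACGT":
            if alt == ref_base:
                continue
            mutated = seq[:pos] + alt + seq[pos + 1:]
            windows.append(mutated[local - context: local + context + 1])
            rows.append({"offset": off, "ref_base": ref_base, "alt_base": alt})
    if local - context < 0 or local + context + 1 > len(seq):
        raise DataError("site window extends past the sequence")
    x = np.stack([one_hot_encode(w) for w in windows])
    out = ensemble_predict(models, x)[:, 0, :]
    col = 3 * TISSUES.index(tissue) + 2
    usage = out[:, col]
    df = pd.DataFrame(rows)
    df["delta"] = usage[1:] - usage[0]
    return df


def run_pipeline(out_dir: Path, seed: int, n_genes: int = 250,
                 config: ModelConfig = MINI_CONFIG,
                 schedule: TrainingSchedule = MINI_SCHEDULE,
                 mutagenesis_max_sites: int | None = 120,
                 **sim_kwargs) -> dict:
    """Run the full desk-scale study and return all metrics."""
    rng = np.random.default_rng(seed)
    data = simulate_and_quantify(Path(out_dir), _child_seed(rng),
                                 n_genes=n_genes, **sim_kwargs)
    blocks, genome, db = prepare_blocks(data)
    bundle = train_models(blocks, seed=_child_seed(rng), config=config,
                          schedule=schedule)
    results = {
        "n_train_genes": len(data.train_ids),
        "n_test_genes": len(data.test_ids),
        "probability": evaluate_probability(bundle, genome, db, data),
        "usage": evaluate_usage(bundle, genome, db, data),
    }
    if mutagenesis_max_sites != 0:
        results["mutagenesis"] = evaluate_mutagenesis(
            bundle, genome, db, data, max_sites=mutagenesis_max_sites,
            seed=_child_seed(rng))
    if bundle.log is not None:
        bundle.log.to_csv(Path(out_dir) / "training_log.csv", index=False)
    results["_bundle"] = bundle
    results["_data"] = data
    return results
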