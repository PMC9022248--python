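"""Splice-site labeling and usage quantification from junction read evidence.

A splice site's usage -- the fraction of a gene's transcripts that use the
site -- is estimated from four classes of RNA-seq reads counted per sample:

* ``alpha``: split reads mapping to or across the target junction,
  i.e. direct evidence *for* usage;
* ``beta1``: non-split reads spanning the site (evidence against);
* ``beta2_simple``: split reads giving direct evidence against usage;
* ``beta2_cryptic``: split reads giving indirect evidence against usage via
  a *partner* site ``p``, weighted by that partner's own split support
  ``alpha_p``.

The Splice-Site Strength Estimate (SSE) combines them as

    SSE = alpha / (alpha + beta1 + beta2_simple
                   + (1/alpha) * sum_p alpha_p * beta2_cryptic_p)

Sites are labeled *spliced* when supported by at least one split read in at
least two samples; everything else inside a gene body is *unspliced* with
usage 0.  Usage is quantified only for sites with
``alpha + beta1 + beta2_simple >= 5`` in at least two samples; spliced sites
failing this coverage rule are masked out of training and evaluation.

Coordinate convention: a site is keyed by its intron-terminal base -- the
first intronic base for donors and the last intronic base for acceptors --
0-based, on the transcribed strand's reading direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, NoEvidenceError

TISSUES = ("heart", "liver", "brain", "testis")

#: default coverage rule: alpha + beta1 + beta2_simple >= MIN_COVERAGE
#: in at least MIN_COVERED_SAMPLES samples
MIN_COVERAGE = 5
MIN_COVERED_SAMPLES = 2
#: spliced label rule: >=1 split read in at least MIN_SPLICED_SAMPLES samples
MIN_SPLICED_SAMPLES = 2

EVIDENCE_COLUMNS = [
    "chrom", "position", "strand", "side", "sample_id",
    "alpha", "beta1", "beta2_simple", "partner_alpha_beta2c",
]


@dataclass
class SpliceSiteEvidence:
    """Read-count evidence for one site in one sample (or pooled samples)."""

    site_id: str
    alpha: int
    beta1: int
    beta2_simple: int
    partners: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = [self.alpha, self.beta1, self.beta2_simple]
        counts += [c for pair in self.partners for c in pair]
        if any(c < 0 for c in counts):
            raise DataError(f"negative read count in evidence for {self.site_id}")

    @property
    def coverage(self) -> int:
        """Reads entering the coverage rule (cryptic partners excluded)."""
        return self.alpha + self.beta1 + self.beta2_simple

    @property
    def total(self) -> int:
        return self.coverage + sum(c for _, c in self.partners)


def compute_sse(evidence: SpliceSiteEvidence) -> float:
    """Splice-Site Strength Estimate in [0, 1].

    When ``alpha == 0`` the partner term ``(1/alpha) * sum(...)`` is taken in
    the limit: no split read supports the junction, so the estimate is 0
    provided any counter-evidence exists.  If every count is zero the site
    has no evidence at all and :class:`NoEvidenceError` is raised.
    """
    a = evidence.alpha
    if a == 0:
        if evidence.total == 0:
            raise NoEvidenceError(f"no reads at all for site {evidence.site_id}")
        return 0.0
    cryptic = sum(ap * b2c for ap, b2c in evidence.partners)
    return a / (a + evidence.beta1 + evidence.beta2_simple + cryptic / a)


def label_spliced(split_read_counts: Sequence[int],
                  min_samples: int = MIN_SPLICED_SAMPLES) -> bool:
    """True iff >=1 split read in at least ``min_samples`` samples."""
    if len(split_read_counts) == 0:
        raise DataError("label_spliced requires at least one sample")
    return sum(1 for c in split_read_counts if c >= 1) >= min_samples


def pool_evidence(samples: Sequence[SpliceSiteEvidence]) -> SpliceSiteEvidence:
    """Sum counts across samples; partner lists are merged positionally.

    Each sample is expected to report the same (possibly empty) partner set
    in the same order; the k-th partner's ``alpha_p`` and ``beta2_cryptic``
    are summed across samples.
    """
    if not samples:
        raise DataError("cannot pool an empty evidence list")
    n_partners = max(len(s.partners) for s in samples)
    pooled_partners = [
        (sum(s.partners[k][0] for s in samples if len(s.partners) > k),
         sum(s.partners[k][1] for s in samples if len(s.partners) > k))
        for k in range(n_partners)
    ]
    return SpliceSiteEvidence(
        site_id=samples[0].site_id,
        alpha=sum(s.alpha for s in samples),
        beta1=sum(s.beta1 for s in samples),
        beta2_simple=sum(s.beta2_simple for s in samples),
        partners=pooled_partners,
    )


def quantify_usage(samples: Sequence[SpliceSiteEvidence],
                   spliced: bool,
                   min_coverage: int = MIN_COVERAGE,
                   min_covered_samples: int = MIN_COVERED_SAMPLES,
                   mode: str = "pooled") -> tuple[float, bool]:
    """Per-tissue usage for a site already labeled spliced/unspliced.

    Returns ``(usage, quantifiable)``.  Unspliced sites are assigned usage 0
    with a true mask.  Spliced sites failing the coverage rule return
    ``(nan, False)`` and must be excluded from training and evaluation.

    ``mode`` selects how per-sample evidence is aggregated into one value:
    ``"pooled"`` (default) computes one SSE on counts summed over the
    samples passing the coverage rule; ``"mean"`` averages per-sample SSEs.
    """
    if not samples:
        raise DataError("quantify_usage requires at least one sample")
    if not spliced:
        return 0.0, True
    passing = [s for s in samples if s.coverage >= min_coverage]
    if len(passing) < min_covered_samples:
        return float("nan"), False
    if mode == "pooled":
        return compute_sse(pool_evidence(passing)), True
    if mode == "mean":
        return float(np.mean([compute_sse(s) for s in passing])), True
    raise DataError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# Evidence table I/O and the per-tissue site table
# ---------------------------------------------------------------------------

def _parse_partners(cell) -> list[tuple[int, int]]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "" or cell == ".":
        return []
    pairs = []
    for chunk in str(cell).split(";"):
        ap, b2c = chunk.split(":")
        pairs.append((int(ap), int(b2c)))
    return pairs


def format_partners(partners: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{ap}:{b2c}" for ap, b2c in partners) if partners else "."


def read_evidence(path) -> pd.DataFrame:
    """Read a junction-evidence TSV (see :data:`EVIDENCE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"evidence table missing columns: {sorted(missing)}")
    return df


def quantify_sites(evidence: pd.DataFrame,
                   sample_tissues: Mapping[str, str],
                   tissues: Sequence[str] = TISSUES,
                   min_coverage: int = MIN_COVERAGE,
                   min_covered_samples: int = MIN_COVERED_SAMPLES,
                   min_spliced_samples: int = MIN_SPLICED_SAMPLES,
                   mode: str = "pooled") -> pd.DataFrame:
    """Build the per-tissue site table from a long-format evidence table.

    Parameters
    ----------
    evidence
        One row per (site, sample); columns as in :data:`EVIDENCE_COLUMNS`.
    sample_tissues
        Maps each ``sample_id`` to its tissue.

    Returns
    -------
    DataFrame keyed by (chrom, position, strand, side) with, per tissue
    ``t``: ``spliced_t`` (bool), ``usage_t`` (float, NaN when masked) and
    ``mask_t`` (bool, False when the site is spliced but unquantifiable).
    """
    unknown = set(evidence["sample_id"]) - set(sample_tissues)
    if unknown:
        raise DataError(f"samples with no tissue assignment: {sorted(unknown)[:5]}")
    ev = evidence.copy()
    ev["tissue"] = ev["sample_id"].map(sample_tissues)

    rows = []
    site_cols = ["chrom", "position", "strand", "side"]
    for key, site_df in ev.groupby(site_cols, sort=True):
        row: dict = dict(zip(site_cols, key))
        for tissue in tissues:
            tdf = site_df[site_df["tissue"] == tissue]
            samples = [
                SpliceSiteEvidence(
                    site_id=f"{key[0]}:{key[1]}",
                    alpha=int(r.alpha), beta1=int(r.beta1),
                    beta2_simple=int(r.beta2_simple),
                    partners=_parse_partners(r.partner_alpha_beta2c),
                )
                for r in tdf.itertuples()
            ]
            if not samples:
                row[f"spliced_{tissue}"] = False
                row[f"usage_{tissue}"] = 0.0
                row[f"mask_{tissue}"] = True
                continue
            spliced = label_spliced([s.alpha for s in samples], min_spliced_samples)
            usage, ok = quantify_usage(
                samples, spliced, min_coverage, min_covered_samples, mode)
            row[f"spliced_{tissue}"] = spliced
            row[f"usage_{tissue}"] = usage
            row[f"mask_{tissue}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in df.columns:
        if col.startswith(("spliced_", "mask_")):
            df[col] = df[col].astype(bool)
    return df
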