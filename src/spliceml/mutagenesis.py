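"""In silico saturation mutagenesis and interspecies divergence attribution.

Saturation mutagenesis scans the canonical motif window of each splice site
-- 8 intronic + 4 exonic positions for 5' (donor) sites, 15 intronic + 3
exonic positions for 3' (acceptor) sites -- mutating each base to the three
alternatives and recording the mean predicted change in usage across
tissues (the usage model is the readout, since the quantity of interest is
splice-site usage).  Effects are summarized as the fraction of sites whose
usage is predicted to increase or decrease by at least 0.2 per
(position, alternate-base) cell.

For interspecies divergence the probability model is the readout.  The
false sign rate (FSR) at a cutoff is, among site pairs whose predicted
cross-species difference exceeds the cutoff in magnitude, the fraction
where the predicted sign contradicts the observed one.  Single-variant
attribution asks whether one substitution near the site explains the
predicted difference: pairs with more than 20 sequence differences within
100 bp of the site are skipped as too diverged; the difference must be
reproduced (up to a configurable fraction ``f``) by swapping only the
+/-100 bp window between species, and a single substitution is attributed
when introducing it alone into the first species' context recovers at
least ``f`` of the full predicted difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError
from .junctions import TISSUES
from .datasets import one_hot_encode
from .model import SpliceNet, ensemble_predict

USAGE_COLS = {t: 3 * i + 2 for i, t in enumerate(TISSUES)}
SPLICED_COLS = {t: 3 * i + 1 for i, t in enumerate(TISSUES)}

#: (intronic, exonic) scan depths per site side
MUTAGENESIS_WINDOW = {"donor": (8, 4), "acceptor": (15, 3)}


def site_window_offsets(side: str) -> list[int]:
    """Scanned offsets relative to the site's intron-terminal base.

    Donor (5'): the site base is the first intronic base, so offsets run
    from -4 (exon) to +7 (intron).  Acceptor (3'): the site base is the
    last intronic base, so offsets run from -14 (intron) to +3 (exon).
    """
    if side not in MUTAGENESIS_WINDOW:
        raise DataError(f"unknown site side {side!r}")
    intronic, exonic = MUTAGENESIS_WINDOW[side]
    if side == "donor":
        return list(range(-exonic, intronic))
    return list(range(-(intronic - 1), exonic + 1))


@dataclass
class MutagenesisResult:
    """All single-base effects around one site."""

    site_local: int
    side: str
    effects: pd.DataFrame  # columns: offset, ref_base, alt_base, delta


def _usage_at_site(models, windows: list[str], tissues=TISSUES) -> np.ndarray:
    """Mean usage across tissues at the center of each window, shape (n,)."""
    x = np.stack([one_hot_encode(w) for w in windows])
    out = ensemble_predict(models, x)[:, 0, :]
    cols = [USAGE_COLS[t] for t in tissues]
    return out[:, cols].mean(axis=1)


def saturate_site(usage_models: Sequence[SpliceNet], gene_seq: str,
                  site_local: int, side: str) -> MutagenesisResult:
    """Predict the usage effect of every single-base mutation near a site."""
    context = usage_models[0].config.context
    offsets = site_window_offsets(side)
    lo = site_local + offsets[0] - context
    hi = site_local + offsets[-1] + context + 1
    if lo < 0 or hi > len(gene_seq):
        raise DataError("mutagenesis window extends past the sequence")
    windows = [gene_seq[site_local - context: site_local + context + 1]]
    rows = []
    for off in offsets:
        pos = site_local + off
        ref_base = gene_seq[pos]
        for alt in "ACGT":
            if alt == ref_base:
                continue
            mutated = gene_seq[:pos] + alt + gene_seq[pos + 1:]
            windows.append(mutated[site_local - context: site_local + context + 1])
            rows.append({"offset": off, "ref_base": ref_base, "alt_base": alt})
    usages = _usage_at_site(usage_models, windows)
    effects = pd.DataFrame(rows)
    effects["delta"] = usages[1:] - usages[0]
    return MutagenesisResult(site_local, side, effects)


def summarize_effects(results: Sequence[MutagenesisResult],
                      threshold: float = 0.2) -> pd.DataFrame:
    """Per (offset, alternate base): fraction of sites increasing/decreasing.

    Fractions count sites whose predicted usage change is >= +threshold
    (increase) or <= -threshold (decrease), among the sites contributing a
    mutation at that cell.  The square-root display transform used in
    published summaries is left to plotting.
    """
    if not results:
        raise DataError("no mutagenesis results to summarize")
    frames = [r.effects for r in results]
    allf = pd.concat(frames, ignore_index=True)
    grouped = allf.groupby(["offset", "alt_base"])["delta"]
    summary = grouped.agg(
        n="count",
        frac_increase=lambda d: float((d >= threshold).mean()),
        frac_decrease=lambda d: float((d <= -threshold).mean()),
    ).reset_index()
    return summary


def core_disruption_effects(result: MutagenesisResult) -> float:
    """Mean usage change over mutations of the GT/AG core dinucleotide."""
    core = (0, 1) if result.side == "donor" else (-1, 0)
    sel = result.effects["offset"].isin(core)
    if not sel.any():
        raise DataError("core dinucleotide not covered by the scan")
    return float(result.effects.loc[sel, "delta"].mean())


# ---------------------------------------------------------------------------
# Interspecies divergence
# ---------------------------------------------------------------------------

def false_sign_rate(predicted, observed, cutoff: float) -> float:
    """Among |predicted| >= cutoff pairs, the fraction with discordant sign."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise DataError("predicted/observed must be paired")
    passing = np.abs(predicted) >= cutoff
    if not passing.any():
        raise InsufficientDataError(f"no site passes cutoff {cutoff}")
    discordant = np.sign(predicted[passing]) != np.sign(observed[passing])
    return float(discordant.mean())


@dataclass
class DivergenceCall:
    """Attribution outcome for one cross-species site pair."""

    predicted_difference: float
    variant: tuple[int, str, str] | None  # (offset from site, base_a, base_b)
    explained_fraction: float | None
    reason: str


def _prob_score(models, window: str) -> np.ndarray:
    x = one_hot_encode(window)[None]
    out = ensemble_predict(models, x)[0, 0]
    return np.array([out[SPLICED_COLS[t]] for t in TISSUES])


def _signed_max(v: np.ndarray) -> float:
    return float(v[int(np.argmax(np.abs(v)))])


def attribute_single_variant(prob_models: Sequence[SpliceNet],
                             context_a: str, context_b: str,
                             f: float = 0.8, near: int = 100,
                             max_nearby_diffs: int = 20) -> DivergenceCall:
    """Attribute a cross-species score difference to a single substitution.

    ``context_a``/``context_b`` are equal-length windows centered on the
    site in the two species (length 2*context+1 of the probability models).
    The predicted difference is the signed-max across tissues of
    P_spliced(b) - P_spliced(a).
    """
    if len(context_a) != len(context_b):
        raise DataError("species contexts must be pre-aligned to equal length")
    center = len(context_a) // 2
    diffs = [i for i in range(len(context_a)) if context_a[i] != context_b[i]]
    nearby = [i for i in diffs if abs(i - center) <= near]
    full = _signed_max(_prob_score(prob_models, context_b)
                       - _prob_score(prob_models, context_a))
    if len(nearby) > max_nearby_diffs:
        return DivergenceCall(full, None, None, "divergence cap exceeded")
    if not nearby:
        return DivergenceCall(full, None, None, "no nearby difference")
    if abs(full) < 1e-12:
        return DivergenceCall(full, None, None, "no predicted difference")
    # does the +/-near window explain the difference at all?
    lo, hi = center - near, center + near + 1
    hybrid = context_a[:lo] + context_b[lo:hi] + context_a[hi:]
    d_near = _signed_max(_prob_score(prob_models, hybrid)
                         - _prob_score(prob_models, context_a))
    if np.sign(d_near) != np.sign(full) or abs(d_near) < f * abs(full):
        return DivergenceCall(full, None, None,
                              "difference driven by distal divergence")
    best = None
    for i in nearby:
        single = context_a[:i] + context_b[i] + context_a[i + 1:]
        d_i = _signed_max(_prob_score(prob_models, single)
                          - _prob_score(prob_models, context_a))
        if np.sign(d_i) == np.sign(full) and abs(d_i) >= f * abs(full):
            if best is None or abs(d_i) > abs(best[1]):
                best = (i, d_i)
    if best is None:
        return DivergenceCall(full, None, None,
                              "no single variant explains the difference")
    i, d_i = best
    return DivergenceCall(full, (i - center, context_a[i], context_b[i]),
                          float(d_i / full), "attributed")
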