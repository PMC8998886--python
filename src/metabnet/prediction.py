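"""Transcriptome-only prediction of metabolite abundance.

A :class:`~metabnet.network.MetaboliteNetwork` is applied to an expression
matrix the network has never seen.  Each metabolite's predicted (relative)
abundance is a Normalized Enrichment Score (NES): the signed, likelihood-
weighted aggregation of its target transcripts' signature scores, normalized
so that a random signature yields a standard-normal score.

Two signature modes exist:

* ``sample`` — each sample scored relative to the mean of the dataset
  (per-gene z-score across samples), yielding one NES per metabolite per
  sample;
* ``contrast`` — a single Welch t-statistic per gene between two sample
  groups, yielding one NES (+ two-sided p and BH-FDR) per metabolite.

The NES itself: all G signature scores are rank-transformed to normal
quantiles q_g = Phi^-1(rank_g / (G+1)) (average ranks on ties; the rank pool
is the whole signature, so targets are ranked against the transcriptome
background).  With per-target weight w_g = r_g * likelihood_g,

    NES = sum_{g in targets} w_g * q_g / sqrt(sum w_g^2),

which has mean 0 and variance ~1 when the signature carries no information.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix, harmonize_feature_names, zscore_rows
from .network import MetaboliteNetwork

log = logging.getLogger(__name__)


@dataclasses.dataclass
class Signature:
    """Per-gene score matrix (genes x signature columns) with a mode tag."""

    scores: pd.DataFrame
    mode: str  # "sample" | "contrast"

    def __post_init__(self) -> None:
        if self.mode not in ("sample", "contrast"):
            raise ValueError(f"unknown signature mode {self.mode!r}")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("signature scores must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclasses.dataclass
class PredictionResult:
    """NES per metabolite: a metabolites x samples frame in sample mode, a
    single-column frame in contrast mode (with per-metabolite two-sided p and
    BH-FDR).  Metabolites that could not be scored are in ``skipped`` with a
    reason; together the two cover every network metabolite."""

    nes: pd.DataFrame
    mode: str
    skipped: dict[str, str]
    p: pd.Series | None = None
    fdr: pd.Series | None = None


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

def sample_signatures(expr: OmicsMatrix) -> Signature:
    """One signature column per sample: per-gene z-score against the dataset
    mean/sd (n-1 divisor).  Zero-variance genes are dropped and logged."""
    if expr.n_samples < 3:
        raise ValueError(f"sample signatures need >= 3 samples, got {expr.n_samples}")
    z = zscore_rows(expr)
    scores = z.values.dropna(axis=0)  # genes with missing cells leave the rank pool
    if len(scores) < len(z.values):
        log.info("sample_signatures: dropped %d genes with missing values", len(z.values) - len(scores))
    return Signature(scores=scores, mode="sample")


def contrast_signature(group1: OmicsMatrix, group2: OmicsMatrix) -> Signature:
    """Per-gene Welch t-statistic (group1 minus group2) over the shared gene
    set.  Genes constant in both groups score 0 (with a warning)."""
    if group1.n_samples < 2 or group2.n_samples < 2:
        raise ValueError("each group needs >= 2 samples")
    shared = [g for g in group1.feature_ids if g in set(group2.feature_ids)]
    if not shared:
        raise ValueError("empty gene intersection between the two groups")
    a = group1.values.loc[shared].to_numpy(dtype=float)
    b = group2.values.loc[shared].to_numpy(dtype=float)
    m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
    v1 = np.nanvar(a, axis=1, ddof=1) / np.sum(np.isfinite(a), axis=1)
    v2 = np.nanvar(b, axis=1, ddof=1) / np.sum(np.isfinite(b), axis=1)
    denom = np.sqrt(v1 + v2)
    flat = denom == 0
    if flat.any():
        log.warning("contrast_signature: %d genes constant in both groups scored 0", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(flat, 0.0, (m1 - m2) / np.where(flat, 1.0, denom))
    scores = pd.DataFrame({"t": t}, index=pd.Index(shared))
    return Signature(scores=scores, mode="contrast")


# ---------------------------------------------------------------------------
# NES
# ---------------------------------------------------------------------------

def _rank_quantiles(scores: np.ndarray) -> np.ndarray:
    """Column-wise rank transform to normal quantiles Phi^-1(rank/(G+1)),
    average ranks for ties."""
    G = scores.shape[0]
    ranks = stats.rankdata(scores, axis=0, method="average")
    return stats.norm.ppf(ranks / (G + 1.0))


def _nes_from_q(q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """NES for one target set over one or more signature columns.

    q : (n_targets, n_columns) normal-quantile scores of the targets.
    w : (n_targets,) signed weights (r * likelihood).
    """
    norm = np.sqrt(np.sum(w * w))
    return (w @ q) / norm


def nes_score(signature: Signature, targets: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Score one metabolite's target set against each signature column.

    ``targets`` needs columns ``transcript``, ``r``, ``likelihood``; targets
    absent from the signature's gene pool are ignored.  Returns (nes, p)
    arrays with one entry per signature column, or NaN markers if no target
    is present.
    """
    present = targets[targets["transcript"].isin(signature.scores.index)]
    ncol = signature.scores.shape[1]
    if present.empty:
        return np.full(ncol, np.nan), np.full(ncol, np.nan)
    q_all = _rank_quantiles(signature.scores.to_numpy(dtype=float))
    pos = signature.scores.index.get_indexer(present["transcript"])
    w = (present["r"] * present["likelihood"]).to_numpy(dtype=float)
    nes = _nes_from_q(q_all[pos], w)
    return nes, 2.0 * stats.norm.sf(np.abs(nes))


# ---------------------------------------------------------------------------
# Prediction driver
# ---------------------------------------------------------------------------

def predict(
    net: MetaboliteNetwork,
    expr: OmicsMatrix,
    mode: str = "sample",
    minsize: int = 10,
    group1: Sequence[str] | None = None,
    group2: Sequence[str] | None = None,
) -> PredictionResult:
    """Predict metabolite abundance from expression alone.

    Gene ids are harmonized (exact after case/whitespace/underscore
    normalization) between the network's transcripts and ``expr``.  A
    metabolite is scored only if at least ``minsize`` of its network targets
    are measured in ``expr``; otherwise it is skipped with a recorded reason.
    """
    if mode not in ("sample", "contrast"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    if mode == "contrast":
        if group1 is None or group2 is None:
            raise ValueError("contrast mode requires group1 and group2 sample lists")
        sig = contrast_signature(expr.subset(samples=list(group1)), expr.subset(samples=list(group2)))
    else:
        sig = sample_signatures(expr)

    harm = harmonize_feature_names(net.transcript_ids, sig.gene_ids)
    t2g = harm.mapping
    q_all = _rank_quantiles(sig.scores.to_numpy(dtype=float))

    nes_rows: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for m in net.metabolite_ids:
        reg = net.regulon(m)
        genes = reg["transcript"].map(t2g)
        ok = genes.notna()
        n_meas = int(ok.sum())
        if n_meas < minsize:
            skipped[m] = f"targets_measured={n_meas} < minsize={minsize}"
            continue
        pos = sig.scores.index.get_indexer(genes[ok])
        w = (reg.loc[ok, "r"] * reg.loc[ok, "likelihood"]).to_numpy(dtype=float)
        nes_rows[m] = _nes_from_q(q_all[pos], w)

    if not nes_rows:
        raise ValueError(
            "no metabolite predictable: "
            f"{len(net.metabolite_ids)} network metabolites, "
            f"{harm.n_matched}/{len(net.transcript_ids)} network transcripts matched "
            f"to {len(sig.gene_ids)} measured genes, minsize={minsize}"
        )
    cols = list(sig.scores.columns) if mode == "sample" else ["NES"]
    nes = pd.DataFrame.from_dict(nes_rows, orient="index", columns=cols)
    nes = nes.loc[[m for m in net.metabolite_ids if m in nes_rows]]
    log.info("predict: scored %d metabolites, skipped %d", len(nes), len(skipped))

    p = fdr = None
    if mode == "contrast":
        pv = 2.0 * stats.norm.sf(np.abs(nes["NES"].to_numpy()))
        from .evaluation import bh_adjust  # local import to avoid a cycle

        p = pd.Series(pv, index=nes.index, name="p")
        fdr = pd.Series(bh_adjust(pv), index=nes.index, name="fdr")
    return PredictionResult(nes=nes, mode=mode, skipped=skipped, p=p, fdr=fdr)
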