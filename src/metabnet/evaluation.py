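"""Validation harness: predicted-vs-measured scoring, repeated split-half
validation, the degree-proportional shuffled-network null, and the small
statistical utilities (one-tail Wilcoxon signed-rank summary, BH adjustment)
used to report them.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inference import InferenceConfig, infer_network, pairwise_pearson
from .matrix import OmicsMatrix, harmonize_feature_names
from .network import MetaboliteNetwork
from .prediction import PredictionResult, predict

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Statistical utilities
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_one_tail_greater(values) -> float:
    """One-tail Wilcoxon signed-rank p that the values are shifted above 0.

    Zeros are discarded (at least one non-zero value required).  Exact
    distribution of the positive-rank sum for n <= 25 without ties in the
    absolute values; otherwise normal approximation with tie correction and
    a 0.5 continuity correction.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    v = v[v != 0]
    n = v.size
    if n == 0:
        raise ValueError("need at least one non-zero value")
    absv = np.abs(v)
    ranks = stats.rankdata(absv)
    w_plus = float(ranks[v > 0].sum())
    if n <= 25 and np.unique(absv).size == n:
        # exact: counts of subset rank-sums via the generating polynomial
        total = n * (n + 1) // 2
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for i in range(1, n + 1):
            new = counts.copy()
            new[i:] += counts[:-i]
            counts = new
        return float(counts[int(round(w_plus)):].sum() / 2.0**n)
    mu = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
    z = (w_plus - mu - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Predicted vs measured
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvalReport:
    """Per-metabolite predicted-vs-measured scores and a summary.

    ``table`` columns: r, p, fdr, n_samples, class_adj (BH-adjusted call),
    class_nominal (raw-p call); classes are ``positive-significant``,
    ``negative-significant`` or ``non-significant`` at alpha = 0.05.
    ``skipped`` maps metabolites that could not be evaluated to a reason.
    """

    table: pd.DataFrame
    skipped: dict[str, str]
    summary: dict

    @property
    def mean_r(self) -> float:
        return self.summary["mean_r"]


def _classify(r: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    out = np.full(len(r), "non-significant", dtype=object)
    out[(p < alpha) & (r > 0)] = "positive-significant"
    out[(p < alpha) & (r < 0)] = "negative-significant"
    return out


def per_metabolite_correlation(
    pred: PredictionResult, measured: OmicsMatrix, alpha: float = 0.05
) -> EvalReport:
    """Pearson r between predicted NES and measured abundance per metabolite,
    across the shared samples; BH-FDR across metabolites; classification at
    alpha both on adjusted and on nominal p."""
    if pred.mode != "sample":
        raise ValueError("evaluation requires a sample-mode prediction")
    harm = harmonize_feature_names(list(pred.nes.index), measured.feature_ids)
    if harm.n_matched == 0:
        raise ValueError(
            "no shared metabolite between prediction and measurement; "
            f"unmatched predicted (first 5): {harm.unmatched_a[:5]}, "
            f"unmatched measured (first 5): {harm.unmatched_b[:5]}"
        )
    shared_samples = [s for s in pred.nes.columns if s in set(measured.sample_ids)]
    if len(shared_samples) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared_samples)}")

    rows = []
    skipped = dict(pred.skipped)
    for pm, mm_ in harm.matches:
        x = pred.nes.loc[pm, shared_samples].to_numpy(dtype=float)
        y = measured.values.loc[mm_, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            skipped[pm] = f"shared_samples={int(ok.sum())} < 3"
            continue
        r, p, npairs = _pearson(x[ok], y[ok])
        if not np.isfinite(r):
            skipped[pm] = "correlation not computable (constant values)"
            continue
        rows.append((pm, r, p, npairs))
    if not rows:
        raise ValueError("no metabolite could be evaluated")
    table = pd.DataFrame(rows, columns=["metabolite", "r", "p", "n_samples"]).set_index("metabolite")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["class_adj"] = _classify(table["r"].to_numpy(), table["fdr"].to_numpy(), alpha)
    table["class_nominal"] = _classify(table["r"].to_numpy(), table["p"].to_numpy(), alpha)
    rs = table["r"].to_numpy()
    summary = {
        "n_evaluated": len(table),
        "n_skipped": len(skipped),
        "mean_r": float(np.mean(rs)),
        "wilcoxon_p": wilcoxon_one_tail_greater(rs) if np.any(rs != 0) else 1.0,
        "counts_adj": table["class_adj"].value_counts().to_dict(),
        "counts_nominal": table["class_nominal"].value_counts().to_dict(),
    }
    return EvalReport(table=table, skipped=skipped, summary=summary)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    r, p, n = pairwise_pearson(x[None, :], y[None, :], min_pairs=3)
    return float(r[0, 0]), float(p[0, 0]), int(n[0, 0])


# ---------------------------------------------------------------------------
# Split-half validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitHalfResult:
    """Per-split, per-metabolite predicted-vs-measured r (NaN = not
    predictable in that split) for the real network and, optionally, for its
    degree-proportional shuffled twin."""

    r: pd.DataFrame
    shuffled_r: pd.DataFrame | None = None

    def mean_r(self) -> pd.Series:
        return self.r.mean(axis=0, skipna=True)


def split_half_evaluate(
    combined: OmicsMatrix,
    n_splits: int,
    cfg: InferenceConfig,
    seed: int,
    minsize: int = 10,
    shuffled: bool = False,
) -> SplitHalfResult:
    """Repeated random 50/50 split of the samples: infer the network on the
    training half (floor(n/2) samples), predict sample-by-sample on the test
    half from its transcripts alone, and record predicted-vs-measured Pearson
    r per metabolite.  Deterministic given ``seed``.

    With ``shuffled=True`` each trained network is additionally shuffled
    (degree-proportional transcript relabeling) and scored the same way.
    """
    if combined.n_samples < 20:
        raise ValueError("split-half validation needs >= 20 samples")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    samples = np.asarray(combined.sample_ids)
    n_train = combined.n_samples // 2
    metab_ids = combined.metabolites().feature_ids

    real = np.full((n_splits, len(metab_ids)), np.nan)
    shuf = np.full((n_splits, len(metab_ids)), np.nan) if shuffled else None
    col = {m: j for j, m in enumerate(metab_ids)}
    for s in range(n_splits):
        perm = rng.permutation(len(samples))
        train_ids = samples[perm[:n_train]]
        test_ids = samples[perm[n_train:]]
        cfg_s = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
        net = infer_network(combined.subset(samples=train_ids), cfg_s, source=f"split_{s}")
        if net.n_edges == 0:
            continue
        test_expr = combined.transcripts().subset(samples=test_ids)
        test_metab = combined.metabolites().subset(samples=test_ids)
        for which, out in (("real", real),) + ((("shuffled", shuf),) if shuffled else ()):
            use_net = net
            if which == "shuffled":
                use_net = shuffle_network(net, seed=int(rng.integers(2**31)))
            try:
                pred = predict(use_net, test_expr, mode="sample", minsize=minsize)
            except ValueError:
                continue
            rep = _quick_r(pred, test_metab)
            for m, r in rep.items():
                out[s, col[m]] = r
    return SplitHalfResult(
        r=pd.DataFrame(real, columns=metab_ids),
        shuffled_r=pd.DataFrame(shuf, columns=metab_ids) if shuffled else None,
    )


def _quick_r(pred: PredictionResult, measured: OmicsMatrix) -> dict[str, float]:
    """Per-metabolite predicted-vs-measured r without the BH machinery
    (exact-id match; used inside the split loop)."""
    out: dict[str, float] = {}
    shared = [s for s in pred.nes.columns if s in set(measured.sample_ids)]
    for m in pred.nes.index:
        if m not in measured.values.index:
            continue
        x = pred.nes.loc[m, shared].to_numpy(dtype=float)
        y = measured.values.loc[m, shared].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3:
            r, _, _ = _pearson(x[ok], y[ok])
            if np.isfinite(r):
                out[m] = r
    return out


# ---------------------------------------------------------------------------
# Shuffled-network null
# ---------------------------------------------------------------------------

def shuffle_network(net: MetaboliteNetwork, seed: int) -> MetaboliteNetwork:
    """Degree-proportional relabeling of transcript endpoints.

    Per-metabolite edge counts, r, likelihood and DPI flags are preserved;
    each edge's transcript is redrawn (with replacement) from the multiset of
    transcript endpoints, so a transcript's chance of appearing is
    proportional to its degree.  A duplicate (metabolite, transcript) pair is
    redrawn up to 100 times, then dropped with a warning.  Deterministic
    given ``seed``.
    """
    if net.n_edges == 0:
        raise ValueError("cannot shuffle an empty network")
    pool = net.edges["transcript"].to_numpy()
    if len(set(pool)) < 2:
        log.warning("shuffle_network: single-transcript network returned unchanged")
        return MetaboliteNetwork(edges=net.edges.copy(), meta=dict(net.meta, shuffled=True))
    rng = np.random.default_rng(seed)
    taken: set[tuple[str, str]] = set()
    keep_rows: list[int] = []
    new_t: list[str] = []
    n_dropped = 0
    mets = net.edges["metabolite"].to_numpy()
    for i in range(len(pool)):
        m = mets[i]
        t = None
        for _ in range(100):
            cand = pool[rng.integers(len(pool))]
            if (m, cand) not in taken:
                t = cand
                break
        if t is None:
            n_dropped += 1
            continue
        taken.add((m, t))
        keep_rows.append(i)
        new_t.append(t)
    if n_dropped:
        log.warning("shuffle_network: dropped %d colliding edges", n_dropped)
    edges = net.edges.iloc[keep_rows].copy()
    edges["transcript"] = new_t
    return MetaboliteNetwork(
        edges=edges.reset_index(drop=True),
        meta=dict(net.meta, shuffled=True, shuffle_seed=seed, n_dropped=n_dropped),
    )
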