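"""Metabolite-hub co-occurrence network inference.

Pipeline: all metabolite x transcript (and auxiliary metabolite x metabolite)
Pearson correlations with a p-value gate; data-processing-inequality (DPI)
pruning over metabolite-metabolite-transcript triplets; bootstrap resampling
of samples to attach a support likelihood to every candidate edge.  The final
network keeps a candidate if it survives the full-data DPI *or* is supported
by at least one bootstrap (which re-admits edges the full-data DPI removed),
weighting each kept edge by ``likelihood = k / B``.

Metabolite-metabolite correlations are used only to form DPI triplets; they
are never emitted as network edges.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix
from .network import MetaboliteNetwork

log = logging.getLogger(__name__)

# relative tolerance below which a pairwise-complete variance counts as zero
_VAR_RTOL = 1e-10


@dataclasses.dataclass
class InferenceConfig:
    """Knobs of the network-inference stage.

    p_threshold : raw two-sided p-value gate for a putative edge (0.001).
    n_bootstraps : number of sample resamples used for edge likelihood (100).
    min_pairs : minimum pairwise-complete observations per correlation (10).
    seed : governs all bootstrap resamples through a single generator.
    """

    p_threshold: float = 0.001
    n_bootstraps: int = 100
    min_pairs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must lie in (0, 1), got {self.p_threshold}")
        if self.n_bootstraps < 1:
            raise ValueError(f"n_bootstraps must be >= 1, got {self.n_bootstraps}")
        if self.min_pairs < 3:
            raise ValueError(f"min_pairs must be >= 3, got {self.min_pairs}")


@dataclasses.dataclass
class CandidateEdgeSet:
    """Gated correlations: metabolite-transcript candidates (``mt``) and
    auxiliary metabolite-metabolite correlations (``mm``).

    ``mm`` pairs are stored once with ``m1 < m2`` lexicographically.  After
    :func:`dpi_prune`, ``mt`` carries a boolean ``dpi_survivor`` column.
    """

    mt: pd.DataFrame  # metabolite, transcript, r, p, n_pairs [, dpi_survivor]
    mm: pd.DataFrame  # m1, m2, r, p, n_pairs
    n_tested: int = 0


# ---------------------------------------------------------------------------
# Pearson machinery
# ---------------------------------------------------------------------------

def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p-value from the exact t transform
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; |r| = 1 -> p = 0.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r * r
        t = r * np.sqrt((n - 2.0) / denom)
    p = np.where(denom <= 0, 0.0, 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1.0)))
    return np.where(np.isfinite(r) & (n >= 3), p, np.nan)


def pairwise_pearson(
    X: np.ndarray, Y: np.ndarray, min_pairs: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Pearson r between rows of X and rows of Y, pairwise-complete
    over missing (NaN) entries.

    Returns (R, P, N): correlation, two-sided p, and the number of complete
    pairs per cell.  Cells with fewer than ``min_pairs`` complete pairs or a
    zero-variance member are NaN (the "not computable" marker).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mx = np.isfinite(X)
    my = np.isfinite(Y)
    X0 = np.where(mx, X, 0.0)
    Y0 = np.where(my, Y, 0.0)
    fx = mx.astype(float)
    fy = my.astype(float)
    n = fx @ fy.T
    sx = X0 @ fy.T
    sy = fx @ Y0.T
    sxx = (X0 * X0) @ fy.T
    syy = fx @ (Y0 * Y0).T
    sxy = X0 @ Y0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r = cov / np.sqrt(vx * vy)
    # zero variance detected on the scale of the raw second moments
    const = (vx <= _VAR_RTOL * np.maximum(n * sxx, 1e-300)) | (
        vy <= _VAR_RTOL * np.maximum(n * syy, 1e-300)
    )
    r = np.clip(r, -1.0, 1.0)
    bad = const | (n < max(min_pairs, 3)) | ~np.isfinite(r)
    r = np.where(bad, np.nan, r)
    p = _p_from_r(r, n)
    return r, p, n.astype(int)


def pearson_with_p(x, y, min_pairs: int = 3) -> tuple[float, float, int]:
    """Pearson r, two-sided p (exact t-tail), and complete-pair count for two
    vectors, pairwise-complete over missing values.

    Not-computable inputs (fewer than ``min_pairs`` complete pairs, or a
    constant vector) return ``(nan, nan, n)`` rather than raising, so an
    all-pairs scan can simply skip them.
    """
    r, p, n = pairwise_pearson(
        np.asarray(x, dtype=float)[None, :],
        np.asarray(y, dtype=float)[None, :],
        min_pairs=min_pairs,
    )
    return float(r[0, 0]), float(p[0, 0]), int(n[0, 0])


# ---------------------------------------------------------------------------
# Candidate scan
# ---------------------------------------------------------------------------

def candidate_edges(combined: OmicsMatrix, cfg: InferenceConfig) -> CandidateEdgeSet:
    """Test every metabolite x transcript and metabolite x metabolite pair;
    retain pairs with p <= ``cfg.p_threshold`` and at least ``cfg.min_pairs``
    complete observations."""
    metab = combined.metabolites()
    expr = combined.transcripts()
    if metab.n_features == 0:
        raise ValueError("combined matrix contains no metabolite rows")
    if expr.n_features == 0:
        log.warning("combined matrix contains no transcript rows; empty candidate set")
    X = metab.values.to_numpy(dtype=float)
    Y = expr.values.to_numpy(dtype=float)
    mids = np.asarray(metab.feature_ids)
    tids = np.asarray(expr.feature_ids)

    n_tested = 0
    if len(tids):
        R, P, N = pairwise_pearson(X, Y, min_pairs=cfg.min_pairs)
        n_tested += R.size
        keep = np.isfinite(P) & (P <= cfg.p_threshold) & (N >= cfg.min_pairs) & (R != 0)
        i, j = np.nonzero(keep)
        mt = pd.DataFrame(
            {
                "metabolite": mids[i],
                "transcript": tids[j],
                "r": R[i, j],
                "p": P[i, j],
                "n_pairs": N[i, j],
            }
        )
    else:
        mt = pd.DataFrame(columns=["metabolite", "transcript", "r", "p", "n_pairs"])

    if len(mids) >= 2:
        Rm, Pm, Nm = pairwise_pearson(X, X, min_pairs=cfg.min_pairs)
        iu, ju = np.triu_indices(len(mids), k=1)
        n_tested += len(iu)
        keep = (
            np.isfinite(Pm[iu, ju])
            & (Pm[iu, ju] <= cfg.p_threshold)
            & (Nm[iu, ju] >= cfg.min_pairs)
            & (Rm[iu, ju] != 0)
        )
        a = mids[iu[keep]]
        b = mids[ju[keep]]
        swap = a > b
        lo = np.where(swap, b, a)
        hi = np.where(swap, a, b)
        mm = pd.DataFrame(
            {
                "m1": lo,
                "m2": hi,
                "r": Rm[iu[keep], ju[keep]],
                "p": Pm[iu[keep], ju[keep]],
                "n_pairs": Nm[iu[keep], ju[keep]],
            }
        )
    else:
        mm = pd.DataFrame(columns=["m1", "m2", "r", "p", "n_pairs"])

    if mt.empty:
        log.warning("candidate_edges: no metabolite-transcript pair passed the gate")
    log.info(
        "candidate_edges: tested %d pairs, retained %d metabolite-transcript and %d metabolite-metabolite",
        n_tested, len(mt), len(mm),
    )
    return CandidateEdgeSet(mt=mt.reset_index(drop=True), mm=mm.reset_index(drop=True), n_tested=n_tested)


# ---------------------------------------------------------------------------
# DPI pruning
# ---------------------------------------------------------------------------

def _dpi_removed(mt: pd.DataFrame, mm: pd.DataFrame) -> np.ndarray:
    """Boolean mask over ``mt`` rows flagged as indirect by the DPI rule.

    For every triplet (m1, m2, t) whose three correlations are all present,
    the edge with strictly the lowest |r| is removed if it is a
    metabolite-transcript edge.  Ties keep all edges; flags are computed
    against the full input set in one pass (removals never cascade).
    """
    removed = np.zeros(len(mt), dtype=bool)
    if mt.empty or mm.empty:
        return removed
    e = mt.reset_index(drop=True)
    e = e.assign(_pos=np.arange(len(e)))
    pairs = e.merge(e, on="transcript", suffixes=("_a", "_b"))
    pairs = pairs[pairs["metabolite_a"] < pairs["metabolite_b"]]
    if pairs.empty:
        return removed
    trip = pairs.merge(
        mm[["m1", "m2", "r"]],
        left_on=["metabolite_a", "metabolite_b"],
        right_on=["m1", "m2"],
        how="inner",
    )
    if trip.empty:
        return removed
    aa = trip["r_a"].abs().to_numpy()
    ab = trip["r_b"].abs().to_numpy()
    am = trip["r"].abs().to_numpy()
    rem_a = (aa < ab) & (aa < am)
    rem_b = (ab < aa) & (ab < am)
    removed[trip.loc[rem_a, "_pos_a"].to_numpy()] = True
    removed[trip.loc[rem_b, "_pos_b"].to_numpy()] = True
    return removed


def dpi_prune(cands: CandidateEdgeSet) -> CandidateEdgeSet:
    """Flag indirect metabolite-transcript candidates via the DPI rule;
    returns a copy whose ``mt`` table carries a ``dpi_survivor`` column."""
    flags = _dpi_removed(cands.mt, cands.mm)
    mt = cands.mt.copy()
    mt["dpi_survivor"] = ~flags
    log.info("dpi_prune: flagged %d of %d candidate edges as indirect", int(flags.sum()), len(mt))
    return CandidateEdgeSet(mt=mt, mm=cands.mm, n_tested=cands.n_tested)


# ---------------------------------------------------------------------------
# Bootstrap likelihood
# ---------------------------------------------------------------------------

def bootstrap_likelihood(
    combined: OmicsMatrix, cands: CandidateEdgeSet, cfg: InferenceConfig
) -> np.ndarray:
    """Support count k per metabolite-transcript candidate over
    ``cfg.n_bootstraps`` resamples of the samples (with replacement, full
    size).  An edge is supported in a bootstrap iff its per-bootstrap p
    passes the gate *and* it survives DPI recomputed within that bootstrap;
    pairs that become constant in a resample count as unsupported.
    Deterministic given ``cfg.seed``.
    """
    mt = cands.mt
    k = np.zeros(len(mt), dtype=int)
    if mt.empty:
        return k
    metab = combined.metabolites()
    tids_needed = list(dict.fromkeys(mt["transcript"]))
    expr = combined.transcripts().subset(features=tids_needed)
    X = metab.values.to_numpy(dtype=float)
    Y = expr.values.to_numpy(dtype=float)
    n = X.shape[1]
    m_index = {m: i for i, m in enumerate(metab.feature_ids)}
    t_index = {t: i for i, t in enumerate(expr.feature_ids)}
    mi = mt["metabolite"].map(m_index).to_numpy()
    ti = mt["transcript"].map(t_index).to_numpy()
    mm = cands.mm
    if len(mm):
        ai = mm["m1"].map(m_index).to_numpy()
        bi = mm["m2"].map(m_index).to_numpy()

    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_bootstraps):
        idx = rng.integers(0, n, size=n)
        Rb, Pb, _ = pairwise_pearson(X[:, idx], Y[:, idx], min_pairs=cfg.min_pairs)
        r_b = Rb[mi, ti]
        p_b = Pb[mi, ti]
        passed = np.isfinite(p_b) & (p_b <= cfg.p_threshold)
        if len(mm):
            Rm, Pm, _ = pairwise_pearson(X[:, idx], X[:, idx], min_pairs=cfg.min_pairs)
            pm_b = Pm[ai, bi]
            mm_pass = np.isfinite(pm_b) & (pm_b <= cfg.p_threshold)
            mm_b = mm.loc[mm_pass, ["m1", "m2"]].assign(r=Rm[ai, bi][mm_pass])
        else:
            mm_b = mm
        mt_b = mt.loc[passed, ["metabolite", "transcript"]].assign(r=r_b[passed])
        flags = _dpi_removed(mt_b, mm_b)
        supported = passed.copy()
        supported[np.flatnonzero(passed)[flags]] = False
        k += supported
    return k


# ---------------------------------------------------------------------------
# Full inference
# ---------------------------------------------------------------------------

def infer_network(
    combined: OmicsMatrix, cfg: InferenceConfig, source: str = ""
) -> MetaboliteNetwork:
    """Run the full inference: gate -> DPI -> bootstrap -> assemble network.

    Final edges are candidates that survive the full-data DPI or are
    supported in at least one bootstrap.  ``likelihood = k / B``, floored at
    1/B for a full-data survivor with zero bootstrap support so every stored
    edge keeps positive weight in downstream enrichment.
    """
    cands = dpi_prune(candidate_edges(combined, cfg))
    k = bootstrap_likelihood(combined, cands, cfg)
    surv = cands.mt["dpi_survivor"].to_numpy() if len(cands.mt) else np.zeros(0, bool)
    keep = surv | (k >= 1)
    k_eff = np.where(surv & (k == 0), 1, k)
    lik = k_eff / cfg.n_bootstraps
    edges = cands.mt.loc[keep, ["metabolite", "transcript", "r", "p"]].copy()
    edges["likelihood"] = lik[keep]
    edges["dpi_survivor"] = surv[keep]
    n_removed = int((~surv).sum())
    n_recovered = int(((~surv) & (k >= 1)).sum())
    log.info(
        "infer_network: %d candidates, %d DPI-removed, %d recovered by bootstrap, %d final edges",
        len(cands.mt), n_removed, n_recovered, int(keep.sum()),
    )
    meta = {
        "p_threshold": cfg.p_threshold,
        "n_bootstraps": cfg.n_bootstraps,
        "min_pairs": cfg.min_pairs,
        "seed": cfg.seed,
        "n_samples": combined.n_samples,
        "source": source,
        "n_pairs_tested": cands.n_tested,
        "n_candidates": len(cands.mt),
        "n_dpi_removed": n_removed,
        "n_recovered": n_recovered,
    }
    return MetaboliteNetwork(edges=edges.reset_index(drop=True), meta=meta)
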