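"""Feature-by-sample omics matrices: container, TSV I/O, combination, and
row standardization.

The whole pipeline works on one fixed orientation — features in rows,
samples in columns — and never transposes silently: an input supplied the
wrong way round is the caller's problem.  Metabolite abundances are expected
in scaled arbitrary units and expression values on a variance-stabilized /
log scale; no normalization is applied here.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

METABOLITE = "metabolite"
TRANSCRIPT = "transcript"

_KEY_RE = re.compile(r"[\s_]+")


@dataclasses.dataclass
class OmicsMatrix:
    """Numeric features x samples matrix with a per-feature kind tag.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns = sample ids.  Missing
        measurements are carried as NaN; everything else must be finite.
    kinds
        Series aligned to ``values.index`` with one of ``"metabolite"`` /
        ``"transcript"`` per feature.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        idx = pd.Index([str(f).strip() for f in self.values.index], name=self.values.index.name)
        cols = pd.Index([str(s).strip() for s in self.values.columns])
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.values = self.values.copy()
        self.values.index = idx
        self.values.columns = cols
        self.kinds = pd.Series(np.asarray(self.kinds), index=idx)
        bad_kind = set(self.kinds.unique()) - {METABOLITE, TRANSCRIPT}
        if bad_kind:
            raise ValueError(f"unknown feature kind(s): {sorted(bad_kind)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("matrix values must be numeric")
        if np.isinf(arr).any():
            raise ValueError("matrix contains non-finite (infinite) values")

    # -- basic accessors ----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, values: pd.DataFrame, kind: str) -> "OmicsMatrix":
        """Wrap a DataFrame whose rows are all of one feature kind."""
        kinds = pd.Series([kind] * len(values.index), index=values.index)
        return cls(values=values, kinds=kinds)

    def subset(
        self,
        features: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "OmicsMatrix":
        v = self.values
        if features is not None:
            v = v.loc[list(features)]
        if samples is not None:
            v = v[list(samples)]
        return OmicsMatrix(values=v, kinds=self.kinds.loc[v.index])

    def metabolites(self) -> "OmicsMatrix":
        return self.subset(features=self.values.index[self.kinds == METABOLITE])

    def transcripts(self) -> "OmicsMatrix":
        return self.subset(features=self.values.index[self.kinds == TRANSCRIPT])

    def __eq__(self, other: object) -> bool:  # value equality, NaN == NaN
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and bool((self.kinds == other.kinds).all())
            and np.array_equal(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_omics_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a features x samples TSV (first column = feature id, header =
    sample ids, cells numeric or the token ``NA``).

    Raises
    ------
    ValueError
        On duplicate feature ids (naming the offender), non-numeric cells
        (naming row/column), or fewer than 2 sample columns.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.map(lambda s: str(s).strip())
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 sample columns, found {raw.shape[1]}")
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature id {dup[0]!r}")
    probe = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = probe.isna().to_numpy() & (raw.to_numpy() != "NA")
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    # numpy's float parser is round-trip exact for %.17g output
    numeric = pd.DataFrame(
        raw.replace("NA", "nan").to_numpy().astype(np.float64),
        index=raw.index, columns=raw.columns,
    )
    m = OmicsMatrix.from_frame(numeric, kind=kind)
    log.info(
        "read %s: %d features x %d samples (%d missing cells)",
        path, m.n_features, m.n_samples, int(numeric.isna().to_numpy().sum()),
    )
    return m


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; missing values serialized as ``NA``."""
    m.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g", index_label="feature")


# ---------------------------------------------------------------------------
# Combination and harmonization
# ---------------------------------------------------------------------------

def combine_matrices(metab: OmicsMatrix, expr: OmicsMatrix) -> OmicsMatrix:
    """Stack a metabolite and a transcript matrix over their shared samples.

    Sample order follows the metabolite matrix; metabolite rows come first.
    """
    if metab.n_features == 0 or expr.n_features == 0:
        raise ValueError("both input matrices must be non-empty")
    clash = set(metab.feature_ids) & set(expr.feature_ids)
    if clash:
        raise ValueError(f"feature id(s) present in both inputs: {sorted(clash)[:5]}")
    shared = [s for s in metab.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise ValueError("no shared sample ids between the two matrices")
    log.info("combine_matrices: %d shared samples", len(shared))
    values = pd.concat([metab.values[shared], expr.values[shared]], axis=0)
    kinds = pd.concat([metab.kinds, expr.kinds])
    return OmicsMatrix(values=values, kinds=kinds)


@dataclasses.dataclass
class Harmonization:
    """Result of exact (case/whitespace/underscore-insensitive) id matching."""

    matches: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self.matches)

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def _norm_key(s: str) -> str:
    return _KEY_RE.sub("", str(s).strip()).casefold()


def harmonize_feature_names(a: Iterable[str], b: Iterable[str]) -> Harmonization:
    """Match two id lists exactly after trimming, lowercasing, and removal of
    whitespace/underscores.  No fuzzy matching: metabolite naming is not
    standardized across platforms and approximate matching would fabricate
    overlap.  Empty overlap is a valid outcome.
    """
    a = list(a)
    b = list(b)
    key_b: dict[str, str] = {}
    for ident in b:
        k = _norm_key(ident)
        if k in key_b:
            log.warning("harmonize: %r collides with %r after normalization", ident, key_b[k])
            continue
        key_b[k] = ident
    matches: list[tuple[str, str]] = []
    unmatched_a: list[str] = []
    seen_b: set[str] = set()
    for ident in a:
        k = _norm_key(ident)
        if k in key_b and key_b[k] not in seen_b:
            matches.append((ident, key_b[k]))
            seen_b.add(key_b[k])
        else:
            unmatched_a.append(ident)
    unmatched_b = [x for x in b if x not in seen_b]
    log.info(
        "harmonize: %d matched, %d unmatched left, %d unmatched right",
        len(matches), len(unmatched_a), len(unmatched_b),
    )
    return Harmonization(matches=matches, unmatched_a=unmatched_a, unmatched_b=unmatched_b)


# ---------------------------------------------------------------------------
# Row standardization
# ---------------------------------------------------------------------------

def zscore_rows(m: OmicsMatrix) -> OmicsMatrix:
    """Standardize each row to mean 0, sd 1 (n-1 divisor), NaN-aware.

    Zero-variance rows are dropped (and logged); an all-constant matrix is a
    hard error.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(arr, axis=1, keepdims=True)
        sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    ok = np.isfinite(sd[:, 0]) & (sd[:, 0] > 0)
    if not ok.any():
        raise ValueError("every row has zero variance; nothing to standardize")
    dropped = m.values.index[~ok]
    if len(dropped):
        log.info("zscore_rows: dropped %d zero-variance rows (e.g. %s)", len(dropped), dropped[0])
    z = (arr[ok] - mu[ok]) / sd[ok]
    values = pd.DataFrame(z, index=m.values.index[ok], columns=m.values.columns)
    return OmicsMatrix(values=values, kinds=m.kinds.loc[values.index])
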