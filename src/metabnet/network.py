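"""Metabolite-hub network container and its on-disk edge-table format.

A network is strictly bipartite-hubbed: every edge links one metabolite
(the hub, or "centroid") to one transcript, carrying the full-data Pearson
correlation ``r``, its p-value ``p``, the bootstrap likelihood ``likelihood``
(fraction of bootstrap resamples supporting the edge), and whether the edge
survived the data-processing-inequality prune on the full data.

Serialization is a 6-column TSV plus a JSON metadata sidecar
(``<path>.meta.json``) holding the inference parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["metabolite", "transcript", "r", "p", "likelihood", "dpi_survivor"]


@dataclasses.dataclass
class Edge:
    metabolite: str
    transcript: str
    r: float
    p: float
    likelihood: float
    dpi_survivor: bool


@dataclasses.dataclass
class MetaboliteNetwork:
    """Edge table (one row per metabolite-transcript link) plus metadata."""

    edges: pd.DataFrame
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing column(s): {missing}")
        self.edges = self.edges[EDGE_COLUMNS].reset_index(drop=True)
        _validate_edges(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(dict.fromkeys(self.edges["metabolite"]))

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(set(self.edges["transcript"]))

    def regulon(self, metabolite: str) -> pd.DataFrame:
        """All edges of one metabolite hub (its transcript neighborhood)."""
        return self.edges[self.edges["metabolite"] == metabolite]

    def degree(self) -> pd.Series:
        """Edges per metabolite hub."""
        return self.edges.groupby("metabolite").size()

    def equals(self, other: "MetaboliteNetwork") -> bool:
        return self.edges.equals(other.edges)


def _validate_edges(edges: pd.DataFrame) -> None:
    if edges.empty:
        return
    r = edges["r"].to_numpy(dtype=float)
    p = edges["p"].to_numpy(dtype=float)
    lik = edges["likelihood"].to_numpy(dtype=float)
    if np.any(np.abs(r) > 1) or np.any(~np.isfinite(r)):
        raise ValueError("edge r outside [-1, 1]")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("edge p outside [0, 1]")
    if np.any((lik <= 0) | (lik > 1) | ~np.isfinite(lik)):
        raise ValueError("edge likelihood outside (0, 1]")
    dup = edges.duplicated(subset=["metabolite", "transcript"])
    if dup.any():
        row = edges[dup].iloc[0]
        raise ValueError(
            f"duplicate edge ({row['metabolite']!r}, {row['transcript']!r})"
        )


def _meta_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_network(net: MetaboliteNetwork, path: str | Path) -> None:
    """Write the edge TSV (floats at 17 significant digits, lossless for
    float64) and the JSON metadata sidecar."""
    out = net.edges.copy()
    out["dpi_survivor"] = out["dpi_survivor"].map({True: "True", False: "False"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    with open(_meta_path(path), "w") as fh:
        json.dump(net.meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote network with %d edges to %s", net.n_edges, path)


def read_network(path: str | Path) -> MetaboliteNetwork:
    """Read an edge TSV written by :func:`write_network`.

    Malformed files (missing column, out-of-range values) are hard errors.
    """
    edges = pd.read_csv(
        path, sep="\t", dtype={"metabolite": str, "transcript": str},
        float_precision="round_trip",
    )
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(edges):
        flags = edges["dpi_survivor"].map(
            {"True": True, "False": False, True: True, False: False}
        )
        if flags.isna().any():
            raise ValueError(f"{path}: non-boolean dpi_survivor value")
        edges["dpi_survivor"] = flags.astype(bool)
    else:
        edges["dpi_survivor"] = edges["dpi_survivor"].astype(bool)
    meta: dict[str, Any] = {}
    mp = _meta_path(path)
    if mp.exists():
        with open(mp) as fh:
            meta = json.load(fh)
    return MetaboliteNetwork(edges=edges, meta=meta)
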