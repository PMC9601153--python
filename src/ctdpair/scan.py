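"""Proposer/tester scoring workflow and the synthetic parameter scan.

``score_pair`` is the end-to-end pipeline for one graph pair: take absolute
weights, harmonize the label sets if asked, encode the module in the proposer
and in the tester, and combine the encodings into the weighted-Bonferroni
p-value bound.  The bound is asymmetric by construction — the null length uses
the tester's node count only — so swapping the roles of two different graphs
generally changes the result.

``run_scan`` sweeps a grid of generator parameters with seeded replicates,
skipping cells whose module is below the closed-form detectability floor
(no module that small can reach p <= 0.05, so there is nothing to measure).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .encoder import encode_module
from .graphs import (
    GraphError,
    NodeModule,
    absolute_weights,
    harmonize_by_isolation,
    harmonize_by_removal,
)
from .significance import SignificanceResult, min_module_size, pair_bound
from .synthetic import GenParams, generate_pair, measure_contrast

__all__ = ["ScanRecord", "score_pair", "run_scan", "summarize_scan", "records_frame"]

SIGNIFICANCE_THRESHOLD = 0.05
_SEED_MOD = 2**31


@dataclass(frozen=True)
class ScanRecord:
    """One generator cell x replicate with its significance outcome."""

    params: GenParams
    replicate_seed: int
    realized_contrast: Optional[float]
    log2_p_bound: Optional[float]
    significant: Optional[bool]
    skipped: bool = False


def score_pair(
    G1: nx.Graph,
    G2: nx.Graph,
    S: NodeModule,
    harmonization: str = "none",
) -> SignificanceResult:
    """Bound the p-value of module S shared by proposer G1 and tester G2.

    Weights are replaced by their absolute values first.  ``harmonization``
    is one of 'removal' (drop module nodes missing from the tester, from both
    the module and the proposer), 'isolation' (extend both graphs to the
    union label set with isolated nodes), or 'none' (require S to be present
    in both graphs as given).
    """
    G1 = absolute_weights(G1)
    G2 = absolute_weights(G2)
    if harmonization == "removal":
        G1, S = harmonize_by_removal(G1, G2, S)
    elif harmonization == "isolation":
        G1, G2 = harmonize_by_isolation(G1, G2)
    elif harmonization == "none":
        missing = sorted(S.label_set - (set(G1.nodes) & set(G2.nodes)))
        if missing:
            raise GraphError(
                f"module labels {missing[:5]} missing from one of the graphs; "
                "pass harmonization='removal' or 'isolation'"
            )
    else:
        raise ValueError("harmonization must be 'removal', 'isolation' or 'none'")
    enc1 = encode_module(G1, S)
    enc2 = encode_module(G2, S)
    return pair_bound(enc1, enc2)


def _cell_seed(base_seed: int, params_wo_seed: tuple, replicate: int) -> int:
    """Stable replicate seed: base + CRC32 of the cell + replicate index."""
    digest = zlib.crc32(repr(params_wo_seed).encode())
    return (base_seed + digest + replicate) % _SEED_MOD


def run_scan(
    grid: dict[str, Sequence],
    replicates: int = 20,
    base_seed: int = 0,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[ScanRecord]:
    """Cartesian sweep of generator axes with seeded replicates per cell.

    ``grid`` maps axis names (n_nodes, avg_degree, module_fraction, contrast,
    pattern) to value lists.  Cells whose module size falls below the
    detectability floor min_module_size(n, threshold) are marked skipped
    without generating anything.  Records are deterministic given
    ``base_seed`` and independent of execution order.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    axes = ("n_nodes", "avg_degree", "module_fraction", "contrast", "pattern")
    unknown = set(grid) - set(axes)
    if unknown:
        raise ValueError(f"unknown grid axes: {sorted(unknown)}")
    missing = [a for a in axes if a not in grid or not grid[a]]
    if missing:
        raise ValueError(f"grid missing axes: {missing}")

    records: list[ScanRecord] = []
    for cell in itertools.product(*(grid[a] for a in axes)):
        n, deg, frac, contrast, pattern = cell
        module_size = round(frac * n)
        for rep in range(replicates):
            seed = _cell_seed(base_seed, cell, rep)
            params = GenParams(
                n_nodes=n,
                avg_degree=deg,
                module_fraction=frac,
                contrast=contrast,
                pattern=pattern,
                seed=seed,
            )
            if min_module_size(n, threshold) > module_size:
                records.append(
                    ScanRecord(
                        params=params,
                        replicate_seed=seed,
                        realized_contrast=None,
                        log2_p_bound=None,
                        significant=None,
                        skipped=True,
                    )
                )
                continue
            G1, G2, S = generate_pair(params)
            result = score_pair(G1, G2, S, harmonization="none")
            records.append(
                ScanRecord(
                    params=params,
                    replicate_seed=seed,
                    realized_contrast=measure_contrast(G2, S.planted_edges),
                    log2_p_bound=result.log2_p_bound,
                    significant=result.p_bound < threshold,
                    skipped=False,
                )
            )
    return records


def records_frame(records: Iterable[ScanRecord]) -> pd.DataFrame:
    """Flatten scan records into a DataFrame (one row per replicate)."""
    rows = []
    for r in records:
        rows.append(
            {
                "n_nodes": r.params.n_nodes,
                "avg_degree": r.params.avg_degree,
                "module_fraction": r.params.module_fraction,
                "contrast": r.params.contrast,
                "pattern": r.params.pattern,
                "replicate_seed": r.replicate_seed,
                "realized_contrast": r.realized_contrast,
                "log2_p_bound": r.log2_p_bound,
                "significant": r.significant,
                "skipped": r.skipped,
            }
        )
    return pd.DataFrame(rows)


def summarize_scan(records: Iterable[ScanRecord]) -> pd.DataFrame:
    """Per-cell summary: replicate count, significant fraction, median bound.

    Skipped cells appear with NaN fraction and median (not-applicable).
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    keys = ["n_nodes", "avg_degree", "module_fraction", "contrast", "pattern"]

    def _one(group: pd.DataFrame) -> pd.Series:
        if group["skipped"].all():
            return pd.Series(
                {
                    "replicates": len(group),
                    "significant_fraction": float("nan"),
                    "median_log2_p_bound": float("nan"),
                    "skipped": True,
                }
            )
        live = group[~group["skipped"]]
        return pd.Series(
            {
                "replicates": len(live),
                "significant_fraction": float(live["significant"].mean()),
                "median_log2_p_bound": float(live["log2_p_bound"].median()),
                "skipped": False,
            }
        )

    out = df.groupby(keys, sort=True).apply(_one, include_groups=False).reset_index()
    out["replicates"] = out["replicates"].astype(int)
    out["skipped"] = out["skipped"].astype(bool)
    return out
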