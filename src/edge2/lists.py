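"""Priority-list construction from per-species summaries.

A species qualifies for the EDGE List when it is threatened (VU, EN, CR) or
Extinct in the Wild and its EDGE2 score exceeds the across-species median in
at least 95% of iterations.  Threatened/EW species that clear 80% but not
95% are borderline.  DD/NE species clearing 95% form the Research List
(they would become EDGE species if assessed VU or above); LC/NT species
clearing 95% form the Watch List (they secure imperilled deep branches).
The five outcomes (including NONE) partition the scored taxa.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .redlist import protocol_constants
from .trees import THREATENED

__all__ = ["LIST_NAMES", "classify", "emit_lists"]

LIST_NAMES = ("EDGE", "BORDERLINE", "RESEARCH", "WATCH", "NONE")

_PRIORITY_ELIGIBLE = set(THREATENED) | {"EW"}


def classify(
    summary: pd.DataFrame,
    priority_threshold: float = 0.95,
    borderline_threshold: float = 0.80,
) -> pd.DataFrame:
    """Assign every summarised taxon to exactly one list.

    ``summary`` is the output of :func:`edge2.pipeline.summarise` (needs
    ``category`` and ``above_median_fraction`` columns).  Returns the summary
    with an added ``list`` column plus rank columns: ``rank_overall`` (within
    all scored taxa, by median EDGE2 descending, ties by label) and
    ``rank_in_list``.
    """
    if not 0 < borderline_threshold < priority_threshold <= 1:
        raise ValueError("need 0 < borderline < priority <= 1")
    for col in ("category", "above_median_fraction", "median_edge2"):
        if col not in summary.columns:
            raise ValueError(f"summary is missing required column {col!r}")
    out = summary.copy()
    frac = out["above_median_fraction"]
    cat = out["category"]
    eligible = cat.isin(sorted(_PRIORITY_ELIGIBLE))
    certain = frac >= priority_threshold
    borderline = (frac >= borderline_threshold) & ~certain
    assignment = pd.Series("NONE", index=out.index, dtype=object)
    assignment[eligible & certain] = "EDGE"
    assignment[eligible & borderline] = "BORDERLINE"
    assignment[cat.isin(["DD", "NE"]) & certain] = "RESEARCH"
    assignment[cat.isin(["LC", "NT"]) & certain] = "WATCH"
    out["list"] = assignment
    # deterministic rank: score desc, label asc
    ranked = (
        out.reset_index()
        .sort_values(["median_edge2", "taxon"], ascending=[False, True])
        .set_index("taxon")
    )
    ranked["rank_overall"] = range(1, len(ranked) + 1)
    out["rank_overall"] = ranked["rank_overall"]
    out["rank_in_list"] = (
        ranked.groupby("list", sort=False).cumcount().add(1)
    )
    return out


def emit_lists(
    assignments: pd.DataFrame,
    out_dir: str | Path,
    *,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the four priority lists, the combined assignment table and metadata.

    Each list CSV is sorted by median EDGE2 descending (ties by taxon label);
    empty lists still produce a file with a header.  Returns the paths
    written, keyed by list name plus ``"assignments"`` and ``"metadata"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = assignments.reset_index().sort_values(
        ["median_edge2", "taxon"], ascending=[False, True]
    )
    paths: dict[str, Path] = {}
    names = {
        "EDGE": "edge_list.csv",
        "BORDERLINE": "borderline_list.csv",
        "RESEARCH": "research_list.csv",
        "WATCH": "watch_list.csv",
    }
    for list_name, fname in names.items():
        sub = ordered[ordered["list"] == list_name]
        path = out_dir / fname
        sub.to_csv(path, index=False)
        paths[list_name] = path
    all_path = out_dir / "assignments.csv"
    ordered.to_csv(all_path, index=False)
    paths["assignments"] = all_path
    meta = {
        "protocol_constants_version": protocol_constants()["version"],
        "list_counts": {
            name: int((assignments["list"] == name).sum()) for name in LIST_NAMES
        },
    }
    if metadata:
        meta.update(metadata)
    meta_path = out_dir / "lists_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["metadata"] = meta_path
    return paths
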