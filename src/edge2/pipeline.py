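"""Monte-Carlo orchestration over (tree, extinction-probability draw) pairs.

Each iteration pairs one tree from the distribution (cycled in order, so a
posterior sample is covered evenly) with one fresh probability draw per
taxon.  The same drawn p serves both as the species' GE2 and as the p_k
inside its relatives' ED2 products, so every iteration is one coherent
realisation of the future.  Per-species distributions are then summarised by
medians and interquartile ranges, and by the protocol's certainty measure:
the fraction of iterations in which the species' EDGE2 strictly exceeds that
iteration's across-species median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .redlist import GE2Curve, ge1_weight
from .scores import ed2_scores, edge1_score, edge2_score, fair_proportion_ed1
from .trees import DATA_SUFFICIENT, AssessmentTable, TreeSet

__all__ = ["RunConfig", "IterationStore", "run_iterations", "summarise"]

#: iteration band stated by the protocol
PROTOCOL_MIN_ITER = 100
PROTOCOL_MAX_ITER = 1000


@dataclass(frozen=True)
class RunConfig:
    """Run parameters for the uncertainty pipeline.

    ``n_iterations`` must satisfy 100 < n <= 1000 (the protocol band) unless
    ``override_protocol`` is set.  ``priority_threshold`` and
    ``borderline_threshold`` are the above-median certainty levels for the
    EDGE and borderline lists.  ``tree_policy`` is ``"cycle"`` (deterministic,
    default) or ``"sample"`` (with replacement).  ``couple_draws=False``
    draws GE2 separately from the p used inside relatives' ED2 products,
    for future GE2 != p extensions.
    """

    n_iterations: int = 1000
    seed: int = 0
    priority_threshold: float = 0.95
    borderline_threshold: float = 0.80
    tree_policy: str = "cycle"
    override_protocol: bool = False
    couple_draws: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.borderline_threshold < self.priority_threshold < 1):
            raise ValueError(
                "thresholds must satisfy 0 < borderline < priority < 1"
            )
        if self.tree_policy not in ("cycle", "sample"):
            raise ValueError(f"unknown tree policy {self.tree_policy!r}")
        if not self.override_protocol and not (
            PROTOCOL_MIN_ITER < self.n_iterations <= PROTOCOL_MAX_ITER
        ):
            raise ValueError(
                f"n_iterations={self.n_iterations} is outside the protocol "
                f"band {PROTOCOL_MIN_ITER} < n <= {PROTOCOL_MAX_ITER}; pass "
                "override_protocol=True to run anyway"
            )


@dataclass
class IterationStore:
    """Long-format per-draw scores plus per-iteration across-species medians."""

    draws: pd.DataFrame  # one row per (iteration, taxon)
    iteration_medians: np.ndarray  # median EDGE2 over scored taxa, per iteration
    config: RunConfig
    n_trees: int
    categories: dict[str, str] = field(default_factory=dict)
    tags: dict[str, frozenset] = field(default_factory=dict)


def run_iterations(
    trees: TreeSet,
    table: AssessmentTable,
    curve: GE2Curve,
    config: RunConfig,
) -> IterationStore:
    """Score every taxon across ``config.n_iterations`` (tree, draw) pairs.

    Trees are cycled in input order (iteration t uses tree t mod n_trees)
    unless ``tree_policy="sample"``.  Per iteration, one p is drawn per
    extant taxon on the current tree; EX tips stay on the tree with p pinned
    at the upper clip bound but receive no scores.  Reproducible bit-for-bit
    for a given (inputs, config) pair: iteration t uses the spawned child
    stream t of the seed.
    """
    n_iter = config.n_iterations
    n_trees = len(trees)
    root_ss = np.random.SeedSequence(config.seed)
    streams = root_ss.spawn(n_iter + 1)
    tree_picker = np.random.default_rng(streams[n_iter])

    categories = {
        t: table.category(t, default="NE") for t in trees.taxon_universe
    }
    scored_taxa = [t for t in trees.taxon_universe if categories[t] != "EX"]
    extinct = [t for t in trees.taxon_universe if categories[t] == "EX"]

    # ED1/TBL depend only on the tree: compute once per distinct tree
    ed1_cache: list[dict[str, float] | None] = [None] * n_trees
    tbl_cache: list[dict[str, float] | None] = [None] * n_trees

    records: list[tuple] = []
    iter_medians = np.empty(n_iter)
    for t_iter in range(n_iter):
        if config.tree_policy == "cycle":
            tree_idx = t_iter % n_trees
        else:
            tree_idx = int(tree_picker.integers(n_trees))
        tree = trees[tree_idx]
        if ed1_cache[tree_idx] is None:
            ed1_cache[tree_idx] = fair_proportion_ed1(tree)
            tbl_cache[tree_idx] = tree.terminal_branch_lengths()
        ed1 = ed1_cache[tree_idx]
        tbl = tbl_cache[tree_idx]

        rng = np.random.default_rng(streams[t_iter])
        present = [t for t in scored_taxa if t in tree._tip_index]
        p_draw: dict[str, float] = {}
        ge2_draw: dict[str, float] = {}
        for taxon in present:
            p = curve.sample(categories[taxon], rng)
            p_draw[taxon] = p
            ge2_draw[taxon] = p
        if not config.couple_draws:
            for taxon in present:
                ge2_draw[taxon] = curve.sample(categories[taxon], rng)
        for taxon in extinct:
            if taxon in tree._tip_index:
                p_draw[taxon] = curve.clip_upper

        ed2 = ed2_scores(tree, p_draw)
        edge2_vals = np.empty(len(present))
        for j, taxon in enumerate(present):
            cat = categories[taxon]
            e2, share = ed2[taxon]
            ge2 = ge2_draw[taxon]
            s_edge2 = edge2_score(e2, ge2)
            edge2_vals[j] = s_edge2
            if cat in DATA_SUFFICIENT:
                ge1 = ge1_weight(cat)
                s_edge1 = edge1_score(ed1[taxon], ge1)
            else:
                ge1 = np.nan
                s_edge1 = np.nan
            records.append(
                (
                    t_iter,
                    tree_idx,
                    taxon,
                    cat,
                    tbl[taxon],
                    ed1[taxon],
                    ge1,
                    s_edge1,
                    e2,
                    share,
                    ge2,
                    s_edge2,
                )
            )
        iter_medians[t_iter] = np.median(edge2_vals)

    draws = pd.DataFrame.from_records(
        records,
        columns=[
            "iteration",
            "tree_index",
            "taxon",
            "category",
            "tbl",
            "ed1",
            "ge1",
            "edge1",
            "ed2",
            "terminal_share",
            "ge2",
            "edge2",
        ],
    )
    return IterationStore(
        draws=draws,
        iteration_medians=iter_medians,
        config=config,
        n_trees=n_trees,
        categories=categories,
        tags={t: table.tags_for(t) for t in trees.taxon_universe},
    )


def summarise(store: IterationStore) -> pd.DataFrame:
    """Per-species medians, IQRs and the above-median certainty fraction.

    Taxa absent from some trees are summarised over the iterations in which
    they are present; ``presence_count`` reports how many.  The across-species
    median of each iteration is computed over all taxa scored in that
    iteration (every category including DD/NE, since draws exist for all).
    """
    draws = store.draws
    if draws.empty:
        raise ValueError("iteration store is empty")
    med = store.iteration_medians[draws["iteration"].to_numpy()]
    above = draws["edge2"].to_numpy() > med
    work = draws.assign(above_median=above)

    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    g = work.groupby("taxon", sort=True)
    summary = pd.DataFrame(
        {
            "category": g["category"].first(),
            "median_tbl": g["tbl"].median(),
            "median_ed1": g["ed1"].median(),
            "median_ed2": g["ed2"].median(),
            "iqr_ed2": g["ed2"].agg(iqr),
            "median_terminal_share": g["terminal_share"].median(),
            "median_ge2": g["ge2"].median(),
            "iqr_ge2": g["ge2"].agg(iqr),
            "median_edge2": g["edge2"].median(),
            "iqr_edge2": g["edge2"].agg(iqr),
            "above_median_fraction": g["above_median"].mean(),
            "presence_count": g.size(),
        }
    )
    summary["tags"] = [
        ";".join(sorted(store.tags.get(t, frozenset()))) for t in summary.index
    ]
    never = [
        t
        for t, c in store.categories.items()
        if c != "EX" and t not in summary.index
    ]
    if never:
        warnings.warn(
            f"taxa present in zero iterations excluded from summary: {never}",
            stacklevel=2,
        )
    summary.index.name = "taxon"
    return summary
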