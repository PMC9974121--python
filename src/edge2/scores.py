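"""Per-tree, per-draw scoring: ED1, EDGE1, ED2, EDGE2, expected PD loss.

Fair-proportion evolutionary distinctiveness (ED1) divides every branch
equally among its descendant tips, so the per-tip scores always sum to the
tree's total phylogenetic diversity.  ED2 is the expected unique PD of a
tip: its terminal branch plus every ancestral branch weighted by the
probability that all co-descendants of that branch go extinct,

    ED2_i = TBL_i + sum_j  L_{i,j} * prod_{k in C_{i,j} - {i}} p_k ,

where the sum runs over the internal branches on the tip's path to the
root.  Traversal always continues to the root of the supplied tree: one
postorder pass accumulates per-branch descendant products in log space, so
deep branches with many secure descendants contribute (correctly) almost
nothing and no truncation is needed.  EDGE2 = ED2 x GE2; EDGE1 =
ln(1 + ED1) + GE ln 2.

``ed2_oracle`` is an intentionally independent check: it enumerates all
survive/perish outcomes of the other tips and averages the realised unique
path length.  It shares no arithmetic with ``ed2_scores`` beyond the tree
itself.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, NamedTuple

import numpy as np

from .trees import PhyloTree

__all__ = [
    "Ed2Score",
    "fair_proportion_ed1",
    "edge1_score",
    "ed2_scores",
    "edge2_score",
    "ed2_oracle",
    "expected_pd_loss",
    "capture_curve",
]


class Ed2Score(NamedTuple):
    ed2: float  # expected unique PD, MY
    terminal_share: float  # fraction of ed2 contributed by the terminal branch


def fair_proportion_ed1(tree: PhyloTree) -> dict[str, float]:
    """Fair-proportion ED: each branch split equally among descendant tips.

    Returns MY per taxon; the values sum to the tree's total PD.
    """
    n = tree.n_nodes
    # per-branch share received by each descendant tip
    share = np.where(tree.n_desc > 0, tree.length / tree.n_desc, 0.0)
    # accumulate down the tree: ed1 of a node = own share + ancestors' shares
    acc = np.zeros(n)
    for v in range(n - 1, -1, -1):  # reverse postorder = parents first
        p = tree.parent[v]
        acc[v] = share[v] + (acc[p] if p >= 0 else 0.0)
    return {t: float(acc[tree.tip_node(t)]) for t in tree.tip_labels}


def edge1_score(ed1: float, ge: int) -> float:
    """Original EDGE score: ln(1 + ED) + GE * ln 2."""
    if ed1 < 0:
        raise ValueError("ED must be non-negative")
    if ge not in (0, 1, 2, 3, 4):
        raise ValueError("GE must be an integer 0..4")
    return math.log1p(ed1) + ge * math.log(2.0)


def ed2_scores(
    tree: PhyloTree, p: Mapping[str, float]
) -> dict[str, Ed2Score]:
    """Expected distinctiveness for every tip under extinction probabilities p.

    ``p`` must cover every tip of the tree — tips whose score is not wanted
    still appear inside other tips' survival products.  Runs in O(tree size)
    per call: one postorder pass accumulates each branch's log product of
    descendant p, then each tip walks its ancestral path.
    """
    n = tree.n_nodes
    logp_tip = np.zeros(n)
    for t in tree.tip_labels:
        if t not in p:
            raise KeyError(f"no extinction probability supplied for tip {t!r}")
        logp_tip[tree.tip_node(t)] = math.log(float(p[t]))
    # postorder: log prod of p over descendant tips of each node
    logprod = np.zeros(n)
    logprod[tree.is_tip] = logp_tip[tree.is_tip]
    for v in range(n):
        pa = tree.parent[v]
        if pa >= 0:
            logprod[pa] += logprod[v]
    out: dict[str, Ed2Score] = {}
    for t in tree.tip_labels:
        tip = tree.tip_node(t)
        tbl = float(tree.length[tip])
        lp_i = logprod[tip]
        ed2 = tbl
        v = int(tree.parent[tip])
        while v >= 0:
            L = float(tree.length[v])
            if L > 0.0:
                ed2 += L * math.exp(logprod[v] - lp_i)
            v = int(tree.parent[v])
        share = tbl / ed2 if ed2 > 0 else 1.0
        out[t] = Ed2Score(ed2=ed2, terminal_share=share)
    return out


def edge2_score(ed2: float, ge2: float) -> float:
    """EDGE2 = ED2 x GE2: avertable expected PD loss, in MY."""
    if ed2 < 0:
        raise ValueError("ED2 must be non-negative")
    if not 0.0 < ge2 < 1.0:
        raise ValueError("GE2 must be a probability strictly between 0 and 1")
    return ed2 * ge2


def ed2_oracle(
    tree: PhyloTree,
    p: Mapping[str, float],
    taxon: str,
    *,
    method: str = "exhaustive",
    n_replicates: int = 100_000,
    rng: np.random.Generator | None = None,
    max_exhaustive_tips: int = 20,
) -> float:
    """Expected unique path length of ``taxon`` by outcome enumeration.

    Enumerates (or, with ``method="mc"``, samples) the survive/perish state
    of every other tip; in each outcome the taxon's unique PD is the length
    of its ancestral path up to the first branch with another surviving
    descendant.  Used as the independent cross-check for ``ed2_scores``.
    """
    others = [t for t in tree.tip_labels if t != taxon]
    path = tree.ancestor_path(taxon)
    tip = path[0]
    # (branch length, co-descendants) per ancestral branch, tip-to-root
    branches: list[tuple[float, frozenset[str]]] = []
    for v in path[1:]:
        co = tree.descendant_tips(v) - {taxon}
        branches.append((float(tree.length[v]), co))
    tbl = float(tree.length[tip])

    if method == "exhaustive":
        if len(others) > max_exhaustive_tips:
            raise ValueError(
                f"{len(others)} other tips would require 2^{len(others)} "
                "outcomes; use method='mc'"
            )
        total = 0.0
        for alive_states in itertools.product((False, True), repeat=len(others)):
            prob = 1.0
            alive = set()
            for t, is_alive in zip(others, alive_states):
                pk = float(p[t])
                prob *= (1.0 - pk) if is_alive else pk
                if is_alive:
                    alive.add(t)
            unique = tbl
            for L, co in branches:
                if alive & co:
                    break
                unique += L
            total += prob * unique
        return total
    if method == "mc":
        if rng is None:
            raise ValueError("Monte-Carlo mode requires an rng")
        pk = np.array([float(p[t]) for t in others])
        draws = rng.random((n_replicates, len(pk))) >= pk  # True = survives
        unique = np.full(n_replicates, tbl)
        blocked = np.zeros(n_replicates, dtype=bool)
        idx = {t: j for j, t in enumerate(others)}
        for L, co in branches:
            cols = [idx[t] for t in co]
            if cols:
                blocked |= draws[:, cols].any(axis=1)
            unique[~blocked] += L
        return float(unique.mean())
    raise ValueError(f"unknown oracle method {method!r}")


def expected_pd_loss(tree: PhyloTree, p: Mapping[str, float]) -> float:
    """Tree-level expected PD loss: sum_b L_b * prod_{k below b} p_k (MY).

    Each branch is lost only if every descendant tip goes extinct.  Note this
    tree-level expectation is not the sum of per-taxon EDGE2 scores, which
    count each shared branch once per descendant.
    """
    n = tree.n_nodes
    logp = np.zeros(n)
    for t in tree.tip_labels:
        if t not in p:
            raise KeyError(f"no extinction probability supplied for tip {t!r}")
        logp[tree.tip_node(t)] = math.log(float(p[t]))
    logprod = np.zeros(n)
    logprod[tree.is_tip] = logp[tree.is_tip]
    for v in range(n):
        pa = tree.parent[v]
        if pa >= 0:
            logprod[pa] += logprod[v]
    return float(np.sum(tree.length * np.exp(logprod)))


def capture_curve(scores: Mapping[str, float], k: int) -> float:
    """Fraction of summed scores captured by the top-k taxa.

    Ties are broken by (score descending, taxon label ascending) so the
    result is deterministic.
    """
    if k < 0 or k > len(scores):
        raise ValueError(f"k={k} outside [0, {len(scores)}]")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(v for _, v in ranked)
    if total == 0:
        return 0.0
    return sum(v for _, v in ranked[:k]) / total
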