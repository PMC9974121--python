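"""Synthetic trees, tree distributions and assessments for testing EDGE2.

The generator emulates the two inputs the protocol consumes: a distribution
of dated phylogenies (here: birth-death simulations with branch-length
jitter and random tip regrafts standing in for imputation uncertainty) and a
Red List assessment table (uniform, frequency-weighted, or phylogenetically
clustered threat, the latter via a sticky Markov copy of categories down the
tree).  Everything is deterministic per seed, with all randomness drawn from
``numpy.random.Generator`` streams.

``worked_fixtures`` builds three micro-configurations whose scoring
behaviour is known qualitatively — a cherry with an outgroup, an
"echidna-like" clade (a long internal branch shared by two highly threatened
tips and one secure close relative, where expected distinctiveness discounts
the shared branch) and a "pangolin-like" genus (one EN tip with three CR
congeners, whose expected distinctiveness exceeds its fair-proportion ED) —
with expected values computed on the spot by the exhaustive oracle, never
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass


import dendropy
import numpy as np

from .redlist import build_ge2_curve
from .scores import ed2_oracle, fair_proportion_ed1
from .trees import DATA_SUFFICIENT, AssessmentTable, PhyloTree, TreeSet

__all__ = [
    "SimConfig",
    "simulate_tree",
    "perturb_tree_set",
    "assign_categories",
    "worked_fixtures",
    "WorkedFixture",
]

#: Red-List-like category frequencies for the frequency-weighted scheme
#: (roughly: half the species secure, a quarter threatened).
DEFAULT_CATEGORY_FREQUENCIES = {
    "LC": 0.50,
    "NT": 0.12,
    "VU": 0.12,
    "EN": 0.08,
    "CR": 0.05,
    "DD": 0.13,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters for tree and assessment simulation.

    Branch lengths are in MY; with the default birth rate of 0.25/MY an
    n-tip pure-birth tree is a few tens of MY deep, comparable to a genus-
    or family-level clade.  ``jitter`` is the log-normal sigma applied
    multiplicatively to branch lengths when perturbing a tree set (0.1 ~
    10% length uncertainty); ``regraft_fraction`` moves that share of tips
    to random new positions per perturbed tree, emulating imputation
    placement uncertainty.
    """

    n_tips: int = 64
    birth_rate: float = 0.25
    death_rate: float = 0.0
    seed: int = 0
    scheme: str = "uniform"
    stickiness: float = 0.8
    n_trees: int = 10
    jitter: float = 0.1
    regraft_fraction: float = 0.1
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("need birth_rate > 0 and death_rate >= 0")
        if not 0 <= self.regraft_fraction < 1:
            raise ValueError("regraft_fraction must be in [0, 1)")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")



def simulate_tree(config: SimConfig) -> PhyloTree:
    """Simulate one rooted birth-death tree with the requested tip count.

    Forward-time Gillespie simulation starting from a single lineage; the
    simulation stops one waiting time after the lineage count first reaches
    ``n_tips`` and extinct lineages are pruned.  If the process dies out it
    is retried (up to ``max_retries``) on a fresh substream.
    """
    for attempt in range(config.max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(attempt,))
        )
        newick = _simulate_newick(config, rng)
        if newick is not None:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="default-rooted"
            )
            return PhyloTree(tree)
    raise RuntimeError(
        f"birth-death process went extinct in all {config.max_retries} attempts"
    )


def _simulate_newick(config: SimConfig, rng: np.random.Generator) -> str | None:
    b, d = config.birth_rate, config.death_rate
    next_id = 0
    parent: dict[int, int] = {}
    birth: dict[int, float] = {0: 0.0}
    death: dict[int, float] = {}
    alive: list[int] = [0]
    next_id = 1
    t = 0.0
    while len(alive) < config.n_tips or config.n_tips == 1:
        if config.n_tips == 1:
            t = rng.exponential(1.0 / b)
            break
        if not alive:
            return None  # extinction
        rate = len(alive) * (b + d)
        t += rng.exponential(1.0 / rate)
        k = int(rng.integers(len(alive)))
        lineage = alive[k]
        if rng.random() < b / (b + d):
            for _ in range(2):
                parent[next_id] = lineage
                birth[next_id] = t
                alive.append(next_id)
                next_id += 1
            death[lineage] = t
            alive.remove(lineage)
        else:
            death[lineage] = t
            alive.remove(lineage)
    if config.n_tips > 1:
        # extend extant tips past the last speciation by one waiting time
        t += rng.exponential(1.0 / (len(alive) * (b + d)))
    present = t
    # build newick recursively from the lineage records
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    labels = {lineage: f"t{i + 1}" for i, lineage in enumerate(sorted(alive))}

    def render(lineage: int) -> str | None:
        end = death.get(lineage, present)
        length = end - birth[lineage]
        kids = children.get(lineage, [])
        if not kids:  # leaf: extant tips only
            if lineage not in labels:
                return None
            return f"{labels[lineage]}:{length:.10g}"
        parts = [s for s in (render(c) for c in kids) if s is not None]
        if not parts:
            return None
        if len(parts) == 1:  # child survived alone; merge branch
            head, blen = parts[0].rsplit(":", 1)
            return f"{head}:{float(blen) + length:.10g}"
        return f"({','.join(parts)}):{length:.10g}"

    rendered = render(0)
    if rendered is None:
        return None
    return rendered + ";"


def perturb_tree_set(tree: PhyloTree, config: SimConfig) -> TreeSet:
    """Emulate a posterior distribution around one tree.

    Produces ``config.n_trees`` copies with (a) every branch length
    multiplied by a log-normal factor exp(jitter * N(0,1)), preserving
    non-negativity, and (b) exactly round(regraft_fraction * n_tips) tips
    detached and re-attached to a uniformly chosen remaining branch at a
    uniform split point, keeping each tip's pendant length.  The taxon
    universe is preserved.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, 0)))
    n_move = int(round(config.regraft_fraction * tree.n_tips))
    out = []
    base_newick = tree.as_newick()
    for _ in range(config.n_trees):
        dt = dendropy.Tree.get(
            data=base_newick, schema="newick", rooting="default-rooted"
        )
        if n_move:
            tips = sorted(
                (lf for lf in dt.leaf_node_iter()), key=lambda nd: nd.taxon.label
            )
            chosen = rng.choice(len(tips), size=n_move, replace=False)
            for idx in sorted(chosen):
                _regraft_tip(dt, tips[idx], rng)
        if config.jitter > 0:
            for edge in dt.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(edge.length) * float(
                        np.exp(config.jitter * rng.standard_normal())
                    )
        out.append(PhyloTree(dt))
    return TreeSet.from_trees(out)


def _regraft_tip(
    dt: dendropy.Tree, leaf: dendropy.Node, rng: np.random.Generator
) -> None:
    pendant = leaf.edge.length or 0.0
    parent = leaf.parent_node
    if parent is None:
        return  # single-tip tree
    parent.remove_child(leaf)
    # collapse the now-unary parent
    siblings = parent.child_nodes()
    if len(siblings) == 1:
        only = siblings[0]
        only.edge.length = (only.edge.length or 0.0) + (parent.edge.length or 0.0)
        grand = parent.parent_node
        if grand is None:
            parent.remove_child(only)
            only.parent_node = None
            dt.seed_node = only
        else:
            grand.remove_child(parent)
            grand.add_child(only)
    # candidate attachment branches: every node with an edge length > 0
    candidates = [
        nd
        for nd in dt.preorder_node_iter()
        if nd.parent_node is not None and (nd.edge.length or 0.0) > 0
    ]
    if not candidates:
        # degenerate: reattach at root
        dt.seed_node.add_child(leaf)
        leaf.edge.length = pendant
        return
    target = candidates[int(rng.integers(len(candidates)))]
    split = float(rng.uniform(0.0, target.edge.length))
    upper = target.edge.length - split
    tparent = target.parent_node
    new = dendropy.Node()
    tparent.remove_child(target)
    tparent.add_child(new)
    new.edge.length = upper
    new.add_child(target)
    target.edge.length = split
    new.add_child(leaf)
    leaf.edge.length = pendant


def assign_categories(
    tree: PhyloTree,
    scheme: str = "uniform",
    seed: int = 0,
    *,
    stickiness: float = 0.8,
    frequencies: dict[str, float] | None = None,
) -> AssessmentTable:
    """Assign a Red List category to every tip.

    ``"uniform"`` draws each tip independently from the five data-sufficient
    categories; ``"frequency"`` uses Red-List-like frequencies (including a
    DD share); ``"clustered"`` runs a sticky Markov copy of categories from
    the root towards the tips — each node keeps its parent's category with
    probability ``stickiness``, else redraws uniformly — so threat is
    phylogenetically autocorrelated (stickiness 1 gives monophyletic blocks).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, 0)))
    tips = tree.tip_labels
    if scheme == "uniform":
        cats = rng.choice(DATA_SUFFICIENT, size=len(tips))
        table = {t: str(c) for t, c in zip(tips, cats)}
    elif scheme == "frequency":
        freq = frequencies or DEFAULT_CATEGORY_FREQUENCIES
        names = sorted(freq)
        probs = np.array([freq[k] for k in names], dtype=float)
        probs = probs / probs.sum()
        cats = rng.choice(names, size=len(tips), p=probs)
        table = {t: str(c) for t, c in zip(tips, cats)}
    elif scheme == "clustered":
        if not 0 <= stickiness <= 1:
            raise ValueError("stickiness must be in [0, 1]")
        n = tree.n_nodes
        cat_of = np.empty(n, dtype=object)
        root = tree.root_index
        cat_of[root] = rng.choice(DATA_SUFFICIENT)
        for v in range(n - 2, -1, -1):  # reverse postorder, parents first
            p = tree.parent[v]
            if p < 0:
                cat_of[v] = rng.choice(DATA_SUFFICIENT)
            elif rng.random() < stickiness:
                cat_of[v] = cat_of[p]
            else:
                cat_of[v] = rng.choice(DATA_SUFFICIENT)
        table = {t: str(cat_of[tree.tip_node(t)]) for t in tips}
    else:
        raise ValueError(f"unknown category scheme {scheme!r}")
    return AssessmentTable(categories=table)


@dataclass(frozen=True)
class WorkedFixture:
    """A micro-tree, its assessments, a p-assignment and oracle expectations."""

    name: str
    tree: PhyloTree
    table: AssessmentTable
    p: dict[str, float]
    expected_ed2: dict[str, float]  # computed by the exhaustive oracle
    ed1: dict[str, float]

    @property
    def newick(self) -> str:
        return self.tree.as_newick()


def _tree_from_newick(newick: str) -> PhyloTree:
    dt = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
    return PhyloTree(dt)


def worked_fixtures() -> dict[str, WorkedFixture]:
    """Three hand-built configurations with oracle-computed expectations.

    - ``cherry``: ((A:2,B:2):4,C:10); with p_B = 0.5 the expected unique PD
      of A is 2 + 4 x 0.5 = 4 MY, recovered here by outcome enumeration.
    - ``echidna``: two CR sisters share a long internal branch with a secure
      LC relative; the internal contribution to their expected
      distinctiveness shrinks relative to fair-proportion ED.
    - ``pangolin``: an EN tip with three CR congeners; clustered threat
      raises its expected distinctiveness above its fair-proportion ED.
    """
    curve = build_ge2_curve()
    anchor = curve.anchors
    fixtures: dict[str, WorkedFixture] = {}

    newick = "((A:2,B:2):4,C:10);"
    tree = _tree_from_newick(newick)
    table = AssessmentTable(categories={"A": "EN", "B": "VU", "C": "LC"})
    p = {"A": 0.485, "B": 0.5, "C": 0.060625}
    fixtures["cherry"] = WorkedFixture(
        name="cherry",
        tree=tree,
        table=table,
        p=p,
        expected_ed2={t: ed2_oracle(tree, p, t) for t in tree.tip_labels},
        ed1=fair_proportion_ed1(tree),
    )

    # two CR long-beaked tips, a secure LC sister, a distant outgroup
    newick = "(((Zb:5,Za:5):10,Ta:15):40,Out:55);"
    tree = _tree_from_newick(newick)
    table = AssessmentTable(
        categories={"Zb": "CR", "Za": "CR", "Ta": "LC", "Out": "LC"}
    )
    p = {
        "Zb": anchor["CR"],
        "Za": anchor["CR"],
        "Ta": anchor["LC"],
        "Out": anchor["LC"],
    }
    fixtures["echidna"] = WorkedFixture(
        name="echidna",
        tree=tree,
        table=table,
        p=p,
        expected_ed2={t: ed2_oracle(tree, p, t) for t in tree.tip_labels},
        ed1=fair_proportion_ed1(tree),
    )

    # four-tip genus: three CR congeners and one EN, plus an LC outgroup
    newick = "(((M1:3,M2:3):2,(M3:4,Mc:4):1):10,Out:20);"
    tree = _tree_from_newick(newick)
    table = AssessmentTable(
        categories={"M1": "CR", "M2": "CR", "M3": "CR", "Mc": "EN", "Out": "LC"}
    )
    p = {
        "M1": anchor["CR"],
        "M2": anchor["CR"],
        "M3": anchor["CR"],
        "Mc": anchor["EN"],
        "Out": anchor["LC"],
    }
    fixtures["pangolin"] = WorkedFixture(
        name="pangolin",
        tree=tree,
        table=table,
        p=p,
        expected_ed2={t: ed2_oracle(tree, p, t) for t in tree.tip_labels},
        ed1=fair_proportion_ed1(tree),
    )
    return fixtures
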