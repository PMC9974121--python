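"""Tree and assessment-table input.

Trees are read with :mod:`dendropy` (Newick or Nexus, multi-tree files or
directories of single-tree files) and indexed into :class:`PhyloTree`, a flat
array representation that the scoring traversals operate on.  Branch lengths
are taken at face value in millions of years (MY); no ultrametricity check is
enforced, because imputed tree distributions are not guaranteed ultrametric.
Unbranched internal nodes are collapsed at parse time by summing the adjacent
branch lengths, which leaves total phylogenetic diversity (the sum of all
branch lengths) unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "CATEGORIES",
    "DATA_SUFFICIENT",
    "THREATENED",
    "PhyloTree",
    "TreeSet",
    "AssessmentTable",
    "ReconciliationReport",
    "TreeParseError",
    "TreeValidationError",
    "AssessmentError",
    "ReconciliationError",
    "parse_tree_set",
    "load_assessments",
    "reconcile",
]

#: IUCN Red List categories recognised by the protocol.
CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE")

#: Categories with a data-sufficient extinction-risk assessment.
DATA_SUFFICIENT = ("LC", "NT", "VU", "EN", "CR")

#: Threatened categories (priority-eligible together with EW).
THREATENED = ("VU", "EN", "CR")

# Common long-form / variant spellings accepted in assessment tables.
_CATEGORY_SYNONYMS = {
    "LEAST CONCERN": "LC",
    "NEAR THREATENED": "NT",
    "VULNERABLE": "VU",
    "ENDANGERED": "EN",
    "CRITICALLY ENDANGERED": "CR",
    "EXTINCT IN THE WILD": "EW",
    "EXTINCT": "EX",
    "DATA DEFICIENT": "DD",
    "NOT EVALUATED": "NE",
    "NOT ASSESSED": "NE",
    "LR/LC": "LC",
    "LR/NT": "NT",
    "LC": "LC",
    "NT": "NT",
    "VU": "VU",
    "EN": "EN",
    "CR": "CR",
    "EW": "EW",
    "EX": "EX",
    "DD": "DD",
    "NE": "NE",
}


class TreeParseError(ValueError):
    """A tree file could not be parsed under the named schema."""


class TreeValidationError(ValueError):
    """A parsed tree violates a structural invariant (e.g. negative branch)."""


class AssessmentError(ValueError):
    """An assessment table is malformed (duplicates, unknown categories)."""


class ReconciliationError(ValueError):
    """Tree/table mismatch under strict reconciliation policy."""


class PhyloTree:
    """A rooted phylogeny indexed for fair-proportion and ED2 traversals.

    Nodes are stored in postorder as parallel arrays: ``parent[v]`` is the
    parent index (-1 for the root), ``length[v]`` the length of the branch
    above ``v`` in MY (0 when absent, e.g. the root), and ``n_desc[v]`` the
    number of tips descended from ``v`` (1 for a tip).  ``tip_labels`` holds
    the taxon identifiers in a deterministic (postorder) order.
    """

    def __init__(self, tree: dendropy.Tree, *, collapse: bool = True) -> None:
        if tree.is_rooted is False:
            raise TreeValidationError(
                "tree is explicitly flagged as unrooted; EDGE2 scores require "
                "a rooted phylogeny"
            )
        if collapse:
            _collapse_unifurcations(tree)
        self._dendropy_tree = tree

        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.length = np.zeros(n, dtype=np.float64)
        self.is_tip = np.zeros(n, dtype=bool)
        labels: list[str] = []
        tip_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
            blen = nd.edge.length
            if blen is None:
                blen = 0.0
            blen = float(blen)
            if not np.isfinite(blen) or blen < 0:
                raise TreeValidationError(
                    f"branch above {_describe_node(nd)} has invalid length {blen!r}; "
                    "branch lengths must be finite and >= 0"
                )
            self.length[i] = blen
            if nd.is_leaf():
                label = None if nd.taxon is None else nd.taxon.label
                if not label:
                    raise TreeValidationError("tip without a taxon label")
                if label in tip_index:
                    raise TreeValidationError(f"duplicate tip label {label!r}")
                self.is_tip[i] = True
                tip_index[label] = i
                labels.append(label)
        self.tip_labels: tuple[str, ...] = tuple(labels)
        self._tip_index = tip_index
        # postorder guarantees children precede parents
        self.n_desc = np.zeros(n, dtype=np.int64)
        self.n_desc[self.is_tip] = 1
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self.n_desc[p] += self.n_desc[i]

    # -- basic queries ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def total_pd(self) -> float:
        """Total phylogenetic diversity: the sum of all branch lengths (MY)."""
        return float(self.length.sum())

    def tip_node(self, taxon: str) -> int:
        try:
            return self._tip_index[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} is not a tip of this tree") from None

    def terminal_branch_length(self, taxon: str) -> float:
        return float(self.length[self.tip_node(taxon)])

    def terminal_branch_lengths(self) -> dict[str, float]:
        return {t: float(self.length[i]) for t, i in self._tip_index.items()}

    def ancestor_path(self, taxon: str) -> list[int]:
        """Node indices from the tip up to and including the root."""
        v = self.tip_node(taxon)
        path = [v]
        while self.parent[v] >= 0:
            v = int(self.parent[v])
            path.append(v)
        return path

    def root_to_tip_length(self, taxon: str) -> float:
        """Sum of branch lengths on the tip's ancestral path (MY)."""
        return float(sum(self.length[v] for v in self.ancestor_path(taxon)))

    def descendant_tips(self, node: int) -> frozenset[str]:
        """Tip labels below ``node`` (``node`` itself if it is a tip)."""
        out = self._descendant_cache().get(node)
        if out is None:
            raise IndexError(node)
        return out

    def _descendant_cache(self) -> dict[int, frozenset[str]]:
        cache = getattr(self, "_desc_sets", None)
        if cache is None:
            cache = {}
            for i in range(self.n_nodes):
                if self.is_tip[i]:
                    cache[i] = frozenset(
                        {t for t, j in self._tip_index.items() if j == i}
                    )
                else:
                    cache[i] = frozenset()
            for i in range(self.n_nodes):
                p = self.parent[i]
                if p >= 0:
                    cache[p] = cache[p] | cache[i]
            self._desc_sets = cache
        return cache

    def as_newick(self) -> str:
        return self._dendropy_tree.as_string(schema="newick").strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips}, total_pd={self.total_pd:.3g})"


def _describe_node(nd: dendropy.Node) -> str:
    if nd.is_leaf() and nd.taxon is not None:
        return f"tip {nd.taxon.label!r}"
    tips = [lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None]
    return f"internal node above {{{', '.join(sorted(tips)[:3])}...}}"


def _collapse_unifurcations(tree: dendropy.Tree) -> None:
    # merge single-child nodes, summing the two branch lengths
    changed = True
    while changed:
        changed = False
        for nd in list(tree.preorder_node_iter()):
            children = nd.child_nodes()
            if len(children) != 1:
                continue
            child = children[0]
            extra = nd.edge.length or 0.0
            child.edge.length = (child.edge.length or 0.0) + extra
            parent = nd.parent_node
            if parent is None:
                nd.remove_child(child)
                child.parent_node = None
                tree.seed_node = child
            else:
                parent.remove_child(nd)
                parent.add_child(child)
            changed = True
            break


@dataclass(frozen=True)
class TreeSet:
    """An ordered distribution of trees sharing a taxon universe."""

    trees: tuple[PhyloTree, ...]
    taxon_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeValidationError("a TreeSet must contain at least one tree")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    def presence(self, taxon: str) -> tuple[bool, ...]:
        return tuple(taxon in t.tip_labels for t in self.trees)

    @classmethod
    def from_trees(cls, trees: Iterable[PhyloTree]) -> "TreeSet":
        trees = tuple(trees)
        universe: set[str] = set()
        for t in trees:
            universe.update(t.tip_labels)
        return cls(trees=trees, taxon_universe=tuple(sorted(universe)))


def parse_tree_set(
    source: str | Path | Sequence[str | Path],
    format: str = "newick",
) -> TreeSet:
    """Read one or more tree files (or a directory of them) into a TreeSet.

    Parameters
    ----------
    source
        A file path, a directory containing tree files, or a sequence of
        file paths.  Multi-tree files are supported for both schemas.
    format
        ``"newick"`` or ``"nexus"``.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    paths = _expand_sources(source)
    trees: list[PhyloTree] = []
    for path in paths:
        tl = dendropy.TreeList()
        try:
            tl.read(
                path=str(path),
                schema=format,
                rooting="default-rooted",
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise TreeParseError(f"failed to parse {path}: {exc}") from exc
        for t in tl:
            trees.append(PhyloTree(t))
    if not trees:
        raise TreeParseError(f"no trees found in {source!r}")
    return TreeSet.from_trees(trees)


def _expand_sources(source) -> list[Path]:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            paths = sorted(q for q in p.iterdir() if q.is_file())
            if not paths:
                raise TreeParseError(f"directory {p} contains no files")
            return paths
        if not p.exists():
            raise TreeParseError(f"tree file {p} does not exist")
        return [p]
    paths = [Path(q) for q in source]
    for q in paths:
        if not q.exists():
            raise TreeParseError(f"tree file {q} does not exist")
    return paths


@dataclass(frozen=True)
class AssessmentTable:
    """Taxon -> Red List category, plus free-text tags (e.g. Possibly Extinct)."""

    categories: Mapping[str, str]
    tags: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.categories.values() if c not in CATEGORIES}
        if bad:
            raise AssessmentError(f"unknown Red List categories: {sorted(bad)}")

    def category(self, taxon: str, default: str = "NE") -> str:
        return self.categories.get(taxon, default)

    def tags_for(self, taxon: str) -> frozenset[str]:
        return self.tags.get(taxon, frozenset())

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def extinct_taxa(self) -> tuple[str, ...]:
        return tuple(t for t, c in self.categories.items() if c == "EX")


def normalise_category(raw: str) -> str:
    key = str(raw).strip().upper()
    try:
        return _CATEGORY_SYNONYMS[key]
    except KeyError:
        raise AssessmentError(f"unknown Red List category {raw!r}") from None


def load_assessments(
    source: str | Path,
    *,
    taxon_column: str = "taxon",
    category_column: str = "category",
    tag_column: str | None = "tags",
    sep: str | None = None,
) -> AssessmentTable:
    """Load a delimited assessment table.

    The delimiter is inferred from the extension (``.tsv`` -> tab, otherwise
    comma) unless ``sep`` is given.  Category strings are normalised
    (case-insensitive, long forms such as "Least Concern" accepted); unknown
    values and duplicate taxa are reported as errors listing the offenders.
    """
    import pandas as pd

    path = Path(source)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (taxon_column, category_column):
        if col not in df.columns:
            raise AssessmentError(
                f"{path}: required column {col!r} not found "
                f"(have {list(df.columns)})"
            )
    taxa = df[taxon_column].astype(str).str.strip()
    dup = taxa[taxa.duplicated()].unique().tolist()
    if dup:
        raise AssessmentError(f"{path}: duplicate taxa: {dup}")
    unknown = []
    categories: dict[str, str] = {}
    for taxon, raw in zip(taxa, df[category_column]):
        try:
            categories[taxon] = normalise_category(raw)
        except AssessmentError:
            unknown.append(raw)
    if unknown:
        raise AssessmentError(f"{path}: unknown categories: {unknown}")
    tags: dict[str, frozenset[str]] = {}
    if tag_column and tag_column in df.columns:
        for taxon, raw in zip(taxa, df[tag_column]):
            if isinstance(raw, str) and raw.strip():
                tags[taxon] = frozenset(
                    s.strip() for s in raw.split(";") if s.strip()
                )
    return AssessmentTable(categories=categories, tags=tags)


@dataclass(frozen=True)
class ReconciliationReport:
    """Outcome of matching a tree distribution against an assessment table."""

    in_trees_not_table: tuple[str, ...]  # scored as NE
    in_table_not_all_trees: tuple[str, ...]  # absent from >= 1 tree
    extinct: tuple[str, ...]  # EX taxa, excluded from scoring
    messages: tuple[str, ...]

    @property
    def clean(self) -> bool:
        return not (self.in_trees_not_table or self.in_table_not_all_trees)


def reconcile(
    trees: TreeSet,
    table: AssessmentTable,
    policy: str = "warn",
) -> ReconciliationReport:
    """Match the tree taxon universe against the assessment table.

    Taxa on the trees but missing from the table are treated as Not Evaluated
    (NE); taxa in the table but absent from one or more trees are reported;
    EX taxa are excluded from scoring (their tips, if present, remain on the
    tree with extinction probability pinned at the upper clip bound).  Under
    ``policy="strict"`` any mismatch raises :class:`ReconciliationError`.
    """
    if policy not in ("warn", "strict"):
        raise ValueError(f"unknown reconciliation policy {policy!r}")
    universe = set(trees.taxon_universe)
    table_taxa = set(table.taxa)
    missing_from_table = tuple(sorted(universe - table_taxa))
    not_everywhere = tuple(
        sorted(
            t
            for t in table_taxa
            if any(t not in tr.tip_labels for tr in trees)
        )
    )
    extinct = tuple(sorted(set(table.extinct_taxa()) & universe))
    messages = []
    if missing_from_table:
        messages.append(
            f"{len(missing_from_table)} taxa on trees lack assessments; "
            f"treated as NE: {list(missing_from_table)[:10]}"
        )
    if not_everywhere:
        messages.append(
            f"{len(not_everywhere)} assessed taxa absent from >=1 tree "
            f"(summaries use iterations where present): "
            f"{list(not_everywhere)[:10]}"
        )
    if extinct:
        messages.append(
            f"EX taxa excluded from scoring (p pinned at upper clip bound "
            f"on the tree): {list(extinct)}"
        )
    report = ReconciliationReport(
        in_trees_not_table=missing_from_table,
        in_table_not_all_trees=not_everywhere,
        extinct=extinct,
        messages=tuple(messages),
    )
    if policy == "strict" and not report.clean:
        raise ReconciliationError("; ".join(report.messages))
    return report
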