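"""Trees and trait tables: reading, writing, pruning, polytomy resolution.

Trees are Newick with mandatory branch lengths on every non-root edge
(independent contrasts are meaningless without them, so a missing length
is an error, never a silent default).  Trait tables are delimited text
with one row per species and one column per trait key
``<wing>.<surface>.s<sector>`` (e.g. ``fore.dorsal.s3``), holding
non-negative integer colour-component counts, or real values for
simulated data before discretization.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .config import SURFACES, WINGS

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "TraitValidationError",
    "PhyloTree",
    "TraitKey",
    "TraitMatrix",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "resolve_polytomies",
    "read_traits",
    "write_traits",
]


class NewickParseError(ValueError):
    """Raised for syntactically malformed Newick input."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the invariants the analysis needs."""


class TraitValidationError(ValueError):
    """Raised for malformed trait tables."""


class PhyloTree:
    """A rooted tree with branch lengths, backed by a :class:`dendropy.Tree`.

    Invariants enforced at construction: exactly one root; every non-root
    edge has a finite branch length >= 0; tip labels are unique non-empty
    strings.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def _validate(self) -> None:
        t = self._tree
        if t.seed_node is None:
            raise TreeValidationError("tree has no root node")
        labels = []
        for leaf in t.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeValidationError("tip with empty or missing label")
            labels.append(label)
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                continue
            bl = nd.edge.length
            if bl is None:
                raise TreeValidationError(
                    f"missing branch length on edge above "
                    f"{_node_name(nd)!r}; branch lengths are mandatory"
                )
            if not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(
                    f"invalid branch length {bl!r} above {_node_name(nd)!r}"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self._tree.preorder_node_iter())

    def is_bifurcating(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_internal_node_iter()
        )

    def root_to_tip_distances(self) -> dict[str, float]:
        """Path length from the root to every tip, in branch-length units."""
        dist: dict[dendropy.Node, float] = {self._tree.seed_node: 0.0}
        out: dict[str, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is not None:
                dist[nd] = dist[nd.parent_node] + nd.edge.length
            if nd.is_leaf():
                out[nd.taxon.label] = dist[nd]
        return out

    @property
    def depth(self) -> float:
        return max(self.root_to_tip_distances().values())

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree with {self.n_tips} tips>"


def _node_name(nd: dendropy.Node) -> str:
    if nd.taxon is not None and nd.taxon.label:
        return nd.taxon.label
    if nd.label:
        return nd.label
    return "<unnamed internal node>"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" (line {line}, column {col})" if line is not None else ""
        if "duplicate" in str(exc).lower():
            raise TreeValidationError(f"duplicate tip labels{where}: {exc}") from exc
        raise NewickParseError(f"malformed Newick{where}: {exc}") from exc
    return PhyloTree(tree)


def read_newick_file(path: str) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: PhyloTree, path: str | None = None) -> str:
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Prune to the tips in ``keep``, collapsing pass-through nodes.

    Degree-2 internal nodes created by pruning are collapsed with their
    branch lengths summed, so root-to-tip path lengths of retained tips
    are conserved exactly.
    """
    keep = set(keep)
    tips = set(tree.tip_labels)
    unknown = sorted(keep - tips)
    if unknown:
        raise TreeValidationError(f"cannot prune: labels not in tree: {unknown}")
    if len(keep) < 2:
        raise TreeValidationError("need at least 2 tips to keep")
    work = tree.dendropy_tree.clone(depth=1)
    work.retain_taxa_with_labels(sorted(keep))
    # a root left with a single child keeps the child subtree intact but
    # carries the pruned stem; collapse it so the root is the retained MRCA
    root = work.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        work.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    work.purge_taxon_namespace()
    return PhyloTree(work)


def resolve_polytomies(
    tree: PhyloTree, epsilon: float = 0.0, seed: int = 0
) -> PhyloTree:
    """Arbitrarily resolve multifurcations into bifurcations.

    Each inserted edge gets length ``epsilon``.  The resolution order is
    deterministic given ``seed``.  Bifurcating input is returned
    topologically unchanged (as a copy).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rng = random.Random(seed)
    out = tree.copy()
    work = out.dendropy_tree
    for nd in list(work.preorder_internal_node_iter()):
        children = nd.child_nodes()
        while len(children) > 2:
            order = sorted(range(len(children)), key=lambda i: _min_tip(children[i]))
            i, j = sorted(rng.sample(order, 2))
            a, b = children[i], children[j]
            nd.remove_child(a)
            nd.remove_child(b)
            merged = nd.new_child(edge_length=epsilon)
            merged.add_child(a)
            merged.add_child(b)
            children = nd.child_nodes()
    return PhyloTree(work)


def _min_tip(nd: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in nd.leaf_iter())


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class TraitKey:
    """Identifies one trait: wing, surface, and sector label."""

    wing: str
    surface: str
    sector: str

    def __post_init__(self) -> None:
        if self.wing not in WINGS:
            raise TraitValidationError(f"unknown wing {self.wing!r}")
        if self.surface not in SURFACES:
            raise TraitValidationError(f"unknown surface {self.surface!r}")

    def encode(self) -> str:
        return f"{self.wing}.{self.surface}.s{self.sector}"

    @classmethod
    def decode(cls, column: str) -> "TraitKey":
        parts = column.split(".")
        if len(parts) != 3 or not parts[2].startswith("s"):
            raise TraitValidationError(
                f"cannot parse trait column {column!r}; "
                "expected <wing>.<surface>.s<sector>"
            )
        return cls(parts[0], parts[1], parts[2][1:])


class TraitMatrix:
    """Species x trait table of eyespot colour-component counts.

    ``mode`` is ``"count"`` (non-negative integers, the scored data) or
    ``"continuous"`` (real values, simulated traits before
    discretization).  Missing values are explicit NaN, never zeros.
    """

    def __init__(self, data: pd.DataFrame, mode: str = "count"):
        if mode not in ("count", "continuous"):
            raise TraitValidationError(f"unknown mode {mode!r}")
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise TraitValidationError(f"duplicate species rows: {dupes}")
        for col in data.columns:
            TraitKey.decode(col)  # raises if malformed
        values = data.to_numpy(dtype=float)
        if mode == "count":
            finite = values[np.isfinite(values)]
            if np.any(finite < 0):
                raise TraitValidationError("negative count values")
            if np.any(finite != np.round(finite)):
                raise TraitValidationError("non-integer count values in count mode")
        self._data = data.astype(float)
        self.mode = mode

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    @property
    def keys(self) -> tuple[TraitKey, ...]:
        return tuple(TraitKey.decode(c) for c in self._data.columns)

    @property
    def n_missing(self) -> int:
        return int(self._data.isna().to_numpy().sum())

    def column(self, key: TraitKey | str) -> pd.Series:
        col = key.encode() if isinstance(key, TraitKey) else key
        return self._data[col]

    def values_for_tips(self, key: TraitKey | str, tips: Sequence[str]) -> np.ndarray:
        return self.column(key).reindex(tips).to_numpy(dtype=float)

    def equals(self, other: "TraitMatrix") -> bool:
        a, b = self._data, other._data
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and np.allclose(a.to_numpy(), b.to_numpy(), equal_nan=True)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TraitMatrix {len(self.species)} species x "
            f"{self._data.shape[1]} traits, mode={self.mode}>"
        )


def read_traits(source: str | io.TextIOBase, mode: str = "count") -> TraitMatrix:
    """Read a delimited trait table (comma or tab separated)."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return TraitMatrix(df, mode=mode)


def write_traits(matrix: TraitMatrix, path: str, sep: str = ",") -> None:
    df = matrix.data
    if matrix.mode == "count":
        df = df.astype("Int64")  # keeps NaN explicit, prints integers
    df.to_csv(path, sep=sep, index_label="species")
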