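"""Phylogenetic-signal testing: Moran's I with Abouheif proximities.

The gatekeeping step of the comparative analysis: before computing
contrasts, each trait is tested for phylogenetic autocorrelation.  The
test statistic is Moran's I computed with the Abouheif proximity matrix
``A_ij = 1 / prod(dd_k)``, where the product runs over the internal
nodes on the tip-to-tip path between i and j and ``dd_k`` is the number
of direct descendants of node k.  Significance is assessed by permuting
tip values uniformly at random, with the add-one Monte-Carlo estimator
``p = (1 + #{I_perm >= I_obs}) / (1 + n_permutations)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_io import PhyloTree, TraitMatrix

__all__ = [
    "SignalTestResult",
    "abouheif_proximity",
    "abouheif_test",
    "abouheif_test_all",
]


class NoVarianceError(ValueError):
    """Raised when a trait is constant across tips (signal undefined)."""


@dataclass(frozen=True)
class SignalTestResult:
    trait: str
    statistic: float
    n_permutations: int
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


def abouheif_proximity(tree: PhyloTree, normalize: bool = False) -> pd.DataFrame:
    """Abouheif proximity matrix over tips.

    ``A_ij`` is the inverse product of direct-descendant counts over the
    internal nodes on the path between tips i and j; the diagonal is 0.
    With ``normalize=True`` rows are scaled to sum to 1 (the weight
    matrix used by the Moran index).
    """
    tips = [lf for lf in tree.dendropy_tree.leaf_node_iter()]
    if len(tips) < 3:
        raise ValueError("Abouheif proximity needs at least 3 tips")
    labels = [lf.taxon.label for lf in tips]
    # ancestor chains, tip -> root
    chains = []
    for lf in tips:
        chain = []
        nd = lf.parent_node
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        chains.append(chain)
    dd = {nd: len(nd.child_nodes()) for ch in chains for nd in ch}
    n = len(tips)
    A = np.zeros((n, n))
    for i in range(n):
        anc_i = {nd: k for k, nd in enumerate(chains[i])}
        for j in range(i + 1, n):
            # path nodes: strict ancestors of each tip below the MRCA,
            # plus the MRCA itself
            prod = 1.0
            mrca_depth = None
            for nd in chains[j]:
                if nd in anc_i:
                    mrca_depth = anc_i[nd]
                    prod *= dd[nd]
                    break
                prod *= dd[nd]
            for k in range(mrca_depth):
                prod *= dd[chains[i][k]]
            A[i, j] = A[j, i] = 1.0 / prod
    if normalize:
        A = A / A.sum(axis=1, keepdims=True)
    return pd.DataFrame(A, index=labels, columns=labels)


def _moran(values: np.ndarray, W: np.ndarray) -> float:
    z = values - values.mean()
    denom = float(z @ z)
    return float(z @ W @ z) / denom


def abouheif_test(
    tree: PhyloTree,
    values: Mapping[str, float] | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    trait: str = "trait",
) -> SignalTestResult:
    """Permutation test of phylogenetic autocorrelation for one trait.

    ``values`` maps every tip label to a trait value.  The returned
    p-value is one-sided (large I = positive autocorrelation), exactly
    reproducible from ``seed``.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    labels = list(tree.tip_labels)
    x = np.asarray([values[lb] for lb in labels], dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite trait values")
    if np.ptp(x) == 0:
        raise NoVarianceError(f"trait {trait!r} is constant across tips")
    W = abouheif_proximity(tree, normalize=True).to_numpy()
    obs = _moran(x, W)
    rng = np.random.default_rng(seed)
    n = len(x)
    perms = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    Z = perms - perms.mean(axis=1, keepdims=True)
    stats = np.einsum("ij,ij->i", Z @ W, Z) / np.einsum("ij,ij->i", Z, Z)
    n_ge = int(np.sum(stats >= obs))
    p = (1 + n_ge) / (1 + n_permutations)
    return SignalTestResult(
        trait=trait,
        statistic=obs,
        n_permutations=n_permutations,
        p_value=p,
        seed=seed,
    )


def abouheif_test_all(
    tree: PhyloTree,
    traits: TraitMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the Abouheif test per trait; one row per trait column.

    Constant traits get NaN statistic/p with a note rather than an
    exception, so a whole-matrix screen never aborts.
    """
    rows = []
    for k, col in enumerate(traits.data.columns):
        series = traits.column(col)
        try:
            res = abouheif_test(
                tree,
                series,
                n_permutations=n_permutations,
                seed=seed + k,
                trait=col,
            )
            rows.append(
                dict(
                    trait=col,
                    statistic=res.statistic,
                    n_permutations=res.n_permutations,
                    p_value=res.p_value,
                    seed=res.seed,
                    note="",
                )
            )
        except NoVarianceError:
            rows.append(
                dict(
                    trait=col,
                    statistic=np.nan,
                    n_permutations=n_permutations,
                    p_value=np.nan,
                    seed=seed + k,
                    note="constant trait; signal undefined",
                )
            )
    return pd.DataFrame(rows)
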