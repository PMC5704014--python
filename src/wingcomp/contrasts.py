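"""Felsenstein independent contrasts and through-origin correlation.

For each internal node of a bifurcating tree with child values x_i, x_j
on edges of length v_i, v_j, the standardized contrast is
``C = (x_i - x_j) / sqrt(v_i + v_j)``; the reconstructed nodal value is
the precision-weighted mean ``(x_i/v_i + x_j/v_j) / (1/v_i + 1/v_j)``
and the node's own edge picks up the extra variance
``v' = v + v_i v_j / (v_i + v_j)``.  Under Brownian-motion evolution the
N-1 contrasts are independent with mean zero, so trait association is
measured by the correlation through the origin of paired contrasts,
``r = sum(CxCy) / sqrt(sum(Cx^2) sum(Cy^2))``, with
``t = r sqrt(df/(1-r^2))`` on ``df = n_contrasts - 1`` degrees of
freedom and a two-tailed p from the central t distribution.

Branch lengths are used untransformed.  Contrast order is deterministic:
post-order with children ordered by their smallest descendant tip label.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_SECTOR_CONFIG, SURFACES, WINGS, SectorConfig
from .phylo_io import PhyloTree, TraitKey, TraitMatrix, prune_to_taxa

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "ComparisonPlan",
    "StudyResult",
    "ContrastError",
    "UndefinedCorrelationError",
    "contrast_structure",
    "felsenstein_contrasts",
    "correlation_through_origin",
    "p_from_r",
    "bm_adequacy_diagnostic",
    "build_comparison_plans",
    "eyespot_totals",
    "run_study",
]


class ContrastError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastStructure:
    """Tree-only part of the contrasts recursion.

    ``matrix`` maps tip values (ordered as ``tips``) linearly onto the
    N-1 standardized contrasts; ``node_matrix`` maps them onto the
    reconstructed nodal values.  Reusable across traits on the same
    tree, which makes simulation studies cheap.
    """

    tips: tuple[str, ...]
    node_ids: tuple[str, ...]
    matrix: np.ndarray  # (n_tips - 1, n_tips)
    node_matrix: np.ndarray  # (n_tips - 1, n_tips)
    contrast_sds: np.ndarray  # sqrt(v_i + v_j) per node
    adjusted_lengths: np.ndarray  # v' per node


@dataclass(frozen=True)
class ContrastSet:
    trait: str
    tips: tuple[str, ...]
    node_ids: tuple[str, ...]
    contrasts: np.ndarray
    node_values: np.ndarray
    contrast_sds: np.ndarray
    adjusted_lengths: np.ndarray

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)


@dataclass(frozen=True)
class CorrelationResult:
    trait_x: str
    trait_y: str
    r: float
    t: float
    df: int
    p: float
    n_contrasts: int


def _pic_recursion(tree: PhyloTree, leaf_state, zero_length_epsilon):
    """Shared Felsenstein pruning pass, canonical child order.

    ``leaf_state(label)`` supplies the state carried up the tree — a
    scalar trait value, or a tip-indicator weight vector when building
    the linear contrast operator.  Returns (contrast states, node
    states, contrast SDs, adjusted lengths v', node ids, tip order).
    """
    if not tree.is_bifurcating():
        raise ContrastError(
            "contrasts require a strictly bifurcating tree; "
            "apply resolve_polytomies() first"
        )
    tips = list(tree.tip_labels)
    if len(tips) < 2:
        raise ContrastError("need at least 2 tips")
    if zero_length_epsilon == "auto":
        zero_length_epsilon = 1e-8 * max(tree.depth, 1.0)

    contrasts, node_states, sds, vprimes, node_ids = [], [], [], [], []

    def visit(nd):
        # returns (state, edge variance incl. extra term, min tip label)
        if nd.is_leaf():
            return leaf_state(nd.taxon.label), float(nd.edge.length), nd.taxon.label
        results = [visit(ch) for ch in nd.child_nodes()]
        results.sort(key=lambda r: r[2])
        (x1, v1, m1), (x2, v2, m2) = results
        denom = v1 + v2
        if denom == 0:
            if zero_length_epsilon is None:
                raise ContrastError(
                    f"zero contrast denominator at node above tip {m1!r}; "
                    "configure zero_length_epsilon (e.g. 'auto') to inflate "
                    "zero-length sister branches"
                )
            logger.warning(
                "zero contrast denominator at node above tip %r; "
                "inflating both branches by %.3g",
                m1,
                zero_length_epsilon,
            )
            v1 = v2 = zero_length_epsilon
            denom = v1 + v2
        sd = np.sqrt(denom)
        contrasts.append((x1 - x2) / sd)
        # precision-weighted mean (x1/v1 + x2/v2)/(1/v1 + 1/v2), written
        # so identical child values propagate exactly
        node_state = x1 + (v1 / denom) * (x2 - x1)
        node_states.append(node_state)
        sds.append(sd)
        edge = nd.edge.length if nd.parent_node is not None else 0.0
        vprimes.append(float(edge) + v1 * v2 / denom)
        node_ids.append(f"{m1}|{m2}")
        return node_state, vprimes[-1], m1

    visit(tree.dendropy_tree.seed_node)
    return contrasts, node_states, sds, vprimes, node_ids, tips


def contrast_structure(
    tree: PhyloTree, zero_length_epsilon: float | str | None = "auto"
) -> ContrastStructure:
    """Build the linear contrast operator for a bifurcating tree.

    Standardized contrasts are linear in the tip values, so running the
    recursion on tip-indicator vectors yields a reusable matrix — cheap
    when many traits share one tree.  Zero denominators (v_i + v_j = 0,
    possible after zero-epsilon polytomy resolution) are inflated to
    ``zero_length_epsilon`` with a logged warning; ``"auto"`` means
    1e-8 x tree depth; ``None`` makes them a hard error.
    """
    tips = list(tree.tip_labels)
    n = len(tips)
    index = {lb: i for i, lb in enumerate(tips)}

    def leaf_state(label: str) -> np.ndarray:
        w = np.zeros(n)
        w[index[label]] = 1.0
        return w

    rows, node_rows, sds, vprimes, node_ids, tips = _pic_recursion(
        tree, leaf_state, zero_length_epsilon
    )
    return ContrastStructure(
        tips=tuple(tips),
        node_ids=tuple(node_ids),
        matrix=np.vstack(rows),
        node_matrix=np.vstack(node_rows),
        contrast_sds=np.asarray(sds),
        adjusted_lengths=np.asarray(vprimes),
    )


def felsenstein_contrasts(
    tree: PhyloTree | ContrastStructure,
    values: Mapping[str, float] | pd.Series,
    trait: str = "trait",
    zero_length_epsilon: float | str | None = "auto",
) -> ContrastSet:
    """Standardized independent contrasts for one trait.

    ``values`` must supply a finite value for every tip.  Accepts a
    prebuilt :class:`ContrastStructure` in place of the tree to amortize
    the tree traversal over many traits.
    """
    if isinstance(tree, ContrastStructure):
        struct = tree
        x = np.asarray([values[lb] for lb in struct.tips], dtype=float)
        if np.any(~np.isfinite(x)):
            missing = [lb for lb, v in zip(struct.tips, x) if not np.isfinite(v)]
            raise ContrastError(f"missing trait values for tips: {missing}")
        return ContrastSet(
            trait=trait,
            tips=struct.tips,
            node_ids=struct.node_ids,
            contrasts=struct.matrix @ x,
            node_values=struct.node_matrix @ x,
            contrast_sds=struct.contrast_sds,
            adjusted_lengths=struct.adjusted_lengths,
        )
    bad = [
        lb
        for lb in tree.tip_labels
        if lb not in values or not np.isfinite(values[lb])
    ]
    if bad:
        raise ContrastError(f"missing trait values for tips: {bad}")
    contrasts, node_vals, sds, vprimes, node_ids, tips = _pic_recursion(
        tree, lambda lb: float(values[lb]), zero_length_epsilon
    )
    return ContrastSet(
        trait=trait,
        tips=tuple(tips),
        node_ids=tuple(node_ids),
        contrasts=np.asarray(contrasts),
        node_values=np.asarray(node_vals),
        contrast_sds=np.asarray(sds),
        adjusted_lengths=np.asarray(vprimes),
    )


def p_from_r(r: float, n_contrasts: int) -> float:
    """Two-tailed p for a through-origin contrast correlation.

    Uses ``t = |r| sqrt(df/(1-r^2))`` with ``df = n_contrasts - 1``.
    For |r| >= 1 the statistic is unbounded; 0.0 is returned with a
    warning rather than raising.
    """
    if n_contrasts < 3:
        raise ValueError("need at least 3 contrasts")
    if abs(r) >= 1.0:
        warnings.warn(
            f"|r| = {abs(r):g} >= 1; p-value degenerate at 0", RuntimeWarning
        )
        return 0.0
    df = n_contrasts - 1
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def correlation_through_origin(
    csx: ContrastSet, csy: ContrastSet
) -> CorrelationResult:
    """Correlation of paired contrasts, constrained through the origin.

    Contrast signs are arbitrary but paired, so no mean-centring is
    applied; this is the standard statistic for independent contrasts.
    """
    if csx.tips != csy.tips or csx.node_ids != csy.node_ids:
        raise ValueError("contrast sets come from different trees or orders")
    cx, cy = csx.contrasts, csy.contrasts
    n = len(cx)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    sxx, syy = float(cx @ cx), float(cy @ cy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError(
            "all contrasts are zero for "
            + (csx.trait if sxx == 0.0 else csy.trait)
        )
    r = float(cx @ cy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 1
    if abs(r) < 1.0:
        t = r * np.sqrt(df / (1.0 - r * r))
    else:
        t = np.inf * np.sign(r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = p_from_r(r, n)
    return CorrelationResult(
        trait_x=csx.trait, trait_y=csy.trait, r=r, t=float(t), df=df, p=p,
        n_contrasts=n,
    )


def bm_adequacy_diagnostic(cs: ContrastSet) -> tuple[float, float]:
    """Diagnostic for the Brownian-motion standardization.

    Ordinary (Pearson) correlation between |standardized contrast| and
    its standard deviation sqrt(v_i + v_j) across nodes, with two-tailed
    p.  Under an adequate BM standardization the two are uncorrelated;
    a significant positive correlation indicates branch lengths that do
    not absorb the variance.
    """
    if cs.n_contrasts < 4:
        raise ValueError("need at least 4 contrasts for the diagnostic")
    a = np.abs(cs.contrasts)
    s = cs.contrast_sds
    if np.ptp(a) == 0 or np.ptp(s) == 0:
        if np.ptp(s) > 0 and np.ptp(a) == 0:
            return 0.0, 1.0  # constant |contrasts|: no trend by definition
        raise UndefinedCorrelationError(
            "zero variance in contrast SDs; diagnostic undefined"
        )
    stat, p = stats.pearsonr(a, s)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# comparison plans (the within/between wing-surface machinery)
# ---------------------------------------------------------------------------

SCOPES = ("within_surface_pairs", "cross_surface_homologous", "cross_surface_totals")


@dataclass(frozen=True)
class ComparisonPlan:
    scope: str
    wing: str
    surfaces: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    @property
    def name(self) -> str:
        return f"{self.scope}:{self.wing}:{'-'.join(self.surfaces)}"


def total_column(wing: str, surface: str) -> str:
    return f"{wing}.{surface}.total"


def build_comparison_plans(
    config: SectorConfig = DEFAULT_SECTOR_CONFIG,
) -> list[ComparisonPlan]:
    """All planned trait-pair comparisons.

    Per wing surface: the 28 unordered within-surface sector pairs.
    Per wing: the 8 dorsal-ventral homologous-sector pairs, plus one
    dorsal-vs-ventral comparison of eyespot totals (number of sectors
    with a positive count).
    """
    plans: list[ComparisonPlan] = []
    for wing in WINGS:
        sectors = config.sectors(wing)
        if len(sectors) != 8:
            raise ValueError(
                f"{wing}wing sector set must have 8 labels, got {len(sectors)}"
            )
        for surface in SURFACES:
            keys = [TraitKey(wing, surface, s).encode() for s in sectors]
            pairs = tuple(itertools.combinations(keys, 2))
            plans.append(
                ComparisonPlan("within_surface_pairs", wing, (surface,), pairs)
            )
        homologous = tuple(
            (
                TraitKey(wing, "dorsal", s).encode(),
                TraitKey(wing, "ventral", s).encode(),
            )
            for s in sectors
        )
        plans.append(
            ComparisonPlan(
                "cross_surface_homologous", wing, ("dorsal", "ventral"), homologous
            )
        )
        plans.append(
            ComparisonPlan(
                "cross_surface_totals",
                wing,
                ("dorsal", "ventral"),
                ((total_column(wing, "dorsal"), total_column(wing, "ventral")),),
            )
        )
    return plans


def eyespot_totals(
    traits: TraitMatrix, config: SectorConfig = DEFAULT_SECTOR_CONFIG
) -> pd.DataFrame:
    """Eyespot count per wing surface: sectors with component count > 0.

    Missing sector values are ignored in the count; a surface with all
    sectors missing gets NaN.
    """
    out = {}
    for wing in WINGS:
        for surface in SURFACES:
            cols = [
                TraitKey(wing, surface, s).encode() for s in config.sectors(wing)
            ]
            cols = [c for c in cols if c in traits.data.columns]
            if not cols:
                continue
            block = traits.data[cols]
            totals = (block > 0).sum(axis=1).astype(float)
            totals[block.isna().all(axis=1)] = np.nan
            out[total_column(wing, surface)] = totals
    return pd.DataFrame(out, index=traits.data.index)


@dataclass
class StudyResult:
    table: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)
    alpha: float = 0.05

    def all_surface_significant_pairs(self) -> list[tuple[str, str]]:
        """Sector pairs with a significant positive correlation on every
        wing surface (the compartment-boundary signature)."""
        sub = self.table[self.table.scope == "within_surface_pairs"]
        surfaces = sub.groupby(["wing", "surfaces"]).ngroups
        flagged: dict[tuple[str, str], int] = {}
        for _, row in sub[sub.significant & (sub.r > 0)].iterrows():
            sx = TraitKey.decode(row.trait_x).sector
            sy = TraitKey.decode(row.trait_y).sector
            key = tuple(sorted((sx, sy), key=_sector_sort_key))
            flagged[key] = flagged.get(key, 0) + 1
        return sorted(
            [k for k, v in flagged.items() if v == surfaces],
            key=lambda k: (_sector_sort_key(k[0]), _sector_sort_key(k[1])),
        )

    def format_report(self) -> str:
        """Plain-text report: significant pairs per wing surface."""
        lines = [
            "Significant independent-contrast correlations "
            f"(two-tailed, alpha = {self.alpha:g})",
            "",
        ]
        sub = self.table[self.table.scope == "within_surface_pairs"]
        for (wing, surfaces), grp in sub.groupby(["wing", "surfaces"]):
            lines.append(f"{wing}wing, {surfaces[0]} surface:")
            sig = grp[grp.significant]
            if sig.empty:
                lines.append("  (none)")
            for _, row in sig.iterrows():
                sx = TraitKey.decode(row.trait_x).sector
                sy = TraitKey.decode(row.trait_y).sector
                lines.append(
                    f"  {sx} + {sy} (r = {row.r:.2f}, p = {row.p:.4g})"
                )
            lines.append("")
        allsurf = self.all_surface_significant_pairs()
        lines.append(
            "Pairs significant on every wing surface: "
            + (", ".join(f"{a} + {b}" for a, b in allsurf) if allsurf else "(none)")
        )
        other = self.table[self.table.scope != "within_surface_pairs"]
        if not other.empty:
            lines.append("")
            lines.append("Cross-surface comparisons:")
            for _, row in other.iterrows():
                mark = " *" if row.significant else ""
                lines.append(
                    f"  {row.trait_x} vs {row.trait_y}: "
                    f"r = {row.r:.2f}, p = {row.p:.4g}{mark}"
                )
        if self.skipped:
            lines.append("")
            lines.append("Skipped pairs:")
            for item in self.skipped:
                lines.append(
                    f"  {item['trait_x']} vs {item['trait_y']}: {item['reason']}"
                )
        return "\n".join(lines) + "\n"


def _sector_sort_key(label: str):
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


def run_study(
    tree: PhyloTree,
    traits: TraitMatrix,
    plans: Sequence[ComparisonPlan] | None = None,
    alpha: float = 0.05,
    bh: bool = False,
    config: SectorConfig = DEFAULT_SECTOR_CONFIG,
    zero_length_epsilon: float | str | None = "auto",
) -> StudyResult:
    """Run every planned pairwise contrast correlation.

    The tree must already be pruned/rooted to exactly the trait species.
    Pairs with missing values are computed on the tree pruned to the
    species carrying both traits (df adjusts); pairs with fewer than 4
    such species, or with zero contrast variance, are skipped with a
    logged reason.  ``bh=False`` reports raw p-values against ``alpha``
    (no multiple-testing correction); ``bh=True`` flags on
    Benjamini-Hochberg adjusted values instead.
    """
    tree_tips = set(tree.tip_labels)
    trait_species = set(traits.species)
    if tree_tips != trait_species:
        only_tree = sorted(tree_tips - trait_species)
        only_traits = sorted(trait_species - tree_tips)
        raise ValueError(
            "species mismatch between tree and traits; "
            f"only in tree: {only_tree}; only in traits: {only_traits}"
        )
    if plans is None:
        plans = build_comparison_plans(config)

    data = traits.data.join(eyespot_totals(traits, config))
    structures: dict[frozenset, ContrastStructure] = {}
    contrast_cache: dict[tuple[frozenset, str], ContrastSet] = {}

    def structure_for(species: frozenset) -> ContrastStructure:
        if species not in structures:
            sub = tree if species == frozenset(tree_tips) else prune_to_taxa(
                tree, species
            )
            structures[species] = contrast_structure(sub, zero_length_epsilon)
        return structures[species]

    def contrasts_for(species: frozenset, col: str) -> ContrastSet:
        key = (species, col)
        if key not in contrast_cache:
            contrast_cache[key] = felsenstein_contrasts(
                structure_for(species), data[col], trait=col
            )
        return contrast_cache[key]

    rows = []
    skipped = []
    for plan in plans:
        for cx, cy in plan.pairs:
            present = data.index[data[cx].notna() & data[cy].notna()]
            species = frozenset(present)
            if len(species) < 4:
                reason = f"only {len(species)} species with both traits"
                logger.warning("skipping %s vs %s: %s", cx, cy, reason)
                skipped.append(dict(trait_x=cx, trait_y=cy, reason=reason))
                continue
            try:
                res = correlation_through_origin(
                    contrasts_for(species, cx), contrasts_for(species, cy)
                )
            except UndefinedCorrelationError as exc:
                logger.warning("skipping %s vs %s: %s", cx, cy, exc)
                skipped.append(dict(trait_x=cx, trait_y=cy, reason=str(exc)))
                continue
            rows.append(
                dict(
                    scope=plan.scope,
                    wing=plan.wing,
                    surfaces=plan.surfaces,
                    trait_x=cx,
                    trait_y=cy,
                    r=res.r,
                    t=res.t,
                    df=res.df,
                    p=res.p,
                    n_contrasts=res.n_contrasts,
                )
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        if bh:
            table["p_adjusted"] = stats.false_discovery_control(
                table["p"].to_numpy(), method="bh"
            )
            table["significant"] = table["p_adjusted"] < alpha
        else:
            table["significant"] = table["p"] < alpha
    return StudyResult(table=table, skipped=skipped, alpha=alpha)
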