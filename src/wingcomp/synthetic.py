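"""Synthetic trees, correlated count traits, and mosaic wing specimens.

The generators reproduce the statistical structure the analysis assumes,
so every pipeline stage is testable without specimen data: a Yule
(pure-birth) phylogeny of 22 ingroup species plus one basal outgroup
used to root the tree; 32 eyespot-complexity traits (2 wings x 2
surfaces x 8 sectors) evolving by correlated Brownian motion with
designated correlated sector pairs (2, 5) and (3, 4) on every surface,
then discretized to small counts; and wings bearing polygonal mitotic
clones that either respect or ignore a Far-Posterior (F-P) boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .config import DEFAULT_SECTOR_CONFIG, SURFACES, WINGS, SectorConfig
from .phylo_io import PhyloTree, TraitKey, TraitMatrix
from .clone_geometry import LandmarkSet, WingSpecimen

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "discretize_counts",
    "study_correlation_matrix",
    "generate_study_like_dataset",
    "generate_wing_specimens",
    "TEMPLATE_LANDMARKS",
    "TEMPLATE_FP_BOUNDARY",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the study-like simulation.

    ``rho_block`` is the Brownian correlation imposed on sector pairs
    (2, 5) and (3, 4) within every wing surface; ``rho_homology`` the
    dorsal-ventral correlation of homologous sectors (0 by default).
    ``tip_sd`` is the Brownian standard deviation accumulated from root
    to tip, in count units (the per-branch rate is ``tip_sd /
    sqrt(tree depth)``, so the marginal spread of species counts does
    not depend on the arbitrary time units of the simulated tree);
    ``root_value`` is the ancestral count level and ``max_count`` the
    ceiling of the discretized colour-component counts.
    """

    n_ingroup: int = 22
    birth_rate: float = 1.0
    rho_block: float = 0.8
    rho_homology: float = 0.0
    tip_sd: float = 2.0
    root_value: float = 3.0
    max_count: int = 6
    outgroup_depth_factor: float = 1.0
    sectors: SectorConfig = field(default_factory=lambda: DEFAULT_SECTOR_CONFIG)
    seed: int = 0


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, prefix: str = "t"
) -> PhyloTree:
    """Ultrametric pure-birth tree with exponential waiting times.

    Starting from the root split (2 lineages), each epoch with k
    lineages lasts Exp(k * birth_rate); after the n-th lineage appears a
    final Exp(n * birth_rate) epoch runs to the present, so the expected
    depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # active lineages, each with its birth time
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root.new_child(), 0.0))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        for _ in range(2):
            active.append((node.new_child(), t))
        k += 1
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    width = len(str(n_tips))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"{prefix}{i + 1:0{width}d}")
    return PhyloTree(tree)


def _psd_factor(R: np.ndarray) -> np.ndarray:
    """Matrix L with L L^T = R, valid for any PSD R (rank-deficient ok)."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not PSD (smallest eigenvalue {vals.min():.3e})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_bm_traits(
    tree: PhyloTree,
    trait_keys: list[str],
    R: np.ndarray,
    sigma: float | np.ndarray = 1.0,
    root_values: float | np.ndarray = 0.0,
    seed: int = 0,
) -> TraitMatrix:
    """Correlated Brownian-motion traits on a tree (continuous).

    Along each branch of length v, increments are drawn jointly from a
    zero-mean multivariate normal with covariance ``v * D R D`` where
    ``D = diag(sigma)``; tip values are the root values plus the summed
    increments along the root-to-tip path.
    """
    p = len(trait_keys)
    L = _psd_factor(R)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (p,))
    root = np.broadcast_to(np.asarray(root_values, dtype=float), (p,))
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.parent_node is None:
            values[id(nd)] = root.astype(float).copy()
        else:
            v = nd.edge.length
            incr = math.sqrt(v) * sig * (L @ rng.standard_normal(p))
            values[id(nd)] = values[id(nd.parent_node)] + incr
        if nd.is_leaf():
            rows[nd.taxon.label] = values[id(nd)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=trait_keys)
    df = df.loc[list(tree.tip_labels)]
    df.index.name = "species"
    return TraitMatrix(df, mode="continuous")


def discretize_counts(traits: TraitMatrix, max_count: int = 6) -> TraitMatrix:
    """Round half away from zero, then clip to [0, max_count].

    Monotone by construction, idempotent on integers already in range.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    x = traits.data.to_numpy(dtype=float)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    clipped = np.clip(rounded, 0, max_count)
    df = pd.DataFrame(
        clipped, index=traits.data.index, columns=traits.data.columns
    )
    df[traits.data.isna()] = np.nan
    return TraitMatrix(df, mode="count")


def study_trait_keys(config: SectorConfig = DEFAULT_SECTOR_CONFIG) -> list[str]:
    return [
        TraitKey(wing, surface, s).encode()
        for wing in WINGS
        for surface in SURFACES
        for s in config.sectors(wing)
    ]


def study_correlation_matrix(
    rho_block: float = 0.8,
    rho_homology: float = 0.0,
    config: SectorConfig = DEFAULT_SECTOR_CONFIG,
) -> tuple[list[str], np.ndarray]:
    """Trait correlation matrix with (2,5) and (3,4) blocks per surface.

    Per wing the matrix is the Kronecker product of a 2x2 surface
    correlation (``rho_homology`` between dorsal and ventral) and an 8x8
    sector correlation (``rho_block`` between sectors 2-5 and 3-4, zero
    elsewhere); the two wings are independent.  A Kronecker product of
    correlation matrices is PSD by construction, so any valid
    (``|rho| <= 1``) combination of the two parameters is admissible;
    cross-surface non-homologous block pairs inherit the product
    ``rho_homology * rho_block``.
    """
    keys = study_trait_keys(config)
    blocks = []
    U = np.array([[1.0, rho_homology], [rho_homology, 1.0]])
    for wing in WINGS:
        sectors = config.sectors(wing)
        S = np.eye(len(sectors))
        pos = {s: i for i, s in enumerate(sectors)}
        for sa, sb in (("2", "5"), ("3", "4")):
            if sa in pos and sb in pos:
                S[pos[sa], pos[sb]] = S[pos[sb], pos[sa]] = rho_block
        blocks.append(np.kron(U, S))  # surfaces vary slower than sectors
    p = sum(b.shape[0] for b in blocks)
    R = np.zeros((p, p))
    at = 0
    for b in blocks:
        R[at : at + b.shape[0], at : at + b.shape[0]] = b
        at += b.shape[0]
    return keys, R


def generate_study_like_dataset(
    seed: int = 0,
    config: SimulationConfig | None = None,
    discretize: bool = True,
) -> tuple[PhyloTree, TraitMatrix]:
    """A 23-tip study-like dataset: tree plus trait matrix.

    The tree is a Yule ingroup (default 22 species) with one outgroup
    attached basally at a deep root (stem depth = ingroup depth, keeping
    the tree ultrametric), mirroring an analysis rooted on a single
    retained outgroup.  Traits follow the block-correlated BM model of
    :func:`study_correlation_matrix`; with ``discretize=True`` (default)
    they are rounded and clipped to counts in [0, max_count], with
    ``discretize=False`` the continuous Brownian values are returned.
    Note that discretization attenuates contrast-level correlations
    markedly (rounding behaves as unstructured measurement error, which
    dominates the shallowest contrasts), so designed correlations are
    recovered faithfully on the continuous variant and in attenuated
    form on the counts.
    """
    cfg = config or SimulationConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = SimulationConfig(**{**config.__dict__, "seed": seed})
    ingroup = simulate_yule_tree(
        cfg.n_ingroup, cfg.birth_rate, seed=cfg.seed, prefix="sp"
    )
    depth = ingroup.depth
    stem = cfg.outgroup_depth_factor * depth
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    out_tip = root.new_child(edge_length=depth + stem)
    out_tip.taxon = taxa.new_taxon(label="outgroup")
    sub = ingroup.dendropy_tree
    sub_root = sub.seed_node
    root.add_child(sub_root)
    sub_root.edge.length = stem
    for lf in sub.leaf_node_iter():
        lf.taxon = taxa.new_taxon(label=lf.taxon.label)
    full = PhyloTree(tree)

    keys, R = study_correlation_matrix(cfg.rho_block, cfg.rho_homology, cfg.sectors)
    sigma = cfg.tip_sd / math.sqrt(full.depth)
    continuous = simulate_bm_traits(
        full,
        keys,
        R,
        sigma=sigma,
        root_values=cfg.root_value,
        seed=cfg.seed + 1_000_003,
    )
    if not discretize:
        return full, continuous
    return full, discretize_counts(continuous, cfg.max_count)


# ---------------------------------------------------------------------------
# wing specimens
# ---------------------------------------------------------------------------

# template wing frame (arbitrary planar units, y-up): 4 vein-intersection
# landmarks, two anterior and two posterior, plus a straight F-P boundary
# polyline running through the posterior wing field
TEMPLATE_LANDMARKS = {
    "ant_prox": (0.05, 0.95),
    "ant_dist": (1.05, 0.85),
    "post_prox": (0.00, 0.05),
    "post_dist": (1.00, 0.00),
}
TEMPLATE_FP_BOUNDARY = np.array([[-0.15, 0.35], [0.55, 0.35], [1.25, 0.35]])

POSTERIOR_ANCHORS = ("post_prox", "post_dist")

_CLONE_BAND_HALFWIDTH = 0.15  # clone centres: |y - boundary| <= this
_CLONE_RADIUS = 0.08  # circumradius of the regular clone polygon
_CLONE_VERTICES = 32
_RESPECT_MARGIN = 0.02  # clearance kept when clipping to one side


def _clone_polygon(center: np.ndarray, radius: float, phase: float) -> np.ndarray:
    ang = phase + 2 * np.pi * np.arange(_CLONE_VERTICES) / _CLONE_VERTICES
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def clone_crossing_probability() -> float:
    """Analytic crossing probability in ``ignore`` mode.

    Clone centres are uniform in a band of half-width h around the
    straight boundary; a regular polygon of circumradius r crosses when
    the centre is closer than (approximately) r, so P = r_eff / h with
    r_eff the mean of circumradius and apothem.
    """
    r_eff = _CLONE_RADIUS * (1 + math.cos(math.pi / _CLONE_VERTICES)) / 2
    return r_eff / _CLONE_BAND_HALFWIDTH


def generate_wing_specimens(
    n: int,
    boundary_respect: str = "respect",
    seed: int = 0,
    landmark_noise: float = 0.002,
    clones_per_wing: int = 1,
) -> list[WingSpecimen]:
    """Synthetic digitized wings with clones, in per-specimen frames.

    Each wing is a randomly perturbed similarity transform (rotation,
    scale, translation) of the template landmark frame, with small
    Gaussian digitization noise on the landmarks.  Clones are regular
    polygons placed in a band straddling the template F-P boundary; in
    ``respect`` mode they are clipped to the side of the boundary their
    centre falls on (with a safety margin) before transformation, in
    ``ignore`` mode they are left unconstrained.  The first specimen is
    the untransformed template and carries the boundary polyline.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if boundary_respect not in ("respect", "ignore"):
        raise ValueError("boundary_respect must be 'respect' or 'ignore'")
    rng = np.random.default_rng(seed)
    y0 = TEMPLATE_FP_BOUNDARY[0, 1]
    halfplane_above = Polygon(
        [(-10, y0 + _RESPECT_MARGIN), (10, y0 + _RESPECT_MARGIN), (10, 10), (-10, 10)]
    )
    halfplane_below = Polygon(
        [(-10, y0 - _RESPECT_MARGIN), (10, y0 - _RESPECT_MARGIN), (10, -10), (-10, -10)]
    )
    specimens: list[WingSpecimen] = []
    for i in range(n):
        clones = []
        while len(clones) < clones_per_wing:
            cx = rng.uniform(0.15, 0.85)
            cy = y0 + rng.uniform(-_CLONE_BAND_HALFWIDTH, _CLONE_BAND_HALFWIDTH)
            poly = _clone_polygon(
                np.array([cx, cy]), _CLONE_RADIUS, rng.uniform(0, 2 * np.pi)
            )
            if boundary_respect == "respect":
                side = halfplane_above if cy >= y0 else halfplane_below
                clipped = Polygon(poly).intersection(side)
                if clipped.is_empty or clipped.geom_type != "Polygon":
                    continue
                if clipped.area < 1e-4:
                    continue
                poly = np.asarray(clipped.exterior.coords[:-1])
            clones.append(poly)

        if i == 0:  # reference: the template frame itself, with boundary
            specimens.append(
                WingSpecimen(
                    specimen_id="wing000",
                    landmarks=LandmarkSet(TEMPLATE_LANDMARKS),
                    clones=tuple(clones),
                    boundaries={"F-P": TEMPLATE_FP_BOUNDARY.copy()},
                )
            )
            continue
        angle = rng.uniform(-0.25, 0.25)
        scale = rng.uniform(0.85, 1.15)
        shift = rng.uniform(-0.2, 0.2, size=2)
        c, s = math.cos(angle), math.sin(angle)
        M = scale * np.array([[c, -s], [s, c]])

        def tf(pts: np.ndarray) -> np.ndarray:
            return np.asarray(pts) @ M.T + shift

        landmarks = {
            name: tf(np.asarray(xy))
            + rng.normal(0.0, landmark_noise * scale, size=2)
            for name, xy in TEMPLATE_LANDMARKS.items()
        }
        specimens.append(
            WingSpecimen(
                specimen_id=f"wing{i:03d}",
                landmarks=LandmarkSet(landmarks),
                clones=tuple(tf(c_) for c_ in clones),
            )
        )
    return specimens


def write_manifest(path: str, **entries) -> None:
    """Persist generator/run configuration so outputs are replayable."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
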