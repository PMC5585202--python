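"""Synthetic limb networks, random trees, and simulated trait evolution.

Real musculoskeletal adjacency matrices come from dissection; to make
every pipeline stage testable without such data, this module generates

* **limb-like networks** with a planted modular ground truth: a
  connected bone scaffold (serial proximo-distal chain of regions,
  optionally ending in five digit rays) plus muscles whose physical
  contacts — bone attachments and muscle–muscle contacts alike —
  fall preferentially within their own region (``p_in``) over other
  regions (``p_out``), every muscle keeping at least two bone
  attachments (origin + insertion); a planted-partition design whose
  true module labels are returned alongside the network;
* **pure-birth (Yule) trees**, ultrametric with exponential waiting
  times, standing in for a time-calibrated phylogeny;
* **Brownian-motion traits** evolved along a tree, optionally damped
  by Pagel's lambda.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .network import AnatomicalNetwork, AnatomicalNode, Tissue
from .phylo import bm_covariance, lambda_transform

__all__ = [
    "LimbGeneratorConfig",
    "PlantedTruth",
    "generate_limb_network",
    "generate_yule_tree",
    "yule_lineage_count",
    "simulate_bm",
]


@dataclass(frozen=True)
class LimbGeneratorConfig:
    """Settings for the planted-partition limb generator.

    Regions are ordered proximal to distal; each contributes
    ``bones_per_region`` serially chained bones and
    ``muscles_per_region`` muscles.  With ``digit_rays > 0`` the
    terminal region is instead a hand: ``digit_rays`` chains of
    ``ray_length`` bones branching from the last bone of the previous
    region.  Each muscle contacts any other node of its own region
    with probability ``p_in`` and nodes of other regions with
    ``p_out`` (requiring ``0 <= p_out < p_in <= 1``); its bone
    attachments are redrawn until there are at least two (origin and
    insertion).  The defaults give networks of roughly 100 nodes, the
    size of a real forelimb network.
    """

    n_regions: int = 5
    bones_per_region: int = 4
    muscles_per_region: int = 14
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0
    digit_rays: int = 5
    ray_length: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_regions < 1 or self.bones_per_region < 1:
            raise ValueError("need at least one region with at least one bone")
        if self.muscles_per_region < 1:
            raise ValueError("need at least one muscle per region")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth node → region assignment of a generated network."""

    assignment: dict[str, int] = field(default_factory=dict)

    def labels_for(self, node_ids: list[str]) -> list[int]:
        return [self.assignment[v] for v in node_ids]


def generate_limb_network(
    cfg: LimbGeneratorConfig,
) -> tuple[AnatomicalNetwork, PlantedTruth]:
    """Generate a limb-like network with planted modules.

    The bone scaffold is deterministic (serial chains, one articulation
    between adjacent regions, digit rays in the terminal region);
    muscle attachments are random.  Returns the network and the true
    region of every node.  Raises if a muscle cannot reach two bone
    attachments after bounded retries (e.g. one-bone regions with
    ``p_out = 0``).
    """
    rng = np.random.default_rng(cfg.seed)
    nodes: list[AnatomicalNode] = []
    edges: set[tuple[str, str]] = set()
    truth: dict[str, int] = {}
    region_bones: list[list[str]] = []

    def add_edge(a: str, b: str) -> None:
        edges.add((a, b) if a < b else (b, a))

    n_chain_regions = cfg.n_regions - 1 if cfg.digit_rays > 0 else cfg.n_regions
    prev_last: str | None = None
    for r in range(n_chain_regions):
        bones = [f"bone:r{r}b{i}" for i in range(cfg.bones_per_region)]
        for i, b in enumerate(bones):
            nodes.append(AnatomicalNode(b, Tissue.BONE, region=f"region{r}"))
            truth[b] = r
            if i > 0:
                add_edge(bones[i - 1], b)
        if prev_last is not None:
            add_edge(prev_last, bones[0])
        prev_last = bones[-1]
        region_bones.append(bones)

    if cfg.digit_rays > 0:
        r = cfg.n_regions - 1
        bones = []
        for ray in range(cfg.digit_rays):
            prev = prev_last  # rays branch from the most distal chain bone
            for seg in range(cfg.ray_length):
                b = f"bone:r{r}d{ray}p{seg}"
                nodes.append(AnatomicalNode(b, Tissue.BONE, region=f"region{r}"))
                truth[b] = r
                if prev is not None:
                    add_edge(prev, b)
                prev = b
                bones.append(b)
        region_bones.append(bones)

    all_bones = [b for bones in region_bones for b in bones]
    muscles: list[str] = []
    for r in range(cfg.n_regions):
        for mi in range(cfg.muscles_per_region):
            m = f"muscle:r{r}m{mi}"
            nodes.append(AnatomicalNode(m, Tissue.MUSCLE, region=f"region{r}"))
            truth[m] = r
            muscles.append(m)

    # muscle-muscle physical contacts follow the planted partition
    for i, m1 in enumerate(muscles):
        for m2 in muscles[i + 1:]:
            p = cfg.p_in if truth[m1] == truth[m2] else cfg.p_out
            if rng.random() < p:
                add_edge(m1, m2)

    # bone attachments: redrawn until each muscle has its origin and
    # insertion (>= 2 bones)
    for m in muscles:
        own = region_bones[truth[m]]
        other = [b for b in all_bones if truth[b] != truth[m]]
        for _attempt in range(1000):
            attach = [b for b in own if rng.random() < cfg.p_in]
            attach += [b for b in other if rng.random() < cfg.p_out]
            if len(attach) >= 2:
                break
        else:
            raise ValueError(
                f"muscle {m} could not attach to 2 bones after 1000 draws; "
                "raise p_in/p_out or bones_per_region"
            )
        for b in attach:
            add_edge(m, b)

    net = AnatomicalNetwork(nodes, edges, name=f"synthetic_limb_seed{cfg.seed}")
    assert len(all_bones) + len(muscles) == net.n_nodes
    return net, PlantedTruth(assignment=truth)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def generate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` tips.

    Starts from two lineages at the root; each waiting time is
    exponential with rate ``birth_rate * k`` for ``k`` current
    lineages, and a uniformly chosen lineage splits.  After the last
    split all lineages are extended by one further exponential waiting
    time, so the tree is ultrametric with strictly positive terminal
    branches.  Tips are labelled T1..Tn.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))

    now = 0.0
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.edge.length = now - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, now))

    present = now + rng.exponential(1.0 / (birth_rate * len(active)))
    for i, (node, birth) in enumerate(active, start=1):
        node.edge.length = present - birth
        node.taxon = taxa.new_taxon(label=f"T{i}")
    root.edge.length = None
    tree.is_rooted = True
    return tree


def yule_lineage_count(birth_rate: float, time: float, seed: int | None = None) -> int:
    """Number of lineages of a pure-birth process run to a fixed time.

    Starting from a single lineage, the expectation is
    ``exp(birth_rate * time)``.
    """
    rng = np.random.default_rng(seed)
    k = 1
    now = 0.0
    while True:
        now += rng.exponential(1.0 / (birth_rate * k))
        if now > time:
            return k
        k += 1


# ---------------------------------------------------------------------------
# trait evolution
# ---------------------------------------------------------------------------

def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    root: float = 0.0,
    lam: float = 1.0,
    seed: int | None = None,
) -> dict[str, float]:
    """Simulate a continuous trait on a tree.

    With ``lam = 1`` (plain Brownian motion) the trait is evolved
    recursively: each child state is its parent's state plus a normal
    increment of variance ``sigma2 * branch length``.  With
    ``lam < 1`` tips are drawn jointly from the multivariate normal
    with the lambda-transformed covariance (off-diagonals scaled by
    ``lam``), which at ``lam = 0`` makes tips independent.  Returns a
    taxon → value mapping.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels, cov = bm_covariance(tree)

    if sigma2 == 0:
        return {label: float(root) for label in labels}

    if lam == 1.0:
        states: dict[dendropy.Node, float] = {}
        out: dict[str, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                states[node] = float(root)
            else:
                bl = node.edge.length or 0.0
                states[node] = states[node.parent_node] + rng.normal(
                    0.0, np.sqrt(sigma2 * bl)
                )
            if node.is_leaf():
                out[node.taxon.label] = states[node]
        return out

    cl = lambda_transform(cov, lam) * sigma2
    chol = np.linalg.cholesky(cl + 1e-12 * np.eye(len(labels)))
    draw = root + chol @ rng.standard_normal(len(labels))
    return {label: float(v) for label, v in zip(labels, draw)}
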