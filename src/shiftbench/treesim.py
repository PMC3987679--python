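"""Tree representation of spectra and the recursive tree similarity.

A spectrum is summarised by recursively bisecting its window at the
intensity centre of mass: each node records the mass (fraction of total
intensity) and centre of mass of its region, and splits into two children
tiling the region at the centre of mass.  Signal-rich regions are therefore
resolved deeply while blank or noisy zones collapse into low-mass leaves.

Two trees are compared depth-wise: the similarity at depth k combines the
similarity of the nodes at that level with the similarity of the subtrees at
depth k+1, through a recursion weight w.  The node kernel is
``exp(-|dcom| / alpha) * min(mass)/max(mass)``, which is 1 exactly when both
centre of mass and mass agree.

A classical binning baseline (cosine similarity of binned profiles) is
provided for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .spectra_io import (
    DegenerateSpectrumError,
    Spectrum,
    bin_spectrum,
    normalize_total,
)


@dataclass(frozen=True)
class TreeParams:
    """Parameters of tree construction and tree similarity.

    max_depth:    maximum recursion depth of the bisection (root at depth 0)
    min_mass:     intensity fraction below which a node becomes a leaf
    min_width:    region width (ppm) below which a node becomes a leaf;
                  None resolves to 2 grid steps of the spectrum at build time
    level_weight: weight w in (0,1) of the current level's node similarity
                  against the mean similarity of the subtrees one level deeper
    com_scale:    decay scale alpha (ppm) of the centre-of-mass kernel
    noise_floor:  fraction of the maximum intensity below which points are
                  zeroed before tree building
    """

    max_depth: int = 8
    min_mass: float = 0.01
    min_width: Optional[float] = None
    level_weight: float = 0.5
    com_scale: float = 0.1
    noise_floor: float = 0.005

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0.0 < self.level_weight < 1.0:
            raise ValueError("level_weight must be in (0, 1)")
        if self.com_scale <= 0:
            raise ValueError("com_scale must be positive")
        if self.min_mass < 0 or self.noise_floor < 0:
            raise ValueError("min_mass and noise_floor must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TreeParams":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TreeParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TreeNode:
    """A node of the spectrum tree over the ppm region (lo, hi)."""

    lo: float
    hi: float
    mass: float
    com: float
    children: Optional[tuple["TreeNode", "TreeNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def to_dict(self) -> dict:
        d = {"lo": self.lo, "hi": self.hi, "mass": self.mass, "com": self.com}
        if self.children is not None:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_tree(s: Spectrum, p: TreeParams = TreeParams()) -> TreeNode:
    """Build the centre-of-mass bisection tree of a unit-total spectrum.

    The root covers the full window.  A node splits at its centre of mass
    into the high-ppm region (com, hi) — grid centres strictly above com —
    and the low-ppm region (lo, com), unless it has reached ``max_depth``,
    its mass falls below ``min_mass``, or its width below ``min_width``.
    A node whose centre of mass coincides with a region edge cannot make
    progress by splitting and becomes a leaf.
    """
    total = s.total()
    if total <= 0:
        raise DegenerateSpectrumError(
            f"spectrum '{s.molecule_id}' has zero mass; cannot build tree"
        )
    grid = s.ppm_grid()
    # prefix sums over descending-ppm order; csum[j] - csum[i] = mass of [i, j)
    csum = np.concatenate(([0.0], np.cumsum(s.intensities)))
    wsum = np.concatenate(([0.0], np.cumsum(s.intensities * grid)))
    min_width = p.min_width if p.min_width is not None else 2.0 * s.delta
    neg_grid = -grid  # ascending, for searchsorted

    def node(i: int, j: int, lo: float, hi: float, depth: int) -> TreeNode:
        mass = float(csum[j] - csum[i])
        if mass > 0:
            com = float((wsum[j] - wsum[i]) / mass)
            com = min(max(com, lo), hi)
        else:
            com = 0.5 * (lo + hi)
        stop = (
            depth >= p.max_depth
            or mass < p.min_mass
            or (hi - lo) < min_width
            or com >= hi
            or com <= lo
        )
        if stop:
            return TreeNode(lo, hi, mass, com)
        # first index with grid[k] <= com; [i, k) lies strictly above com
        k = int(np.searchsorted(neg_grid[i:j], -com, side="left")) + i
        left = node(i, k, com, hi, depth + 1)
        right = node(k, j, lo, com, depth + 1)
        return TreeNode(lo, hi, mass, com, (left, right))

    return node(0, s.n_points, s.ppm_min, s.ppm_max, 0)


def node_similarity(a: TreeNode, b: TreeNode, p: TreeParams = TreeParams()) -> float:
    """Similarity in [0,1] of two nodes from com distance and mass ratio.

    Empty matches empty (both masses zero -> 1); an empty node never matches
    a non-empty one (-> 0).
    """
    if a.mass <= 0.0 and b.mass <= 0.0:
        return 1.0
    if a.mass <= 0.0 or b.mass <= 0.0:
        return 0.0
    mass_ratio = min(a.mass, b.mass) / max(a.mass, b.mass)
    return math.exp(-abs(a.com - b.com) / p.com_scale) * mass_ratio


def tree_similarity(a: TreeNode, b: TreeNode, p: TreeParams = TreeParams()) -> float:
    """Recursive depth-wise similarity of two spectrum trees, in [0,1].

    At each level the node similarity is mixed with the mean similarity of
    the paired subtrees one level deeper using weight ``level_weight``.  When
    only one side has children, the leaf is compared as a node against each
    child subtree, so a region that stops splitting in one spectrum degrades
    smoothly instead of scoring zero.
    """
    if not (
        math.isclose(a.lo, b.lo, rel_tol=0, abs_tol=1e-9)
        and math.isclose(a.hi, b.hi, rel_tol=0, abs_tol=1e-9)
    ):
        raise ValueError(
            f"trees cover different windows: ({a.lo}, {a.hi}) vs ({b.lo}, {b.hi})"
        )
    w = p.level_weight
    alpha = p.com_scale

    def node_sim(x: TreeNode, y: TreeNode) -> float:
        if x.mass <= 0.0 and y.mass <= 0.0:
            return 1.0
        if x.mass <= 0.0 or y.mass <= 0.0:
            return 0.0
        ratio = min(x.mass, y.mass) / max(x.mass, y.mass)
        return math.exp(-abs(x.com - y.com) / alpha) * ratio

    def sim(x: TreeNode, y: TreeNode) -> float:
        ns = node_sim(x, y)
        if x.children is None and y.children is None:
            return ns
        xl, xr = x.children if x.children is not None else (x, x)
        yl, yr = y.children if y.children is not None else (y, y)
        deeper = 0.5 * (sim(xl, yl) + sim(xr, yr))
        return w * ns + (1.0 - w) * deeper

    return sim(a, b)


def apply_noise_floor(s: Spectrum, noise_floor: float) -> Spectrum:
    """Zero intensities below ``noise_floor`` x max and renormalise to 1."""
    if noise_floor <= 0:
        return s
    floor = noise_floor * float(s.intensities.max())
    kept = np.where(s.intensities >= floor, s.intensities, 0.0)
    if kept.sum() <= 0:
        raise DegenerateSpectrumError(
            f"spectrum '{s.molecule_id}' is all noise below the noise floor"
        )
    return normalize_total(s.with_intensities(kept))


def prepare_tree(s: Spectrum, p: TreeParams = TreeParams()) -> TreeNode:
    """Normalise, apply the noise floor, and build the spectrum tree."""
    return build_tree(apply_noise_floor(normalize_total(s), p.noise_floor), p)


def spectrum_similarity(
    s1: Spectrum, s2: Spectrum, p: TreeParams = TreeParams()
) -> float:
    """Tree similarity of two spectra on the same grid."""
    if not s1.same_grid(s2):
        raise ValueError(
            f"spectra '{s1.molecule_id}' and '{s2.molecule_id}' are on different grids"
        )
    return tree_similarity(prepare_tree(s1, p), prepare_tree(s2, p), p)


def binning_similarity(s1: Spectrum, s2: Spectrum, n_bins: int = 256) -> float:
    """Cosine similarity of the n_bins-binned, normalised intensity profiles."""
    if not (
        math.isclose(s1.ppm_max, s2.ppm_max, abs_tol=1e-9)
        and math.isclose(s1.ppm_min, s2.ppm_min, abs_tol=1e-9)
    ):
        raise ValueError("spectra cover different windows")
    v1 = bin_spectrum(normalize_total(s1), n_bins).intensities
    v2 = bin_spectrum(normalize_total(s2), n_bins).intensities
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateSpectrumError("zero-norm binned profile")
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), 0.0, 1.0))
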