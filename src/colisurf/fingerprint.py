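"""Genomic fingerprint similarity, clustering and strain screening.

Works on ladder-normalized (GTG)5 rep-PCR band profiles: each strain is a
set of fragment sizes (bp) with densitometric intensities.  Pairwise
similarity is the curve-based Pearson coefficient used by gel-analysis
software: profiles are rasterized onto a common log-size grid as
Gaussian-smoothed densitometric curves (the band-matching *tolerance* sets
the kernel width) and the correlation is maximized over small global shifts
(the *optimization* value).  Strains above a similarity threshold are
treated as the same genotype and collapsed to one representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BandProfile",
    "SimilarityMatrix",
    "Dendrogram",
    "MarkerProfile",
    "DEFAULT_MIN_BP",
    "DEFAULT_MAX_BP",
    "filter_bands",
    "rasterize_profile",
    "profile_similarity",
    "similarity_matrix",
    "upgma",
    "select_distinct",
    "assign_phylotype",
]

#: Fragment-size window retained for analysis; bands outside are gel artefacts.
DEFAULT_MIN_BP = 300.0
DEFAULT_MAX_BP = 5000.0

#: Raster resolution for densitometric curves (points, uniform in log10 bp).
GRID_POINTS = 1000


@dataclass(frozen=True)
class BandProfile:
    """One strain's fingerprint: fragment sizes (bp, increasing) + intensities."""

    strain_id: str
    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.shape != pos.shape:
            raise ValueError("positions and intensities must be 1-D and equal length")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("band positions must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("band intensities must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def n_bands(self) -> int:
        return int(self.positions.size)


class EmptyProfileError(ValueError):
    """No bands remain after size filtering; strain must be excluded."""


def filter_bands(
    profile: BandProfile,
    min_bp: float = DEFAULT_MIN_BP,
    max_bp: float = DEFAULT_MAX_BP,
) -> BandProfile:
    """Drop bands outside the analysis window.

    The window is closed: bands sitting exactly on 300 or 5000 bp are kept
    (only fragments strictly outside are discarded as false-clustering
    artefacts).  Raises :class:`EmptyProfileError` when nothing survives.
    """
    keep = (profile.positions >= min_bp) & (profile.positions <= max_bp)
    if not np.any(keep):
        raise EmptyProfileError(
            f"strain {profile.strain_id!r}: no bands in [{min_bp}, {max_bp}] bp"
        )
    return BandProfile(profile.strain_id, profile.positions[keep], profile.intensities[keep])


def _log_grid(min_bp: float, max_bp: float, n: int = GRID_POINTS) -> np.ndarray:
    return np.linspace(np.log10(min_bp), np.log10(max_bp), n)


def rasterize_profile(
    profile: BandProfile,
    tolerance: float = 0.005,
    min_bp: float = DEFAULT_MIN_BP,
    max_bp: float = DEFAULT_MAX_BP,
    n_grid: int = GRID_POINTS,
) -> np.ndarray:
    """Render a band profile as a smoothed densitometric curve.

    Bands become Gaussians centred at log10(size) with standard deviation
    ``tolerance * span`` where span is the width of the log-size window, so
    the band-matching tolerance is expressed as a fraction of the lane.
    """
    grid = _log_grid(min_bp, max_bp, n_grid)
    span = grid[-1] - grid[0]
    sigma = tolerance * span
    centers = np.log10(profile.positions)
    # (n_bands, n_grid) Gaussian bump per band, intensity-weighted.
    d = grid[None, :] - centers[:, None]
    curve = (profile.intensities[:, None] * np.exp(-0.5 * (d / sigma) ** 2)).sum(axis=0)
    return curve


def _standardize(curve: np.ndarray) -> np.ndarray:
    sd = curve.std()
    if sd == 0:
        raise ValueError("degenerate densitometric curve (zero variance)")
    return (curve - curve.mean()) / sd


def _shift_search_range(optimization: float, n_grid: int) -> int:
    return int(round(optimization * n_grid))


def profile_similarity(
    a: BandProfile,
    b: BandProfile,
    tolerance: float = 0.005,
    optimization: float = 0.005,
    min_bp: float = DEFAULT_MIN_BP,
    max_bp: float = DEFAULT_MAX_BP,
) -> float:
    """Curve-based Pearson similarity between two fingerprints, in [-1, 1].

    The correlation is maximized over circular shifts of up to
    ``optimization`` (as a fraction of the lane) in either direction; a
    circular shift keeps the statistic exactly symmetric in its arguments.
    """
    ca = rasterize_profile(a, tolerance, min_bp, max_bp)
    cb = rasterize_profile(b, tolerance, min_bp, max_bp)
    za = _standardize(ca)
    zb = _standardize(cb)
    if np.array_equal(ca, cb):
        return 1.0  # identical densitometric curves correlate exactly
    n = za.size
    m = _shift_search_range(optimization, n)
    best = -1.0
    for k in range(-m, m + 1):
        r = float(np.dot(za, np.roll(zb, k)) / n)
        best = max(best, r)
    return min(best, 1.0)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity with unit diagonal and entries in [-1, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [-1, 1]")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="strain_id")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def _pairwise_from_rasters(curves: np.ndarray, m: int) -> np.ndarray:
    """Max-over-shifts Pearson between all rows of a (n, grid) curve stack."""
    n, g = curves.shape
    sds = curves.std(axis=1)
    if np.any(sds == 0):
        raise ValueError("degenerate densitometric curve (zero variance)")
    z = (curves - curves.mean(axis=1, keepdims=True)) / sds[:, None]
    best = np.full((n, n), -1.0)
    for k in range(-m, m + 1):
        zk = np.roll(z, k, axis=1)
        best = np.maximum(best, (z @ zk.T) / g)
    s = np.maximum(best, best.T)  # roll symmetry holds; guard against roundoff
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


def similarity_matrix(
    profiles: Sequence[BandProfile],
    tolerance: float = 0.005,
    optimization: float = 0.005,
    min_bp: float = DEFAULT_MIN_BP,
    max_bp: float = DEFAULT_MAX_BP,
) -> SimilarityMatrix:
    """All-pairs fingerprint similarity.

    Strains with no bands left after size filtering are excluded with a
    warning (they cannot be placed in the similarity analysis).
    """
    kept: list[BandProfile] = []
    for p in profiles:
        try:
            kept.append(filter_bands(p, min_bp, max_bp))
        except EmptyProfileError:
            warnings.warn(
                f"strain {p.strain_id!r} has no bands in the size window; "
                "excluded from similarity analysis",
                stacklevel=2,
            )
    if len(kept) < 2:
        raise ValueError("need at least two strains with usable profiles")
    curves = np.stack(
        [rasterize_profile(p, tolerance, min_bp, max_bp) for p in kept]
    )
    m = _shift_search_range(optimization, curves.shape[1])
    s = _pairwise_from_rasters(curves, m)
    return SimilarityMatrix([p.strain_id for p in kept], s)


# ---------------------------------------------------------------------------
# UPGMA clustering


@dataclass
class DendrogramNode:
    height: float
    label: str | None = None  # leaf label
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:  # type: ignore[union-attr]
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Rooted ultrametric tree from UPGMA; merge heights are dissimilarities."""

    root: DendrogramNode
    merges: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def merge_heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Newick string; branch length = parent height − child height."""

        def rec(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(rec(c, node.height) for c in node.children)  # type: ignore[union-attr]
            return f"({inner}):{bl:.10g}"

        a, b = self.root.children  # type: ignore[misc]
        body = ",".join(rec(c, self.root.height) for c in (a, b))
        return f"({body});"


def upgma(s: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration on dissimilarity d = 1 − s.

    Cluster pairs are merged at the size-weighted average dissimilarity.
    Ties are broken deterministically: among all minimal-distance pairs the
    lexicographically smallest (cluster-label, cluster-label) pair merges
    first, where a cluster is labelled by its smallest member id.
    """
    n = len(s)
    if n < 2:
        raise ValueError("UPGMA needs at least two strains")
    d = 1.0 - s.values
    # active clusters: key -> (node, member index set, label = min strain id)
    clusters: dict[int, tuple[DendrogramNode, frozenset, str]] = {
        i: (DendrogramNode(0.0, label=s.labels[i]), frozenset([i]), s.labels[i])
        for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_key = n
    while len(clusters) > 1:
        best_pair = None
        best_d = np.inf
        best_labels = None
        for (i, j), dij in dist.items():
            lab = tuple(sorted((clusters[i][2], clusters[j][2])))
            if dij < best_d - 1e-15 or (
                abs(dij - best_d) <= 1e-15 and (best_labels is None or lab < best_labels)
            ):
                best_d = dij
                best_pair = (i, j)
                best_labels = lab
        i, j = best_pair  # type: ignore[misc]
        node_i, mem_i, lab_i = clusters.pop(i)
        node_j, mem_j, lab_j = clusters.pop(j)
        height = max(best_d, node_i.height, node_j.height)  # guard non-decreasing
        # put the lexicographically smaller cluster first for determinism
        if lab_j < lab_i:
            node_i, node_j = node_j, node_i
        new_node = DendrogramNode(height, children=(node_i, node_j))
        members_by_id_i = frozenset(s.labels[k] for k in mem_i)
        members_by_id_j = frozenset(s.labels[k] for k in mem_j)
        merges.append((members_by_id_i, members_by_id_j, height))
        new_mem = mem_i | mem_j
        ni, nj = len(mem_i), len(mem_j)
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), val in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = val
        for k in clusters:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[(min(k, next_key), max(k, next_key))] = (ni * dik + nj * djk) / (ni + nj)
        clusters[next_key] = (new_node, new_mem, min(lab_i, lab_j))
        dist = new_dist
        next_key += 1
    (root, _, _), = clusters.values()
    return Dendrogram(root=root, merges=merges)


def select_distinct(s: SimilarityMatrix, threshold: float = 0.90) -> list[str]:
    """Collapse near-identical strains; return one representative per genotype.

    Strains connected (single linkage) by pairwise similarity ≥ ``threshold``
    are considered the same genotype; the representative is the lowest strain
    id of the component.  Strains below the threshold to everything are each
    their own genotype.
    """
    n = len(s)
    adj = (s.values >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 1)
    n_comp, assignment = connected_components(csr_matrix(adj), directed=False)
    reps: list[str] = []
    for c in range(n_comp):
        members = [s.labels[i] for i in range(n) if assignment[i] == c]
        reps.append(min(members))
    return sorted(reps)


# ---------------------------------------------------------------------------
# Phylotyping (quadruplex marker lookup)


@dataclass(frozen=True)
class MarkerProfile:
    """Quadruplex PCR marker presence plus optional confirmation screens.

    ``group_c`` / ``group_e`` are the allele-specific confirmation tests used
    to resolve the ambiguous quadruplex genotypes; each is ``"positive"``,
    ``"negative"`` or ``"untested"``.
    """

    arpA: bool
    chuA: bool
    yjaA: bool
    tspE4: bool
    group_c: str = "untested"
    group_e: str = "untested"

    def __post_init__(self) -> None:
        for f in (self.group_c, self.group_e):
            if f not in ("positive", "negative", "untested"):
                raise ValueError("confirmation results must be positive/negative/untested")


def assign_phylotype(m: MarkerProfile) -> str:
    """Assign a phylogroup from the quadruplex genotype.

    Returns one of ``A, B1, B2, F, A/C, D/E, E, clade, unknown``.  Ambiguous
    genotypes without the relevant confirmation screen keep the composite
    labels ``A/C`` and ``D/E``; contradictory confirmations give ``unknown``.
    """
    if m.group_c == "positive" and m.group_e == "positive":
        return "unknown"  # contradictory screens
    g = (m.arpA, m.chuA, m.yjaA, m.tspE4)
    if g[0] and not g[1]:
        # arpA+ chuA-: A vs B1 split on TspE4.C2
        return "B1" if g[3] else "A"
    if not g[0] and g[1]:
        # arpA- chuA+: B2 when either yjaA or TspE4.C2 present, else F
        return "B2" if (g[2] or g[3]) else "F"
    if g[0] and g[1]:
        if not g[2] and not g[3]:
            # A or C; the C-specific screen resolves it
            if m.group_c == "positive":
                return "A/C"
            if m.group_c == "negative":
                return "A"
            return "A/C"
        if g[2] and g[3]:
            # E or cryptic clade I
            if m.group_e == "positive":
                return "E"
            if m.group_e == "negative":
                return "clade"
            return "unknown"
        # (+,+,-,+) or (+,+,+,-): D or E
        if m.group_e == "positive":
            return "E"
        return "D/E"
    # arpA- chuA-
    if g[2] and not g[3]:
        return "clade"
    return "unknown"
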