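"""Pairwise architecture similarity, ordination and Type assignment.

The computational core that defines cluster "Types": domain architectures
are compared by exact global (Needleman-Wunsch) alignment of domain tokens,
converted to a dissimilarity d = 1 - matches/alignment_length, ordinated by
non-metric MDS (Kruskal stress-1, seeded multi-start SMACOF with isotonic
regression) and clustered by average group linkage (UPGMA).  New clusters
are assigned to the catalog Type whose template is nearest in collapsed-ACP
token space, honouring each template's ACP copy-number range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .model import (Catalog, DomainKind, GeneCluster, TemplateDomain,
                    TypeDefinition, ValidationError, collapse_acp_runs)


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """A global alignment of two token sequences (None marks a gap)."""

    a: tuple
    b: tuple
    score: float
    n_matches: int

    @property
    def length(self) -> int:
        return len(self.a)


def align_tokens(a: Sequence, b: Sequence,
                 scoring: Scoring = DEFAULT_SCORING,
                 eq: Callable = None) -> Alignment:
    """Optimal global alignment of two token sequences.

    Ties are broken deterministically during traceback: diagonal move first,
    then gap in ``b`` (consume from ``a``), then gap in ``a``.  ``eq`` lets
    callers redefine token equality (used for ACP copy-number ranges).
    """
    if len(a) == 0 and len(b) == 0:
        raise ValidationError("cannot align two empty sequences")
    eq = eq or (lambda x, y: x == y)
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1))
    S[:, 0] = scoring.gap * np.arange(n + 1)
    S[0, :] = scoring.gap * np.arange(m + 1)
    match = np.empty((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            match[i, j] = eq(a[i], b[j])
            diag = S[i, j] + (scoring.match if match[i, j] else scoring.mismatch)
            S[i + 1, j + 1] = max(diag, S[i, j + 1] + scoring.gap,
                                  S[i + 1, j] + scoring.gap)
    # traceback with fixed move priority
    out_a, out_b = [], []
    i, j = n, m
    n_matches = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = S[i - 1, j - 1] + (scoring.match if match[i - 1, j - 1]
                                      else scoring.mismatch)
            if S[i, j] == diag:
                i, j = i - 1, j - 1
                out_a.append(a[i]); out_b.append(b[j])
                n_matches += match[i, j]
                continue
        if i > 0 and S[i, j] == S[i - 1, j] + scoring.gap:
            i -= 1
            out_a.append(a[i]); out_b.append(None)
            continue
        j -= 1
        out_a.append(None); out_b.append(b[j])
    return Alignment(a=tuple(reversed(out_a)), b=tuple(reversed(out_b)),
                     score=float(S[n, m]), n_matches=int(n_matches))


def _tokens(cluster: GeneCluster, mode: str) -> tuple:
    kinds = cluster.domain_kinds
    if not kinds:
        raise ValidationError(f"cluster {cluster.cluster_id} has no domains")
    if mode == "raw":
        return tuple(kinds)
    if mode == "collapsed":
        # run lengths are dropped: collapsed ACP tokens compare equal
        # regardless of copy number
        return tuple(k for k, _run in collapse_acp_runs(kinds))
    raise ValueError(f"unknown mode {mode!r}")


def architecture_distance(a: GeneCluster, b: GeneCluster,
                          mode: str = "raw",
                          scoring: Scoring = DEFAULT_SCORING) -> float:
    """Architecture dissimilarity d = 1 - n_matches/alignment_length in [0,1]."""
    aln = align_tokens(_tokens(a, mode), _tokens(b, mode), scoring=scoring)
    return 1.0 - aln.n_matches / aln.length


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix over labelled items."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def submatrix(self, idx: Sequence[int]) -> "DistanceMatrix":
        idx = list(idx)
        return DistanceMatrix(labels=tuple(self.labels[i] for i in idx),
                              values=self.values[np.ix_(idx, idx)])

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().rstrip("\n").split("\t")
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(labels=tuple(labels), values=np.array(rows))


def pairwise_distances(clusters: Sequence[GeneCluster], mode: str = "raw",
                       scoring: Scoring = DEFAULT_SCORING) -> DistanceMatrix:
    """All-against-all architecture distances (symmetric, zero diagonal)."""
    if len(clusters) < 2:
        raise ValidationError("need at least two clusters")
    labels = [c.cluster_id for c in clusters]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate cluster_ids")
    toks = [_tokens(c, mode) for c in clusters]
    n = len(clusters)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_tokens(toks[i], toks[j], scoring=scoring)
            D[i, j] = D[j, i] = 1.0 - aln.n_matches / aln.length
    return DistanceMatrix(labels=tuple(labels), values=D)


# ---------------------------------------------------------------------------
# non-metric MDS (Kruskal stress-1)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    n_starts: int
    best_start_seed: int
    stress_history: list[float] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stress\t{self.stress:.10f}\n")
            fh.write(f"# n_starts\t{self.n_starts}\n")
            k = self.coordinates.shape[1]
            fh.write("label\t" + "\t".join(f"axis{i+1}" for i in range(k)) + "\n")
            for label, row in zip(self.labels, self.coordinates):
                fh.write(label + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")


def _stress1(dhat: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(disp ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - disp) ** 2) / denom))


def _smacof_start(D: np.ndarray, k: int, rng: np.random.Generator,
                  max_iter: int, min_stress: float,
                  rtol: float = 1e-6) -> tuple[np.ndarray, float, list[float]]:
    n = D.shape[0]
    d = squareform(D, checks=False)
    order = np.argsort(d, kind="stable")
    X = rng.normal(size=(n, k))
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        dhat = pdist(X)
        dhat = np.maximum(dhat, 1e-12)
        # monotone (isotonic) regression of configuration distances on
        # dissimilarity rank order gives the disparities d*
        disp = np.empty_like(dhat)
        disp[order] = isotonic_regression(dhat[order]).x
        # rescale so the disparity norm tracks the configuration norm
        disp *= np.sqrt(np.sum(dhat ** 2) / np.sum(disp ** 2))
        stress = _stress1(dhat, disp)
        history.append(stress)
        if stress < min_stress or (np.isfinite(prev) and
                                   abs(prev - stress) < rtol * max(prev, 1e-12)):
            break
        prev = stress
        # Guttman transform toward the disparities
        ratio = squareform(disp / dhat, checks=False)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
        X -= X.mean(axis=0)
    return X, history[-1], history


def nmds(dist: DistanceMatrix, k: int = 2, n_starts: int = 25,
         min_stress: float = 0.01, max_iter: int = 300,
         seed: int = 0) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal's stress-1.

    The configuration with the lowest stress over ``n_starts`` seeded random
    starts is returned.  Start seeds are derived from the master seed and the
    start index after sorting labels canonically, so the result is invariant
    to input label order and bit-reproducible for a given seed.
    """
    if k >= dist.n:
        raise ValidationError(f"k={k} must be < number of items ({dist.n})")
    sort_idx = np.argsort(np.array(dist.labels))
    ds = dist.submatrix(sort_idx)
    best = None
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, start]))
        X, stress, history = _smacof_start(ds.values, k, rng, max_iter, min_stress)
        if best is None or stress < best[1]:
            best = (X, stress, history, start)
        if stress < min_stress:
            break
    X, stress, history, start = best
    # return rows in the caller's original label order
    inverse = np.empty(dist.n, dtype=int)
    inverse[sort_idx] = np.arange(dist.n)
    return OrdinationResult(labels=dist.labels, coordinates=X[inverse],
                            stress=stress, n_starts=n_starts,
                            best_start_seed=start, stress_history=history)


# ---------------------------------------------------------------------------
# average-linkage (UPGMA) clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge tree; ``linkage`` is a scipy hierarchical linkage matrix."""

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, height: float) -> dict[str, int]:
        """Group labels obtained by cutting all merges above ``height``."""
        flat = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return dict(zip(self.labels, (int(g) for g in flat)))

    def cut_k(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(g) for g in flat)))

    def to_newick(self) -> str:
        """Newick string; branch lengths are differences of merge heights
        (leaves sit at height zero, so the tree is ultrametric)."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i].replace(" ", "_")
            row = self.linkage[i - n]
            left, right, h = int(row[0]), int(row[1]), row[2]
            parts = []
            for child in (left, right):
                parts.append(f"{node(child)}:{h - heights[child]:.6f}")
            heights[i] = h
            return "(" + ",".join(parts) + ")"

        for i in range(n, 2 * n - 1):
            row = self.linkage[i - n]
            heights[i] = row[2]
        return node(2 * n - 2) + ";"


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA (unweighted average group linkage) clustering."""
    if dist.n < 2:
        raise ValidationError("need at least two items to cluster")
    Z = hierarchy.linkage(dist.condensed(), method="average")
    return Dendrogram(labels=dist.labels, linkage=Z)


# ---------------------------------------------------------------------------
# Type assignment
# ---------------------------------------------------------------------------

@dataclass
class TypeAssignment:
    cluster_id: str
    best_type: str
    distance_to_best: float
    runner_up: str | None
    margin: float


def _template_token_eq(cluster_token: tuple[DomainKind, int],
                       template_token: TemplateDomain) -> bool:
    """Token compatibility for cluster-vs-template comparison.

    An ACP run is compatible with a template's copy-number range whenever
    it does not exceed the range maximum: any run inside [min, max] is
    compatible, and a run below the minimum is also accepted because
    fragmented or partially lost tandem-ACP runs are common and only the
    Type's upper copy-number bound is diagnostic.
    """
    kind, run = cluster_token
    if kind is not template_token.kind:
        return False
    if kind is DomainKind.ACP:
        return run <= template_token.acp_max
    return True


def template_distance(cluster: GeneCluster, tdef: TypeDefinition,
                      scoring: Scoring = DEFAULT_SCORING) -> float:
    """Collapsed-mode distance between a cluster and a Type template.

    Collapsed ACP tokens match the template's ACP token only when the run
    length falls inside the template's copy-number range.
    """
    ctoks = collapse_acp_runs(cluster.domain_kinds)
    if not ctoks:
        raise ValidationError(f"cluster {cluster.cluster_id} has no domains")
    ttoks = tdef.collapsed_tokens
    aln = align_tokens(ctoks, ttoks, scoring=scoring,
                       eq=lambda c, t: _template_token_eq(c, t))
    return 1.0 - aln.n_matches / aln.length


def assign_type(cluster: GeneCluster, catalog: Catalog,
                threshold: float = 0.2,
                scoring: Scoring = DEFAULT_SCORING) -> TypeAssignment:
    """Assign a cluster to the nearest catalog Type (or "novel").

    Distance ties are broken by alphabetical Type letter; a best distance
    above ``threshold`` yields the call "novel".
    """
    if not catalog.types:
        raise ValidationError("empty catalog")
    scored = sorted(
        (template_distance(cluster, catalog.types[letter], scoring=scoring), letter)
        for letter in catalog.letters)
    best_d, best_letter = scored[0]
    runner = scored[1][1] if len(scored) > 1 else None
    margin = (scored[1][0] - best_d) if len(scored) > 1 else float("inf")
    if best_d > threshold:
        warnings.warn(
            f"cluster {cluster.cluster_id}: nearest Type {best_letter} at "
            f"distance {best_d:.3f} exceeds threshold {threshold}; calling novel",
            stacklevel=2)
        return TypeAssignment(cluster.cluster_id, "novel", best_d, runner, margin)
    return TypeAssignment(cluster.cluster_id, best_letter, best_d, runner, margin)
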