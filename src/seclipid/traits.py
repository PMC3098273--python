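"""Distance-based multivariate statistics on binary life-history traits.

Organisms are described by binary trait vectors (the survey used 33 traits:
habitat, metabolism, oxygen relationship, differentiation, and similar
life-history attributes) and grouped by the cluster Type their genome
carries.  The association between Type and traits is tested with PERMANOVA
(pseudo-F on a dissimilarity matrix, unrestricted permutation of raw
observations) and visualised/tested with canonical analysis of principal
coordinates (CAP) on Bray-Curtis dissimilarities, including the
leave-one-out allocation success and Spearman trait-correlation biplot.

PERMANOVA partitions the total sum of squared dissimilarities
``SS_T = (1/N) sum_{i<j} d_ij^2`` into within-group
``SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij^2`` and among-group
``SS_A = SS_T - SS_W``; the statistic is
``F = (SS_A/(g-1)) / (SS_W/(N-g))``, which reduces to the classical one-way
ANOVA F when the distances are Euclidean on univariate data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .model import ValidationError
from .similarity import DistanceMatrix


# ---------------------------------------------------------------------------
# trait matrix
# ---------------------------------------------------------------------------

@dataclass
class TraitMatrix:
    """Binary organisms x traits matrix with per-organism group labels."""

    organisms: tuple[str, ...]
    traits: tuple[str, ...]
    values: np.ndarray
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        self.traits = tuple(self.traits)
        self.groups = tuple(self.groups)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.organisms), len(self.traits)):
            raise ValidationError("trait matrix shape mismatch")
        if len(self.groups) != len(self.organisms):
            raise ValidationError("one group label per organism required")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("trait values must be binary 0/1")

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.groups:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def filter_by_group_size(self, min_n: int = 5) -> "TraitMatrix":
        """Keep only organisms whose group has n >= min_n; formal tests are
        run only on adequately replicated groups."""
        sizes = self.group_sizes
        keep = [i for i, g in enumerate(self.groups) if sizes[g] >= min_n]
        return TraitMatrix(
            organisms=tuple(self.organisms[i] for i in keep),
            traits=self.traits,
            values=self.values[keep],
            groups=tuple(self.groups[i] for i in keep))

    def write_tsv(self, values_path: str | Path, groups_path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.traits))
        df.insert(0, "organism", list(self.organisms))
        df.to_csv(values_path, sep="\t", index=False)
        pd.DataFrame({"organism": list(self.organisms),
                      "type_letter": list(self.groups)}) \
            .to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, values_path: str | Path, groups_path: str | Path,
                 ) -> "TraitMatrix":
        df = pd.read_csv(values_path, sep="\t")
        gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
        groups = dict(zip(gdf["organism"], gdf["type_letter"]))
        organisms = tuple(df["organism"].astype(str))
        missing = [o for o in organisms if o not in groups]
        if missing:
            raise ValidationError(f"no group label for organisms {missing[:3]}")
        traits = tuple(c for c in df.columns if c != "organism")
        return cls(organisms=organisms, traits=traits,
                   values=df[list(traits)].to_numpy(),
                   groups=tuple(groups[o] for o in organisms))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y))/(sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def bray_curtis_matrix(tm: TraitMatrix) -> DistanceMatrix:
    if (tm.values.sum(axis=1) == 0).any():
        zeros = [tm.organisms[i] for i in np.flatnonzero(tm.values.sum(axis=1) == 0)]
        raise ValidationError(f"all-zero trait rows: {zeros[:3]}")
    D = squareform(pdist(tm.values.astype(float), metric="braycurtis"))
    return DistanceMatrix(labels=tm.organisms, values=D)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    SS_among: float
    SS_within: float
    SS_total: float
    df_among: int
    df_within: int
    exhaustive: bool = False


def _ss_partition(D2: np.ndarray, labels: np.ndarray,
                  group_ids: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer labels."""
    N = D2.shape[0]
    ss_total = D2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for g in group_ids:
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def _pseudo_f(ss_among: float, ss_within: float, g: int, N: int) -> float:
    if ss_within <= 0:
        return math.inf
    return (ss_among / (g - 1)) / (ss_within / (N - g))


def _multiset_permutations(labels: np.ndarray):
    """Distinct permutations of a label multiset (lexicographic)."""
    from sympy.utilities.iterables import multiset_permutations
    yield from multiset_permutations(list(labels))


def permanova(dist: DistanceMatrix, groups: Sequence[str],
              n_permutations: int | str = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``n_permutations`` may be an integer (Monte-Carlo label permutation with
    p = (1 + #{F* >= F}) / (1 + B)) or ``"exhaustive"`` (complete
    enumeration of distinct label arrangements, p = #{F* >= F}/total with
    the identity arrangement included).
    """
    groups = np.asarray(groups)
    if len(groups) != dist.n:
        raise ValidationError("group labels do not match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least two groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValidationError(f"groups with n < 2: {small}")
    g, N = len(uniq), dist.n
    D2 = dist.values ** 2
    ss_total, ss_within = _ss_partition(D2, groups, uniq)
    ss_among = ss_total - ss_within
    F_obs = _pseudo_f(ss_among, ss_within, g, N)

    tol = 1e-12
    if n_permutations == "exhaustive":
        count = total = 0
        for perm in _multiset_permutations(groups):
            _, ssw = _ss_partition(D2, np.asarray(perm), uniq)
            Fp = _pseudo_f(ss_total - ssw, ssw, g, N)
            count += (Fp >= F_obs - tol)
            total += 1
        p = count / total
        return PermanovaResult(F_obs, p, total, ss_among, ss_within, ss_total,
                               g - 1, N - g, exhaustive=True)

    B = int(n_permutations)
    if B < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(groups)
        _, ssw = _ss_partition(D2, perm, uniq)
        Fp = _pseudo_f(ss_total - ssw, ssw, g, N)
        count += (Fp >= F_obs - tol)
    p = (1 + count) / (1 + B)
    return PermanovaResult(F_obs, p, B, ss_among, ss_within, ss_total,
                           g - 1, N - g)


def pairwise_permanova(dist: DistanceMatrix, groups: Sequence[str],
                       n_permutations: int | str = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA for every unordered group pair (raw p-values, no
    multiplicity correction).  p-values at the permutation resolution
    1/(B+1) are flagged in the ``at_resolution`` column."""
    groups = np.asarray(groups)
    uniq = sorted(set(groups))
    rows = []
    for ga, gb in itertools.combinations(uniq, 2):
        idx = np.flatnonzero(np.isin(groups, (ga, gb)))
        sub = dist.submatrix(idx)
        res = permanova(sub, groups[idx], n_permutations=n_permutations,
                        seed=seed)
        resolution = (1.0 / res.n_permutations if res.exhaustive
                      else 1.0 / (res.n_permutations + 1))
        rows.append({"group_a": ga, "group_b": gb,
                     "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                     "n_permutations": res.n_permutations,
                     "at_resolution": res.p_value <= resolution + 1e-15})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# principal coordinates and CAP
# ---------------------------------------------------------------------------

def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


@dataclass
class PcoaResult:
    eigvals: np.ndarray          # positive eigenvalues, descending
    coordinates: np.ndarray      # n x n_pos scores V * sqrt(lambda)
    eigvecs: np.ndarray          # n x n_pos orthonormal eigenvectors
    n_negative: int
    negative_sum: float


def pcoa(D: np.ndarray, eps: float = 1e-9) -> PcoaResult:
    """Principal coordinates analysis (classical scaling).

    Negative eigenvalues (non-Euclidean input) are discarded without
    correction; their number and summed magnitude are reported.
    """
    G = _gower_center(np.asarray(D, dtype=float) ** 2)
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0)
    pos = vals > eps * scale
    neg = vals < -eps * scale
    return PcoaResult(eigvals=vals[pos],
                      coordinates=vecs[:, pos] * np.sqrt(vals[pos]),
                      eigvecs=vecs[:, pos],
                      n_negative=int(neg.sum()),
                      negative_sum=float(vals[neg].sum()))


def _project_point(D2_train: np.ndarray, d2_new: np.ndarray,
                   res: PcoaResult) -> np.ndarray:
    """Place a new point into an existing PCoA space (Gower's formula)."""
    col_means = D2_train.mean(axis=0)
    grand = D2_train.mean()
    b = -0.5 * (d2_new - d2_new.mean() - col_means + grand)
    return (b @ res.eigvecs) / np.sqrt(res.eigvals)


def _indicator(groups: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    Y = (groups[:, None] == uniq[None, :]).astype(float)
    return Y - Y.mean(axis=0)


def _canonical(eigvecs_m: np.ndarray, groups: np.ndarray,
               uniq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenanalysis of Q'HQ on orthonormalised PCo axes.

    Returns (squared canonical correlations desc, axis weight matrix W)
    where canonical scores are ``eigvecs_m @ W``.
    """
    X = _indicator(groups, uniq)
    XtX = X.T @ X
    H_part = X @ np.linalg.pinv(XtX) @ X.T
    A = eigvecs_m.T @ H_part @ eigvecs_m
    vals, W = np.linalg.eigh((A + A.T) / 2)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, 1.0)
    W = W[:, order]
    n_axes = min(eigvecs_m.shape[1], len(uniq) - 1)
    return vals[:n_axes], W[:, :n_axes]


def _allocate(C_train: np.ndarray, groups_train: np.ndarray,
              uniq: np.ndarray, c_new: np.ndarray) -> str:
    dists = []
    for gname in uniq:
        centroid = C_train[groups_train == gname].mean(axis=0)
        dists.append(np.linalg.norm(c_new - centroid))
    return str(uniq[int(np.argmin(dists))])


@dataclass
class CapResult:
    m: int
    canonical_axes: np.ndarray
    canonical_correlations: np.ndarray
    allocation_success_per_group: dict[str, float]
    allocation_success_overall: float
    chance_threshold: float
    permutation_p: float
    n_permutations: int
    groups: tuple[str, ...]
    labels: tuple[str, ...]
    loo_assignments: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)


def _loo_success(D: np.ndarray, groups: np.ndarray, uniq: np.ndarray,
                 m_values: Sequence[int]) -> dict[int, list[str]]:
    """Leave-one-out CAP allocations for each candidate m.

    For each left-out observation the PCoA is refit on the remaining
    observations, the point is placed into the reduced space and allocated
    to the nearest group centroid in canonical coordinates.  The expensive
    eigendecompositions are shared across candidate ``m`` values.
    """
    N = D.shape[0]
    out: dict[int, list[str]] = {m: [] for m in m_values}
    for i in range(N):
        keep = np.delete(np.arange(N), i)
        D_train = D[np.ix_(keep, keep)]
        res = pcoa(D_train)
        q_full = _project_point(D_train ** 2, D[i, keep] ** 2, res)
        g_train = groups[keep]
        for m in m_values:
            mm = min(m, res.eigvecs.shape[1])
            vecs_m = res.eigvecs[:, :mm]
            _, W = _canonical(vecs_m, g_train, uniq)
            C_train = vecs_m @ W
            u_new = q_full[:mm] / np.sqrt(res.eigvals[:mm])
            c_new = u_new @ W
            out[m].append(_allocate(C_train, g_train, uniq, c_new))
    return out


def cap(dist: DistanceMatrix, groups: Sequence[str],
        m: int | str = "auto", n_permutations: int = 10000,
        seed: int | None = None) -> CapResult:
    """Canonical analysis of principal coordinates (constrained ordination).

    PCoA axes are computed from the dissimilarity matrix; the first ``m``
    axes are related to the group indicator matrix by canonical correlation
    analysis.  Allocation success is measured by leave-one-out: each
    observation is placed in the canonical space fit without it and
    allocated to the nearest group centroid.  ``m="auto"`` picks the m in
    1..(N-g) that maximises overall leave-one-out success (smallest m on
    ties); note this choice optimises the reported success and is therefore
    optimistic under the null.  The permutation test permutes group labels
    and compares the sum of squared canonical correlations;
    ``n_permutations=0`` skips it.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != dist.n:
        raise ValidationError("group labels do not match distance matrix")
    uniq = np.unique(groups)
    g, N = len(uniq), dist.n
    if g < 2:
        raise ValidationError("need at least two groups")
    full = pcoa(dist.values)
    m_cap = min(N - g, full.eigvecs.shape[1])
    if isinstance(m, str):
        if m != "auto":
            raise ValidationError(f"unknown m specification {m!r}")
        m_values = list(range(1, m_cap + 1))
    else:
        if not 1 <= m <= N - g:
            raise ValidationError(f"m must be in 1..{N - g}")
        m_values = [min(m, m_cap)]
    loo = _loo_success(dist.values, groups, uniq, m_values)
    success = {mv: float(np.mean(np.asarray(loo[mv]) == groups)) for mv in m_values}
    m_best = max(m_values, key=lambda mv: (success[mv], -mv))

    assignments = np.asarray(loo[m_best])
    per_group = {}
    for gname in uniq:
        mask = groups == gname
        per_group[str(gname)] = float(100.0 * np.mean(assignments[mask] == gname))
    overall = float(100.0 * np.mean(assignments == groups))

    vecs_m = full.eigvecs[:, :m_best]
    sq_corr, W = _canonical(vecs_m, groups, uniq)
    axes = vecs_m @ W

    perm_p = math.nan
    if n_permutations:
        rng = np.random.default_rng(seed)
        stat_obs = float(sq_corr.sum())
        count = 0
        for _ in range(int(n_permutations)):
            vals_p, _ = _canonical(vecs_m, rng.permutation(groups), uniq)
            count += (float(vals_p.sum()) >= stat_obs - 1e-12)
        perm_p = (1 + count) / (1 + int(n_permutations))

    return CapResult(
        m=m_best,
        canonical_axes=axes,
        canonical_correlations=np.sqrt(sq_corr),
        allocation_success_per_group=per_group,
        allocation_success_overall=overall,
        chance_threshold=100.0 / g,
        permutation_p=perm_p,
        n_permutations=int(n_permutations),
        groups=tuple(groups),
        labels=dist.labels,
        loo_assignments=tuple(assignments),
        metadata={"n_negative_eigvals": full.n_negative,
                  "negative_eigval_sum": full.negative_sum,
                  "loo_success_by_m": {mv: success[mv] for mv in m_values}})


def trait_biplot(capresult: CapResult, tm: TraitMatrix,
                 min_abs_rho: float = 0.4) -> pd.DataFrame:
    """Spearman correlation of each trait with each canonical axis.

    Returns rows (trait, axis, rho) with |rho| >= min_abs_rho; constant
    trait columns are omitted with a warning column in the output metadata.
    """
    if tuple(capresult.labels) != tuple(tm.organisms):
        raise ValidationError("CAP result and trait matrix organisms differ")
    rows = []
    import warnings as _warnings
    for t_idx, trait in enumerate(tm.traits):
        col = tm.values[:, t_idx].astype(float)
        if np.all(col == col[0]):
            _warnings.warn(f"trait {trait!r} is constant; correlation undefined",
                           stacklevel=2)
            continue
        for a_idx in range(capresult.canonical_axes.shape[1]):
            rho = spearmanr(col, capresult.canonical_axes[:, a_idx]).statistic
            if abs(rho) >= min_abs_rho:
                rows.append({"trait": trait, "axis": a_idx + 1,
                             "rho": float(rho)})
    return pd.DataFrame(rows, columns=["trait", "axis", "rho"])
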