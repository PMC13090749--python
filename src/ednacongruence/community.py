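"""Distance-based community comparisons with permutation inference.

Whole-dataset species lists (original assignment, uncorrected reanalysis,
basin-corrected reanalysis) are stacked into a binary occurrence matrix, a
Jaccard distance matrix is computed on row supports, and group structure
(continent, assignment type) is tested with PERMANOVA, ANOSIM, a multivariate
dispersion test, and db-RDA.  All permutation inference is implemented here
directly: group labels are freely permuted over observations and the p-value
uses the (1 + #{stat_perm >= stat_obs}) / (1 + n_perm) estimator, so p >=
1/(n_perm + 1) always.  For small balanced designs the full set of distinct
label arrangements can be enumerated instead (``permutations="exact"``).

Ordination support: principal coordinates (Gower double-centering) and a
non-metric MDS minimizing Kruskal stress-1 by alternating pool-adjacent-
violators monotone regression with Guttman majorization steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _iperm
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

ASSIGNMENT_TYPES = ("original", "global_reanalysis", "basin_reanalysis")


@dataclass
class OccurrenceMatrix:
    """Binary (dataset x assignment-type) by species matrix with row metadata."""

    data: pd.DataFrame              # rows: profile id; columns: species; 0/1
    meta: pd.DataFrame              # index matches data; continent, assignment_type, dataset_id


@dataclass
class PermTestResult:
    test: str
    statistic: float
    r_squared: float | None
    p_value: float
    n_permutations: int
    seed: int | None

    def as_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "R2": self.r_squared, "p": self.p_value,
                "n_permutations": self.n_permutations, "seed": self.seed}


def build_occurrence_matrix(collection,
                            assignment_types: Sequence[str] = ASSIGNMENT_TYPES
                            ) -> OccurrenceMatrix:
    """Stack per-dataset species lists into one presence/absence matrix."""
    from .congruence import correct_to_pool

    lists: dict[str, frozenset[str]] = {}
    meta_rows = []
    for ds in collection.datasets:
        for at in assignment_types:
            if at == "original":
                if ds.original is None or ds.original.richness_only:
                    logger.warning("dataset %s lacks an original species list; "
                                   "row omitted", ds.dataset_id)
                    continue
                sp = ds.original.species
            elif at == "global_reanalysis":
                sp = ds.read_table.species
            elif at == "basin_reanalysis":
                sp = correct_to_pool(ds.read_table, ds.pools.basin).species
            else:
                raise ValueError(f"unknown assignment type {at!r}")
            if not sp:
                logger.warning("dataset %s has an empty %s species list; "
                               "row omitted", ds.dataset_id, at)
                continue
            rid = f"{ds.dataset_id}|{at}"
            lists[rid] = sp
            meta_rows.append({"row_id": rid, "dataset_id": ds.dataset_id,
                              "assignment_type": at,
                              "continent": ds.metadata.continent})
    universe = sorted(set().union(*lists.values())) if lists else []
    data = pd.DataFrame(0, index=list(lists), columns=universe, dtype=np.int8)
    for rid, sp in lists.items():
        data.loc[rid, list(sp)] = 1
    meta = pd.DataFrame(meta_rows).set_index("row_id") if meta_rows else pd.DataFrame()
    return OccurrenceMatrix(data=data, meta=meta)


def jaccard_matrix(occ: OccurrenceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances (1 - |A∩B|/|A∪B|) between row supports."""
    data = occ.data if isinstance(occ, OccurrenceMatrix) else occ
    arr = np.asarray(data.values, dtype=bool)
    if (~arr.any(axis=1)).any():
        raise ValueError("all-zero rows have no defined Jaccard distance")
    d = squareform(pdist(arr, metric="jaccard"))
    return pd.DataFrame(d, index=data.index, columns=data.index)


# ---------------------------------------------------------------------------
# permutation machinery


def _as_groups(groups) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(groups))
    return codes


def _check_design(d: np.ndarray, codes: np.ndarray) -> None:
    if d.shape[0] != d.shape[1] or d.shape[0] != codes.size:
        raise ValueError("distance matrix and grouping sizes differ")
    counts = np.bincount(codes)
    if counts.size < 2:
        raise ValueError("at least two groups are required")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")


def _label_perms(codes: np.ndarray, n_perm: int, rng: np.random.Generator,
                 exact: bool) -> tuple[np.ndarray, bool]:
    """(P, n) array of permuted label vectors; first row = observed if exact."""
    n = codes.size
    if exact:
        seen = sorted({tuple(codes[list(p)]) for p in _iperm(range(n))})
        return np.array(seen, dtype=int), True
    perms = np.empty((n_perm, n), dtype=int)
    for i in range(n_perm):
        perms[i] = codes[rng.permutation(n)]
    return perms, False


def _within_pair_sums(mat: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Per-group sums of mat over within-group pairs for each permuted labeling.

    Returns array (P, k): entry [p, g] = sum_{i<j in group g} mat[i, j].
    """
    k = perms.max() + 1
    out = np.empty((perms.shape[0], k))
    for g in range(k):
        m = (perms == g).astype(float)
        out[:, g] = 0.5 * np.einsum("pi,ij,pj->p", m, mat, m)
    return out


def _permanova_f(d2: np.ndarray, perms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-F and R² for each permuted labeling (vectorized)."""
    n = d2.shape[0]
    k = perms.max() + 1
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    within = _within_pair_sums(d2, perms)          # (P, k)
    n_g = np.stack([(perms == g).sum(axis=1) for g in range(k)], axis=1)
    ss_within = (within / n_g).sum(axis=1)
    ss_among = ss_total - ss_within
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    r2 = ss_among / ss_total
    return f, r2


def _p_from_perms(stat_obs: float, stat_perm: np.ndarray, exact: bool) -> float:
    ge = np.count_nonzero(stat_perm >= stat_obs - 1e-12)
    if exact:
        return ge / stat_perm.size  # identity labeling is in the enumeration
    return (1 + ge) / (1 + stat_perm.size)


def permanova(dist: pd.DataFrame | np.ndarray, groups, n_perm: int = 999,
              seed: int | None = None, permutations: str = "free") -> PermTestResult:
    """Permutational multivariate ANOVA (pseudo-F on squared distances).

    ``permutations="exact"`` enumerates every distinct labeling (small n only).
    """
    d = np.asarray(dist, dtype=float)
    codes = _as_groups(groups)
    _check_design(d, codes)
    if permutations == "free" and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    d2 = d ** 2
    f_obs, r2_obs = _permanova_f(d2, codes[None, :])
    perms, exact = _label_perms(codes, n_perm, rng, permutations == "exact")
    f_perm, _ = _permanova_f(d2, perms)
    return PermTestResult("PERMANOVA", float(f_obs[0]), float(r2_obs[0]),
                          _p_from_perms(float(f_obs[0]), f_perm, exact),
                          perms.shape[0] if exact else n_perm, seed)


def _anosim_r(rank_mat: np.ndarray, perms: np.ndarray) -> np.ndarray:
    n = rank_mat.shape[0]
    m_pairs = n * (n - 1) / 2
    total_rank = rank_mat[np.triu_indices(n, 1)].sum()
    k = perms.max() + 1
    within_rank = _within_pair_sums(rank_mat, perms).sum(axis=1)
    n_g = np.stack([(perms == g).sum(axis=1) for g in range(k)], axis=1)
    n_within = (n_g * (n_g - 1) / 2).sum(axis=1)
    n_between = m_pairs - n_within
    r_w = within_rank / n_within
    r_b = (total_rank - within_rank) / n_between
    return (r_b - r_w) / (m_pairs / 2)


def anosim(dist: pd.DataFrame | np.ndarray, groups, n_perm: int = 999,
           seed: int | None = None, permutations: str = "free") -> PermTestResult:
    """Analysis of similarities: rank-based R with permutation inference."""
    d = np.asarray(dist, dtype=float)
    codes = _as_groups(groups)
    _check_design(d, codes)
    if permutations == "free" and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    rank_mat = np.zeros_like(d)
    rank_mat[iu] = ranks
    rank_mat += rank_mat.T
    r_obs = float(_anosim_r(rank_mat, codes[None, :])[0])
    perms, exact = _label_perms(codes, n_perm, rng, permutations == "exact")
    r_perm = _anosim_r(rank_mat, perms)
    return PermTestResult("ANOSIM", r_obs, None,
                          _p_from_perms(r_obs, r_perm, exact),
                          perms.shape[0] if exact else n_perm, seed)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class PCoAResult:
    coordinates: np.ndarray       # n x (number of positive-eigenvalue axes)
    eigenvalues: np.ndarray       # all n, descending
    imag_coordinates: np.ndarray  # axes for negative eigenvalues (|lambda| scaled)


def pcoa(dist: pd.DataFrame | np.ndarray, eps: float = 1e-10) -> PCoAResult:
    """Principal coordinates via Gower double-centering eigendecomposition.

    Negative-eigenvalue axes (a non-Euclidean distance signature) are kept
    separately as "imaginary" coordinates for Anderson-corrected dispersion
    distances.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.max(np.abs(vals), initial=1.0)
    pos = vals > eps * scale
    neg = vals < -eps * scale
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return PCoAResult(coords, vals, imag)


def dispersion_test(dist: pd.DataFrame | np.ndarray, groups, n_perm: int = 999,
                    seed: int | None = None) -> PermTestResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Distance from each observation to its group centroid in PCoA space, with
    the imaginary-axis correction sqrt(max(d_real² − d_imag², 0)); a one-way F
    on those distances, with labels permuted over the distance vector.
    """
    d = np.asarray(dist, dtype=float)
    codes = _as_groups(groups)
    _check_design(d, codes)
    res = pcoa(d)
    k = codes.max() + 1
    dists = np.empty(d.shape[0])
    for g in range(k):
        mask = codes == g
        c_re = res.coordinates[mask].mean(axis=0)
        d_re2 = ((res.coordinates[mask] - c_re) ** 2).sum(axis=1)
        if res.imag_coordinates.size:
            c_im = res.imag_coordinates[mask].mean(axis=0)
            d_im2 = ((res.imag_coordinates[mask] - c_im) ** 2).sum(axis=1)
        else:
            d_im2 = 0.0
        dists[mask] = np.sqrt(np.clip(d_re2 - d_im2, 0.0, None))

    def anova_f(labels: np.ndarray) -> float:
        grand = dists.mean()
        ss_b = ss_w = 0.0
        for g in range(k):
            x = dists[labels == g]
            ss_b += x.size * (x.mean() - grand) ** 2
            ss_w += ((x - x.mean()) ** 2).sum()
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / (k - 1)) / (ss_w / (dists.size - k))

    f_obs = anova_f(codes)
    rng = np.random.default_rng(seed)
    f_perm = np.array([anova_f(codes[rng.permutation(codes.size)])
                       for _ in range(n_perm)])
    return PermTestResult("dispersion", float(f_obs), None,
                          _p_from_perms(f_obs, f_perm, exact=False), n_perm, seed)


def dbrda(dist: pd.DataFrame | np.ndarray, groups, n_perm: int = 999,
          seed: int | None = None) -> PermTestResult:
    """Distance-based redundancy analysis of PCoA coordinates on group dummies.

    Only non-negative-eigenvalue axes enter (no Lingoes/Cailliez correction);
    F = (SS_fit/(k−1)) / (SS_res/(n−k)) with free label permutation.
    """
    d = np.asarray(dist, dtype=float)
    codes = _as_groups(groups)
    _check_design(d, codes)
    y = pcoa(d).coordinates
    y = y - y.mean(axis=0)
    n, k = y.shape[0], codes.max() + 1

    def rda_f(labels: np.ndarray) -> tuple[float, float]:
        x = np.zeros((n, k))
        x[np.arange(n), labels] = 1.0
        x = x - x.mean(axis=0)
        # hat-matrix fit via least squares on the dummy design
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fit = x @ beta
        ss_fit = float((fit ** 2).sum())
        ss_tot = float((y ** 2).sum())
        ss_res = ss_tot - ss_fit
        if ss_res <= 1e-12 * max(ss_tot, 1.0):
            return np.inf, 1.0
        return (ss_fit / (k - 1)) / (ss_res / (n - k)), ss_fit / ss_tot

    f_obs, r2_obs = rda_f(codes)
    rng = np.random.default_rng(seed)
    f_perm = np.array([rda_f(codes[rng.permutation(n)])[0] for _ in range(n_perm)])
    return PermTestResult("db-RDA", float(f_obs), float(r2_obs),
                          _p_from_perms(f_obs, f_perm, exact=False), n_perm, seed)


# ---------------------------------------------------------------------------
# non-metric MDS


@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float                 # Kruskal stress-1
    converged: bool


def _stress1(d_config: np.ndarray, d_hat: np.ndarray) -> float:
    denom = (d_config ** 2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d_config - d_hat) ** 2).sum() / denom))


def nmds(dist: pd.DataFrame | np.ndarray, k: int = 2, seed: int | None = None,
         n_restarts: int = 4, max_iter: int = 300, tol: float = 1e-7) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Alternates pool-adjacent-violators monotone regression (fitted distances
    against the dissimilarity order) with Guttman majorization updates of the
    configuration.  The first restart starts from classical PCoA coordinates,
    the rest from random configurations; the lowest-stress solution is
    returned.  Stress is non-increasing within each restart (the update is
    rejected on any increase).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)
    xs = np.arange(diss.size, dtype=float)

    best: NMDSResult | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            coords = pcoa(d).coordinates
            if coords.shape[1] >= k:
                x = coords[:, :k].copy()
            else:
                x = np.hstack([coords, 1e-3 * rng.standard_normal(
                    (n, k - coords.shape[1]))])
        else:
            x = rng.standard_normal((n, k))
        prev_stress = np.inf
        converged = False
        for _ in range(max_iter):
            dc = pdist(x)
            d_hat = np.empty_like(dc)
            d_hat[order] = iso.fit_transform(xs, dc[order])
            stress = _stress1(dc, d_hat)
            if stress > prev_stress + 1e-12:
                break
            if prev_stress - stress < tol:
                prev_stress, x_best_iter = stress, x
                converged = True
                break
            prev_stress, x_best_iter = stress, x
            # Guttman transform toward the fitted monotone distances
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dc > 0, d_hat / dc, 0.0)
            b = squareform(ratio)
            bm = -b
            np.fill_diagonal(bm, b.sum(axis=1))
            x = bm @ x / n
        cand = NMDSResult(x_best_iter, prev_stress, converged)
        if best is None or cand.stress < best.stress:
            best = cand
    return best
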