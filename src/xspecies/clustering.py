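"""Two-stage clustering of per-species prediction matrices and LOLA-style
hypergeometric enrichment of clusters against external enhancer sets.

OCRs are clustered by their predicted open-chromatin probability across
species, with species lacking a usable ortholog treated as missing data.
The distance is one minus the cosine similarity computed over the species
where both vectors are observed ("masked cosine").  A masked k-means pass
compresses the OCRs into small clusters whose centroids are then grouped by
affinity propagation (self-similarity = preference), which chooses the final
number of clusters itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, Peak, UnionPeaks
from .io import OrthologMap

logger = logging.getLogger(__name__)


def redundancy_filter(
    ocrs_by_species: Mapping[str, Sequence[Peak]],
    priority_order: Sequence[str],
    ortholog_map: OrthologMap,
) -> dict[str, list[Peak]]:
    """Drop OCRs already represented by a higher-priority species.

    An OCR from the species at priority i is removed iff its ortholog in any
    higher-priority species overlaps that species' own OCR set.  The
    highest-priority species keeps everything.
    """
    ocr_unions = {
        sp: UnionPeaks.from_peaks([ocrs_by_species.get(sp, [])]) for sp in priority_order
    }
    out: dict[str, list[Peak]] = {}
    for i, sp in enumerate(priority_order):
        higher = priority_order[:i]
        kept = []
        for p in ocrs_by_species.get(sp, []):
            redundant = False
            for hsp in higher:
                rec = ortholog_map.get(sp, p.name, hsp)
                if rec is not None and ocr_unions[hsp].overlaps(rec.interval):
                    redundant = True
                    break
            if not redundant:
                kept.append(p)
        out[sp] = kept
    return out


def usability_filter(
    matrix: pd.DataFrame,
    clade_membership: Mapping[str, str],
    min_all: float = 0.5,
    min_clade: float = 0.25,
    require_both: bool = True,
) -> pd.DataFrame:
    """Keep rows with usable orthologs in enough species overall and per clade.

    Default reading: keep requires BOTH >= ``min_all`` of all species AND
    >= ``min_clade`` of each clade (boundaries inclusive).  The disjunctive
    reading is available with ``require_both=False``.
    """
    clades: dict[str, list[str]] = {c: [] for c in set(clade_membership.values())}
    for sp in matrix.columns:
        clades[clade_membership[sp]].append(sp)
    for clade, members in clades.items():
        if not members:
            raise ValueError(f"clade {clade!r} has no species in the matrix")
    present = matrix.notna()
    ok_all = present.mean(axis=1) >= min_all
    ok_clades = pd.Series(True, index=matrix.index)
    for members in clades.values():
        ok_clades &= present[members].mean(axis=1) >= min_clade
    keep = (ok_all & ok_clades) if require_both else (ok_all | ok_clades)
    return matrix.loc[keep]


def masked_cosine_distance(u: Sequence[float], v: Sequence[float]) -> float:
    """1 - cosine similarity over the dimensions observed in both vectors.

    Entries are probabilities (nonnegative), so the distance lies in [0, 1].
    Empty shared support or a zero vector gives the maximal distance 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    mask = ~(np.isnan(u) | np.isnan(v))
    if not mask.any():
        return 1.0
    uu, vv = u[mask], v[mask]
    nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
    if nu == 0 or nv == 0:
        return 1.0
    return float(np.clip(1.0 - float(uu @ vv) / (nu * nv), 0.0, 1.0))


def _distances_to_centroid(x0, x0sq, present, centroid):
    """Masked cosine distance from every row to one (possibly partial) centroid.

    ``x0``: data with NaN replaced by 0; ``x0sq = x0**2``;
    ``present``: float mask of observed entries.
    """
    cmask = ~np.isnan(centroid)
    if not cmask.any():
        return np.ones(x0.shape[0])
    c = centroid[cmask]
    dots = x0[:, cmask] @ c
    xnorm2 = x0sq[:, cmask].sum(axis=1)
    cnorm2 = present[:, cmask] @ (c * c)
    denom = np.sqrt(xnorm2 * cnorm2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - dots / denom
    d[denom == 0] = 1.0
    return np.clip(d, 0.0, 1.0)


@dataclass
class KMeansResult:
    assignments: np.ndarray
    centroids: np.ndarray
    objective: float
    n_iter: int


def kmeans_masked(
    matrix: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> KMeansResult:
    """K-means under the masked cosine distance with missing-aware centroids.

    Assignment minimizes masked cosine distance to centroids; the centroid
    update is the per-species mean over members' non-missing entries.
    Initialization is k-means++ (new seeds sampled with probability
    proportional to squared masked distance from the chosen set — plain
    farthest-point chases outliers and blurs tight pattern clouds); an
    emptied cluster is re-seeded from the point farthest from its centroid.
    Deterministic under ``seed``.
    """
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    rng = np.random.default_rng(seed)
    present = (~np.isnan(x)).astype(float)
    x0 = np.nan_to_num(x)
    x0sq = x0 * x0

    # k-means++ init under the masked distance
    first = int(rng.integers(n))
    centroid_idx = [first]
    mind = _distances_to_centroid(x0, x0sq, present, x[first])
    while len(centroid_idx) < k:
        weights = mind ** 2
        total = weights.sum()
        if total == 0:
            nxt = int(rng.integers(n))
        else:
            nxt = int(rng.choice(n, p=weights / total))
        centroid_idx.append(nxt)
        mind = np.minimum(mind, _distances_to_centroid(x0, x0sq, present, x[nxt]))
    centroids = x[centroid_idx].copy()

    assignments = np.full(n, -1)
    objective = math.inf
    for it in range(1, max_iter + 1):
        dmat = np.stack(
            [_distances_to_centroid(x0, x0sq, present, centroids[j]) for j in range(k)],
            axis=1,
        )
        new_assign = dmat.argmin(axis=1)
        new_obj = float(dmat[np.arange(n), new_assign].sum())
        if new_obj > objective + 1e-9:
            # centroid missingness can let the objective tick up; log it
            logger.debug("kmeans_masked: objective rose %.6f -> %.6f", objective, new_obj)
        if np.array_equal(new_assign, assignments):
            assignments, objective = new_assign, new_obj
            break
        assignments, objective = new_assign, new_obj
        with np.errstate(invalid="ignore"):
            for j in range(k):
                members = assignments == j
                if not members.any():
                    far = int(np.argmax(dmat[np.arange(n), assignments]))
                    centroids[j] = x[far]
                    assignments[far] = j
                    logger.debug("kmeans_masked: re-seeded empty cluster %d", j)
                    continue
                counts = present[members].sum(axis=0)
                sums = x0[members].sum(axis=0)
                centroids[j] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return KMeansResult(assignments=assignments, centroids=centroids,
                        objective=objective, n_iter=it)


@dataclass
class APResult:
    exemplars: np.ndarray
    labels: np.ndarray
    converged: bool


def affinity_propagation(
    points: np.ndarray,
    preference: float = -0.6,
    damping: float = 0.5,
    max_iter: int = 200,
    convergence_iter: int = 15,
    seed: int = 0,
) -> APResult:
    """Affinity propagation on masked-cosine similarities.

    Similarity s(i, j) = -masked_cosine_distance(i, j) with self-similarity
    set to ``preference``.  Non-convergence returns the last state flagged
    (every point its own exemplar in the degenerate sklearn fallback).
    """
    from sklearn.cluster import AffinityPropagation
    import warnings

    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    sim = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            d = masked_cosine_distance(pts[i], pts[j])
            sim[i, j] = sim[j, i] = -d
    np.fill_diagonal(sim, preference)
    ap = AffinityPropagation(
        affinity="precomputed",
        preference=preference,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap.fit(sim)
    converged = ap.cluster_centers_indices_ is not None and len(ap.cluster_centers_indices_) > 0 \
        and not np.any(ap.labels_ == -1)
    if not converged:
        return APResult(exemplars=np.arange(n), labels=np.arange(n), converged=False)
    return APResult(
        exemplars=np.asarray(ap.cluster_centers_indices_),
        labels=np.asarray(ap.labels_),
        converged=True,
    )


@dataclass
class ClusterModel:
    """Composition of the two clustering stages.

    Each retained OCR maps to a small k-means cluster, and each small cluster
    to an affinity-propagation exemplar, so every OCR has exactly one final
    cluster; the number of final clusters is data-driven and at most k.
    """

    row_ids: list
    small_assignment: np.ndarray
    small_centroids: np.ndarray
    ap_labels: np.ndarray
    exemplars: np.ndarray
    k: int
    preference: float
    converged: bool = True

    @property
    def final_assignment(self) -> np.ndarray:
        return self.ap_labels[self.small_assignment]

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster: int) -> list:
        mask = self.final_assignment == cluster
        return [rid for rid, m in zip(self.row_ids, mask) if m]


def cluster_predictions(
    matrix: pd.DataFrame,
    k: int,
    preference: float = -0.6,
    seed: int = 0,
    kmeans_max_iter: int = 100,
) -> ClusterModel:
    """Masked k-means into ``k`` small clusters, then affinity propagation on
    the small-cluster centroids."""
    km = kmeans_masked(matrix, k=k, seed=seed, max_iter=kmeans_max_iter)
    ap = affinity_propagation(km.centroids, preference=preference, seed=seed)
    return ClusterModel(
        row_ids=list(matrix.index),
        small_assignment=km.assignments,
        small_centroids=km.centroids,
        ap_labels=ap.labels,
        exemplars=ap.exemplars,
        k=k,
        preference=preference,
        converged=ap.converged,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enhancer_set_prefilter(
    table: pd.DataFrame,
    fdr_max: float = 0.05,
    log2fc_min: float = 1.0,
    direction: str = "up",
    literal_down: bool = False,
    fdr_col: str = "FDR",
    log2fc_col: str = "log2FC",
) -> pd.DataFrame:
    """FDR < ``fdr_max`` (strict) and directional log2 fold-change criterion.

    Up: log2FC > ``log2fc_min``.  Down: log2FC < -``log2fc_min``; the literal
    "< log2fc_min" reading is available via ``literal_down``.
    """
    for col in (fdr_col, log2fc_col):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    keep = table[fdr_col] < fdr_max
    if direction == "up":
        keep &= table[log2fc_col] > log2fc_min
    elif direction == "down":
        thresh = log2fc_min if literal_down else -log2fc_min
        keep &= table[log2fc_col] < thresh
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return table.loc[keep]


@dataclass
class EnrichmentResult:
    cluster_id: object
    overlap: int
    cluster_size: int
    query_size: int
    universe_size: int
    raw_p: float
    adjusted_p: float
    bonferroni_factor: int


def _overlap_members(regions: Sequence[GenomicInterval], universe: Sequence[Peak]) -> set[int]:
    union = UnionPeaks.from_intervals(regions)
    return {i for i, p in enumerate(universe) if union.overlaps(p.interval)}


def cluster_enrichment(
    query_regions: Sequence[GenomicInterval],
    clusters: Mapping[object, Sequence[Peak]],
    universe_regions: Sequence[Peak],
    bonferroni_factor: Optional[int] = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric overlap test of each cluster with a query set.

    Membership is by >= 1 bp overlap against the universe of OCRs.  The raw
    p-value is P(X >= overlap) drawing ``query_size`` from ``universe_size``
    with ``cluster_size`` marked; adjusted_p = min(1, raw_p * factor), the
    factor defaulting to the number of clusters tested.
    """
    query_idx = _overlap_members(query_regions, universe_regions)
    universe_union = UnionPeaks.from_peaks([universe_regions])
    n_outside = sum(1 for r in query_regions if not universe_union.overlaps(r))
    if n_outside:
        logger.warning("cluster_enrichment: %d query regions outside universe dropped", n_outside)
    m = len(universe_regions)
    nq = len(query_idx)
    factor = bonferroni_factor if bonferroni_factor is not None else len(clusters)
    out = []
    for cid, members in clusters.items():
        cluster_idx = _overlap_members([p.interval for p in members], universe_regions)
        ov = len(cluster_idx & query_idx)
        raw_p = float(stats.hypergeom.sf(ov - 1, m, len(cluster_idx), nq))
        out.append(
            EnrichmentResult(
                cluster_id=cid, overlap=ov, cluster_size=len(cluster_idx),
                query_size=nq, universe_size=m, raw_p=raw_p,
                adjusted_p=min(1.0, raw_p * factor), bonferroni_factor=factor,
            )
        )
    return out


@dataclass
class ConfoundReport:
    p_ortholog_count: float
    p_phastcons_like: float
    p_phylop_like: float
    significant: dict[str, bool] = field(default_factory=dict)


def confound_check(
    ortholog_counts_all: Sequence[float],
    phastcons_all: Sequence[float],
    phylop_all: Sequence[float],
    overlap_mask: Sequence[bool],
    alpha: float = 0.05,
) -> ConfoundReport:
    """Are enhancer-set-overlapping OCRs unusual in orthology or conservation?

    Three two-sided rank-sum tests comparing the overlapping OCRs against the
    *full* OCR set (not the complement) on usable-ortholog count and mean
    conservation scores.  A difference is flagged non-significant when the
    nominal p is >= ``alpha``.
    """
    from .evaluation import compare_groups_ranksum

    mask = np.asarray(overlap_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("no overlapping OCRs")
    ps = {}
    for name, values in (
        ("ortholog_count", ortholog_counts_all),
        ("phastcons_like", phastcons_all),
        ("phylop_like", phylop_all),
    ):
        vals = np.asarray(values, dtype=float)
        _, raw_p, _ = compare_groups_ranksum(vals[mask], vals)
        ps[name] = raw_p
    return ConfoundReport(
        p_ortholog_count=ps["ortholog_count"],
        p_phastcons_like=ps["phastcons_like"],
        p_phylop_like=ps["phylop_like"],
        significant={k: (v < alpha) for k, v in ps.items()},
    )
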