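"""Archetype discovery in pathway-score space.

The score matrix is mean-centered and reduced by SVD, keeping the smallest
leading set of components explaining 90% of the variance. In multi-patient
runs the single component carrying the patient batch effect — the one with
the largest absolute distance between patient means after scaling components
to unit variance — is removed. The number of archetypes K is chosen by
consensus clustering: k-means on repeated 80% subsamples, a consensus matrix
of co-clustering frequencies normalized by co-sampling frequencies, and the
PAC criterion (proportion of consensus values strictly inside an ambiguity
band, default 0.1-0.9); the K maximizing stability = 1 - PAC wins, ties to
the smallest K. Cells are then clustered to that K with Louvain modularity
on a shared-nearest-neighbor graph, archetypes are characterized by Wilcoxon
rank-sum differential pathway enrichment, and their per-cycle proportions
are tracked. A small K-means helper clusters copy-number profiles into
subclones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from ._exceptions import ConfigError, ValidationError
from .temporal import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ReducedEmbedding:
    """Cell coordinates in the retained SVD component space."""

    coordinates: pd.DataFrame  # cells x components
    variance_explained: np.ndarray  # per retained component, fractions of total
    retained_variance_target: float
    centering_vector: np.ndarray
    loadings: pd.DataFrame  # pathways x retained components
    removed_component_index: int | None = None
    removed_loading: np.ndarray | None = None

    @property
    def cell_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class ConsensusConfig:
    k_range: tuple[int, int] = (2, 10)
    n_iterations: int = 100
    subsample_fraction: float = 0.8
    ambiguity_band: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction < 1):
            raise ConfigError("subsample_fraction must lie in (0, 1)")
        lo, hi = self.ambiguity_band
        if not (0 < lo < hi < 1):
            raise ConfigError("ambiguity_band must satisfy 0 < low < high < 1")
        if self.k_range[0] < 2 or self.k_range[0] > self.k_range[1]:
            raise ConfigError("k_range must be an increasing pair with low >= 2")


@dataclass
class ConsensusResult:
    pac: dict[int, float]
    stability: dict[int, float]
    selected_k: int
    config: ConsensusConfig

    def as_frame(self) -> pd.DataFrame:
        ks = sorted(self.pac)
        return pd.DataFrame(
            {"k": ks, "pac": [self.pac[k] for k in ks],
             "stability": [self.stability[k] for k in ks],
             "selected": [k == self.selected_k for k in ks]}
        )


@dataclass
class ArchetypeAssignment:
    labels: pd.Series  # cell_id -> archetype label (int)
    profiles: pd.DataFrame | None = None  # top-pathway profiles per archetype
    proportions: pd.DataFrame | None = None  # per (patient, cycle) fractions
    resolution: float | None = None
    extras: dict = field(default_factory=dict)


def reduce_svd(scores, target: float = 0.90) -> ReducedEmbedding:
    """Mean-center pathway columns and project cells onto leading SVD components.

    Keeps the smallest leading set whose cumulative share of total variance
    reaches ``target``. Columns are centered but not scaled (scaling happens
    only inside the batch-distance computation).
    """
    frame = scores.scores if hasattr(scores, "scores") else pd.DataFrame(scores)
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValidationError("need at least 2 cells and 2 pathways")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValidationError("all cells identical; embedding undefined")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(frac), target - 1e-12) + 1)
    n_keep = min(n_keep, len(s))
    coords = U[:, :n_keep] * s[:n_keep]
    return ReducedEmbedding(
        coordinates=pd.DataFrame(
            coords, index=frame.index, columns=[f"SV{i+1}" for i in range(n_keep)]
        ),
        variance_explained=frac[:n_keep],
        retained_variance_target=target,
        centering_vector=center,
        loadings=pd.DataFrame(
            Vt[:n_keep].T, index=frame.columns,
            columns=[f"SV{i+1}" for i in range(n_keep)],
        ),
    )


def remove_batch_component(
    emb: ReducedEmbedding, batch_labels, force: bool = True,
    negligible_distance: float = 0.1,
) -> ReducedEmbedding:
    """Drop the single component most separated between batch groups.

    Components are scaled to unit variance, per-group means computed, and the
    component with the largest absolute between-group mean distance (maximum
    pairwise distance when more than two groups) is removed. Ties go to the
    lowest-index component. If the best distance falls below
    ``negligible_distance`` (in unit-variance units) a warning is logged;
    removal still happens unless ``force`` is False. With a single batch
    label the call is a no-op with a warning.
    """
    labels = np.asarray(batch_labels)
    groups = np.unique(labels)
    if groups.size < 2:
        logger.warning("single batch label; no component removed")
        return emb
    X = emb.coordinates.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    means = np.vstack([Z[labels == g].mean(axis=0) for g in groups])
    dist = np.zeros(Z.shape[1])
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            dist = np.maximum(dist, np.abs(means[a] - means[b]))
    best = int(np.argmax(dist))  # argmax returns the lowest index on ties
    if dist[best] < negligible_distance:
        logger.warning(
            "largest batch distance %.3f is below %.3f; batch effect may be negligible",
            dist[best], negligible_distance,
        )
        if not force:
            return emb
    keep = [i for i in range(X.shape[1]) if i != best]
    return ReducedEmbedding(
        coordinates=emb.coordinates.iloc[:, keep],
        variance_explained=emb.variance_explained[keep],
        retained_variance_target=emb.retained_variance_target,
        centering_vector=emb.centering_vector,
        loadings=emb.loadings.iloc[:, keep],
        removed_component_index=best,
        removed_loading=emb.loadings.iloc[:, best].to_numpy(),
    )


def consensus_select_k(emb, cfg: ConsensusConfig | None = None) -> ConsensusResult:
    """Select the number of archetypes by consensus-clustering stability.

    For each k, ``n_iterations`` k-means runs on fresh subsamples accumulate
    co-clustering and co-sampling counts; consensus(i, j) is their ratio over
    iterations where both cells were drawn, pairs never co-sampled are
    excluded, and PAC is the fraction of off-diagonal consensus values
    strictly inside the ambiguity band. Each k-means uses a single random
    initialization — the run-to-run variability is the quantity being
    measured. The selected k maximizes 1 - PAC, ties to the smallest k.
    """
    cfg = cfg or ConsensusConfig()
    X = emb.coordinates.to_numpy(dtype=float) if hasattr(emb, "coordinates") else np.asarray(emb, float)
    n = X.shape[0]
    k_lo, k_hi = cfg.k_range
    if k_hi > n - 1:
        raise ConfigError(f"k_range {cfg.k_range} exceeds n-1 = {n - 1}")
    if n < k_hi * 5:
        raise ConfigError(f"need at least {k_hi * 5} cells for k up to {k_hi}")
    sub = max(2, int(round(cfg.subsample_fraction * n)))
    lo, hi = cfg.ambiguity_band
    iu = np.triu_indices(n, k=1)

    pac: dict[int, float] = {}
    root = np.random.SeedSequence(cfg.seed)
    for k, k_seq in zip(range(k_lo, k_hi + 1), root.spawn(k_hi - k_lo + 1)):
        co_cluster = np.zeros((n, n), dtype=np.int32)
        co_sample = np.zeros((n, n), dtype=np.int32)
        child_seeds = k_seq.generate_state(cfg.n_iterations)
        rng = np.random.default_rng(k_seq)
        for it in range(cfg.n_iterations):
            idx = rng.choice(n, size=sub, replace=False)
            km = KMeans(
                n_clusters=k, n_init=1,
                random_state=int(child_seeds[it] % (2**31)),
            ).fit(X[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            co_cluster[np.ix_(idx, idx)] += same
            co_sample[np.ix_(idx, idx)] += 1
        sampled = co_sample[iu] > 0
        consensus = co_cluster[iu][sampled] / co_sample[iu][sampled]
        pac[k] = float(np.mean((consensus > lo) & (consensus < hi))) if consensus.size else 0.0
    stability = {k: 1.0 - v for k, v in pac.items()}
    selected = min(stability, key=lambda k: (-stability[k], k))
    return ConsensusResult(pac=pac, stability=stability, selected_k=selected, config=cfg)


def pac_from_consensus(consensus_values, band=(0.1, 0.9)) -> float:
    """PAC of an explicit vector of off-diagonal consensus values."""
    c = np.asarray(consensus_values, dtype=float)
    return float(np.mean((c > band[0]) & (c < band[1])))


def cluster_to_k(
    emb,
    target_k: int,
    n_neighbors: int = 20,
    prune: float = 1 / 15,
    resolution_bounds: tuple[float, float] = (0.01, 5.0),
    max_steps: int = 30,
    min_cluster_size: int = 10,
) -> ArchetypeAssignment:
    """Louvain clustering on an SNN graph, tuned to ``target_k`` clusters.

    Builds a k-nearest-neighbor graph (Euclidean in the embedding), converts
    edges to shared-nearest-neighbor Jaccard weights pruned below ``prune``,
    and runs Louvain modularity clustering, bisecting the resolution until
    the cluster count equals ``target_k``. Communities smaller than
    ``min_cluster_size`` are folded into the nearest real cluster before
    counting. If the target is unreachable in ``max_steps`` the nearest
    achieved count is returned with a warning.
    """
    coords = emb.coordinates if hasattr(emb, "coordinates") else pd.DataFrame(emb)
    X = coords.to_numpy(dtype=float)
    n = X.shape[0]
    if target_k > n:
        raise ValidationError("target_k exceeds the number of cells")
    if target_k == 1:
        return ArchetypeAssignment(
            labels=pd.Series(np.zeros(n, dtype=int), index=coords.index), resolution=None
        )
    k_nn = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row) for row in idx]  # includes self, as in SNN conventions

    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[int(j)])
            jac = inter / (len(neigh[i] | neigh[int(j)]))
            if jac >= prune:
                edges.append((i, int(j)))
                weights.append(jac)
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = weights

    def louvain(res: float) -> np.ndarray:
        part = graph.community_multilevel(weights="weight", resolution=res)
        labels = np.asarray(part.membership)
        # fold micro-communities (stray SNN components) into the nearest
        # real cluster by centroid distance, as graph clusterings of noisy
        # embeddings conventionally do with singletons
        counts = np.bincount(labels)
        small = np.flatnonzero(counts < min_cluster_size)
        big = np.flatnonzero(counts >= min_cluster_size)
        if small.size and big.size:
            centroids = np.vstack([X[labels == b].mean(axis=0) for b in big])
            for s in small:
                for i in np.flatnonzero(labels == s):
                    labels[i] = big[
                        np.argmin(((centroids - X[i]) ** 2).sum(axis=1))
                    ]
        return labels

    lo, hi = resolution_bounds
    best = None  # (|count - target|, resolution, labels)
    for res in (lo, hi):
        labels = louvain(res)
        cand = (abs(len(set(labels)) - target_k), res, labels)
        if best is None or cand[0] < best[0]:
            best = cand
    while best[0] != 0 and max_steps > 0:
        max_steps -= 1
        mid = np.sqrt(lo * hi)  # geometric bisection: resolution acts multiplicatively
        labels = louvain(mid)
        count = len(set(labels))
        cand = (abs(count - target_k), mid, labels)
        if cand[0] < best[0]:
            best = cand
        if count == target_k:
            break
        if count < target_k:
            lo = mid
        else:
            hi = mid
    gap, resolution, labels = best
    if gap:
        logger.warning(
            "could not reach %d clusters; returning %d at resolution %.4f",
            target_k, len(set(labels)), resolution,
        )
    # relabel by decreasing cluster size for stable, readable archetype ids
    order = pd.Series(labels).value_counts().index
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    return ArchetypeAssignment(
        labels=pd.Series(labels, index=coords.index), resolution=float(resolution)
    )


def dpe_wilcoxon(scores, labels: pd.Series, top_n: int = 20) -> pd.DataFrame:
    """Differential pathway enrichment: each archetype vs all other cells.

    Two-sided Wilcoxon rank-sum per pathway, effect = difference of mean
    scores, BH across pathways within each archetype. The profile keeps the
    ``top_n`` positively enriched pathways ranked by fdr then |effect|.
    Archetypes with fewer than 3 cells are excluded with a warning.
    """
    frame = scores.scores if hasattr(scores, "scores") else pd.DataFrame(scores)
    frame = frame.loc[labels.index]
    arr = frame.to_numpy(dtype=float)
    labs = labels.to_numpy()
    archetypes = np.unique(labs)
    if archetypes.size < 2:
        raise ValidationError("need at least 2 archetypes for DPE")
    rows = []
    for a in archetypes:
        mask = labs == a
        if mask.sum() < 3:
            logger.warning("archetype %s has < 3 cells; excluded from DPE", a)
            continue
        x, y = arr[mask], arr[~mask]
        effects = x.mean(axis=0) - y.mean(axis=0)
        pvals = np.ones(arr.shape[1])
        for j in range(arr.shape[1]):
            if np.all(x[:, j] == x[0, j]) and np.all(y[:, j] == x[0, j]):
                pvals[j] = 1.0  # identical distributions, no evidence
            else:
                pvals[j] = stats.mannwhitneyu(
                    x[:, j], y[:, j], alternative="two-sided"
                ).pvalue
        fdr = bh_adjust(pvals)
        table = pd.DataFrame(
            {
                "archetype": a,
                "pathway": frame.columns,
                "effect": effects,
                "p": pvals,
                "fdr": fdr,
            }
        )
        table = table[table["effect"] > 0]
        table = table.sort_values(
            ["fdr", "effect"], ascending=[True, False], kind="stable"
        ).head(top_n)
        rows.append(table)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["archetype", "pathway", "effect", "p", "fdr"]
    )


def archetype_proportions(labels: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Fraction of cells per archetype within each (patient, cycle)."""
    meta = meta.set_index("cell_id")
    covered = labels.index.intersection(meta.index)
    if len(covered) < len(labels):
        raise ValidationError("metadata does not cover all labeled cells")
    df = pd.DataFrame(
        {
            "archetype": labels.loc[covered].to_numpy(),
            "patient": meta.loc[covered, "patient"].to_numpy(),
            "cycle": meta.loc[covered, "cycle"].to_numpy(),
        }
    )
    counts = (
        df.groupby(["patient", "cycle", "archetype"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["patient", "cycle"], observed=True)["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts


def kmeans_cna_subclones(
    cna_profiles, k: int = 2, seed: int = 0, meta: pd.DataFrame | None = None
):
    """K-means subclone clustering of per-cell copy-number profiles.

    Euclidean k-means with 10 restarts. Returns labels (and, when metadata
    is supplied, a per-cluster per-cycle abundance table).
    """
    frame = pd.DataFrame(cna_profiles)
    X = frame.to_numpy(dtype=float)
    if k >= X.shape[0]:
        raise ValidationError("k must be smaller than the number of cells")
    if np.unique(X, axis=0).shape[0] < k:
        logger.warning("fewer distinct profiles than clusters; split is arbitrary but seed-stable")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    labels = pd.Series(km.labels_, index=frame.index, name="subclone")
    if meta is None:
        return labels
    abundance = archetype_proportions(labels, meta).rename(
        columns={"archetype": "subclone"}
    )
    return labels, abundance
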