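"""Similarity-aware cross-validation and performance metrics.

Standard random folds overestimate generalization for interaction data
because near-identical dimers land on both sides of a split.  Folds are
therefore built by partitioning a record-similarity graph (edge weight
1 - Jaccard distance between feature supports, sparsified to k nearest
neighbours) so that similar records share a fold, under per-stratum balance
(~80% non-binders, ~10% strong binders with Kd < 50 nM, ~10% weaker
binders per fold).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import pearsonr, rankdata

from .data import Dataset
from .features import DimerFeaturizer
from .semisvr import DEFAULT_C_GRID, DEFAULT_EPS_GRID, SemiSVR, grid_search


# -- metrics -------------------------------------------------------------------


def metrics(
    pred,
    log10_kd,
    kd_nM,
    strong_cut: float = 250.0,
    ceiling: float = 5000.0,
    binder_lo_nM: float = 1.0,
) -> tuple[float, float]:
    """Pearson R on binders and strong-vs-weak AUC.

    R is computed on records with ``binder_lo_nM < Kd < ceiling`` in log10
    space (NaN if fewer than 3 such records).  The AUC contrasts strong
    binders (Kd < strong_cut) against weak/non-binders (Kd >= ceiling),
    intermediates excluded, via the Mann-Whitney rank statistic with tie
    correction; scores are oriented so that a lower score marks the strong
    class.
    """
    pred = np.asarray(pred, dtype=float)
    log10_kd = np.asarray(log10_kd, dtype=float)
    kd_nM = np.asarray(kd_nM, dtype=float)
    valid = ~np.isnan(pred)

    binders = valid & (kd_nM > binder_lo_nM) & (kd_nM < ceiling)
    if binders.sum() >= 3 and np.std(pred[binders]) > 0 and np.std(log10_kd[binders]) > 0:
        r = float(pearsonr(pred[binders], log10_kd[binders])[0])
    else:
        r = float("nan")

    strong = valid & (kd_nM < strong_cut)
    weak = valid & (kd_nM >= ceiling)
    n1, n0 = int(strong.sum()), int(weak.sum())
    if n1 == 0 or n0 == 0:
        auc = float("nan")
    else:
        # rank low scores first; AUC = P(score_strong < score_weak) + .5 P(tie)
        scores = np.concatenate([pred[strong], pred[weak]])
        ranks = rankdata(scores)
        # this is P(score_strong < score_weak) + .5 P(tie): low-scoring strong
        # binders drive the AUC toward 1
        auc = float((n1 * n0 + n1 * (n1 + 1) / 2 - ranks[:n1].sum()) / (n1 * n0))
    return r, auc


# -- balanced, similarity-aware partitioning -------------------------------------


def _strata(dataset: Dataset) -> list[str]:
    out = []
    for rec in dataset.records:
        if rec.kd_nM < 50:
            out.append("<50")
        elif rec.kd_nM < dataset.ceiling:
            out.append("50-5000")
        else:
            out.append(">=5000")
    return out


def _similarity_knn(X_binary, k_neighbors: int = 20) -> dict[tuple[int, int], float]:
    """Sparse symmetric similarity edges (1 - Jaccard distance on feature
    supports) keeping each record's k most similar neighbours.

    ``X_binary`` is a records-by-features 0/1 sparse matrix; intersection
    sizes come from one sparse product, so this matches the per-pair Jaccard
    on supports exactly.
    """
    import scipy.sparse as sp

    B = sp.csr_matrix(X_binary, dtype=float)
    B.data[:] = 1.0
    nnz = np.asarray(B.sum(axis=1)).ravel()
    inter = (B @ B.T).tocsr()
    n = B.shape[0]
    sims: dict[tuple[int, int], float] = {}
    for i in range(n):
        lo, hi = inter.indptr[i], inter.indptr[i + 1]
        cols = inter.indices[lo:hi]
        vals = inter.data[lo:hi]
        union = nnz[i] + nnz[cols] - vals
        with np.errstate(invalid="ignore"):
            s = np.where(union > 0, vals / union, 0.0)
        mask = cols != i
        cols, s = cols[mask], s[mask]
        if cols.size > k_neighbors:
            top = np.argpartition(-s, k_neighbors)[:k_neighbors]
            cols, s = cols[top], s[top]
        for j, sij in zip(cols, s):
            if sij > 0:
                sims[(min(i, int(j)), max(i, int(j)))] = float(sij)
    return sims


def partition(
    dataset: Dataset,
    K: int = 10,
    seed: int = 0,
    k_neighbors: int = 20,
    n_sweeps: int = 8,
    feature_vectors=None,
) -> np.ndarray:
    """Assign each record a fold 1..K, balanced within strata, with similar
    records preferentially co-located.

    Connected components of the similarity graph are placed whole into folds
    where per-stratum capacity allows (so similar records share a fold), then
    same-stratum swaps further reduce the weight of similarity edges cut by
    the partition.  Per-stratum fold sizes are fixed to within one record.
    Deterministic for a given seed.
    """
    n = len(dataset.records)
    if K > n:
        raise ValueError(f"K={K} exceeds number of records ({n})")
    rng = np.random.default_rng(seed)
    strata = _strata(dataset)
    if feature_vectors is None:
        feature_vectors = DimerFeaturizer().fit_transform(dataset)
    sims = _similarity_knn(feature_vectors, k_neighbors)

    # per-stratum fold capacities (sizes differ by at most one); which folds
    # take the remainder is randomized by the seed
    stratum_names = sorted(set(strata))
    capacity: dict[str, np.ndarray] = {}
    for s in stratum_names:
        m = sum(1 for st in strata if st == s)
        cap = np.full(K, m // K)
        cap[rng.permutation(K)[: m % K]] += 1
        capacity[s] = cap

    # union-find over similarity edges: whole components seed the same fold
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j) in sims:
        parent[find(i)] = find(j)
    comp_members: dict[int, list[int]] = {}
    for i in range(n):
        comp_members.setdefault(find(i), []).append(i)
    components = sorted(comp_members.values(), key=lambda c: (-len(c), c[0]))

    fold = np.zeros(n, dtype=int)
    for comp in components:
        # fold that can absorb the most of this component
        scores = np.zeros(K)
        for k in range(K):
            for s in stratum_names:
                want = sum(1 for i in comp if strata[i] == s)
                scores[k] += min(want, capacity[s][k])
        best_k = int(np.argmax(scores))
        for i in comp:
            k = best_k
            if capacity[strata[i]][k] == 0:  # spill to the roomiest fold
                k = int(np.argmax(capacity[strata[i]]))
            capacity[strata[i]][k] -= 1
            fold[i] = k + 1

    # adjacency for local refinement
    nbrs: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    for (i, j), s in sims.items():
        nbrs[i].append((j, s))
        nbrs[j].append((i, s))

    def gain_of_move(i: int, f_new: int) -> float:
        g = 0.0
        for j, s in nbrs[i]:
            if fold[j] == fold[i]:
                g -= s
            elif fold[j] == f_new:
                g += s
        return g

    order = np.arange(n)
    for _ in range(n_sweeps):
        improved = False
        rng.shuffle(order)
        for i in order:
            # best same-stratum swap partner (keeps all stratum counts fixed)
            best = (0.0, None)
            for j, _s in nbrs[i]:
                if fold[j] == fold[i] or strata[j] != strata[i]:
                    continue
                g = gain_of_move(i, fold[j]) + gain_of_move(j, fold[i])
                for jj, ss in nbrs[i]:
                    if jj == j:  # i and j stay connected after the swap
                        g -= 2 * ss
                if g > best[0] + 1e-12:
                    best = (g, j)
            if best[1] is not None:
                j = best[1]
                fold[i], fold[j] = fold[j], fold[i]
                improved = True
        if not improved:
            break
    return fold


def _stratified_folds(kd_nM, ceiling, K, seed) -> list[np.ndarray]:
    """Plain stratified folds (no similarity graph), for inner loops."""
    rng = np.random.default_rng(seed)
    n = len(kd_nM)
    strata = np.where(
        np.asarray(kd_nM) < 50, 0, np.where(np.asarray(kd_nM) < ceiling, 1, 2)
    )
    fold = np.zeros(n, dtype=int)
    for s in np.unique(strata):
        idx = np.where(strata == s)[0]
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold[i] = pos % K + 1
    return [np.where(fold == k)[0] for k in range(1, K + 1)]


# -- nested cross-validation -----------------------------------------------------


def nested_cv(
    dataset: Dataset,
    K: int = 10,
    inner_K: int = 10,
    seed: int = 0,
    C1_grid=DEFAULT_C_GRID,
    C2_grid=DEFAULT_C_GRID,
    eps_grid=DEFAULT_EPS_GRID,
    categories=None,
    binders_only: bool = False,
    featurizer: DimerFeaturizer | None = None,
    fold_assignment: np.ndarray | None = None,
) -> dict:
    """Outer-CV performance with inner-CV hyperparameter selection.

    Every outer fold is scored by a model whose hyperparameters were chosen
    by ``inner_K``-fold grid search on the remaining data only, so no record
    ever influences the model that scores it.  Predictions on held-out folds
    are pooled; R is computed on binders (1 nM < Kd < ceiling) and AUC on
    strong (< 250 nM) vs weak/non (>= ceiling).

    ``binders_only`` drops censored records from every training set (their
    held-out predictions are still made), to quantify what the one-sided
    censored constraints contribute.
    """
    feat = featurizer or DimerFeaturizer(categories=categories)
    X = feat.fit_transform(dataset)
    y = np.array([r.log10_kd for r in dataset.records])
    kd = np.array([r.kd_nM for r in dataset.records])
    censored = np.array([r.is_censored for r in dataset.records])
    n = len(dataset.records)

    if fold_assignment is None:
        fold_assignment = partition(dataset, K=K, seed=seed, feature_vectors=X)
    folds = [np.where(fold_assignment == k)[0] for k in range(1, K + 1)]

    pred = np.full(n, np.nan)
    detail = []
    for k, test_idx in enumerate(folds, start=1):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if binders_only:
            train_mask &= ~censored
        tr = np.where(train_mask)[0]
        inner = _stratified_folds(kd[tr], dataset.ceiling, inner_K, seed * 1000 + k)
        C1, C2, eps = grid_search(
            X[tr],
            y[tr],
            censored[tr],
            kd[tr],
            inner,
            C1_grid=C1_grid,
            C2_grid=C2_grid,
            eps_grid=eps_grid,
            ceiling=dataset.ceiling,
        )
        est = SemiSVR(C1=C1, C2=C2, epsilon=eps).fit(X[tr], y[tr], censored[tr])
        pred[test_idx] = est.predict(X[test_idx])
        detail.append({"fold": k, "C1": C1, "C2": C2, "epsilon": eps, "n_train": len(tr)})

    r, auc = metrics(pred, y, kd, ceiling=dataset.ceiling)
    return {
        "r": r,
        "auc": auc,
        "pred": pred,
        "log10_kd": y,
        "kd_nM": kd,
        "folds": detail,
        "fold_assignment": fold_assignment,
    }


def bootstrap_ci(
    pred, log10_kd, kd_nM, B: int = 1000, seed: int = 0, ceiling: float = 5000.0
) -> tuple[float, float, float]:
    """Percentile 95% CI of the binder Pearson R under pair resampling."""
    pred = np.asarray(pred, dtype=float)
    log10_kd = np.asarray(log10_kd, dtype=float)
    kd_nM = np.asarray(kd_nM, dtype=float)
    r, _ = metrics(pred, log10_kd, kd_nM, ceiling=ceiling)
    rng = np.random.default_rng(seed)
    n = len(pred)
    rs = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rb, _ = metrics(pred[idx], log10_kd[idx], kd_nM[idx], ceiling=ceiling)
        if not math.isnan(rb):
            rs.append(rb)
    if not rs:
        return r, float("nan"), float("nan")
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return r, float(lo), float(hi)


def permutation_control(dataset: Dataset, seed: int = 0, **cv_kwargs) -> dict:
    """Nested CV after jointly reshuffling Kd values across records.

    A sound validation protocol must report no signal here (R about 0, AUC
    about 0.5); anything else indicates information leakage.
    """
    from .data import InteractionRecord

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset.records))
    shuffled = [
        InteractionRecord(
            idA=rec.idA,
            idB=rec.idB,
            kd_nM=dataset.records[p].kd_nM,
            ceiling=dataset.ceiling,
        )
        for rec, p in zip(dataset.records, perm)
    ]
    return nested_cv(dataset.subset(shuffled), seed=seed, **cv_kwargs)


def learning_curve(
    dataset: Dataset, fractions=None, seed: int = 0, **cv_kwargs
) -> list[dict]:
    """Nested-CV performance on stratified random subsets of the records."""
    fractions = fractions or [x / 10 for x in range(1, 11)]
    rng = np.random.default_rng(seed)
    strata = _strata(dataset)
    rows = []
    for frac in fractions:
        if frac >= 1.0:
            sub = dataset
        else:
            take: list[int] = []
            for s in sorted(set(strata)):
                idx = [i for i, st in enumerate(strata) if st == s]
                m = int(round(frac * len(idx)))
                take.extend(rng.choice(idx, size=m, replace=False))
            sub = dataset.subset([dataset.records[i] for i in sorted(take)])
        res = nested_cv(sub, seed=seed, **cv_kwargs)
        rows.append({"fraction": frac, "n": len(sub), "r": res["r"], "auc": res["auc"]})
    return rows


# -- identity-constrained train/test split ---------------------------------------


def core_identity(a, b) -> float:
    """Fraction of identical residues at a, d, e, g positions over the
    aligned overlap (coils paired on a common register frame)."""
    ca, cb = a.core_residues(), b.core_residues()
    n = min(len(ca), len(cb))
    if n == 0:
        return 0.0
    return sum(ca[i] == cb[i] for i in range(n)) / n


def identity_split(
    dataset: Dataset, max_identity: float = 0.50, target_fraction: float = 0.70
) -> tuple[list[int], list[int], dict]:
    """Split records so no cross-side protein pair exceeds ``max_identity``.

    Proteins are clustered by single linkage at the identity threshold;
    whole clusters are then assigned greedily (largest first) to approach
    ``target_fraction`` of records on the training side.  Records bridging
    the two sides are dropped.  Returns (train record indices, test record
    indices, info).
    """
    ids = dataset.protein_ids()
    index = {p: i for i, p in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, pi in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if core_identity(dataset.coils[pi], dataset.coils[ids[j]]) > max_identity:
                parent[find(i)] = find(j)

    clusters: dict[int, list[str]] = {}
    for i, p in enumerate(ids):
        clusters.setdefault(find(i), []).append(p)
    # records per cluster pair
    cluster_of = {p: find(index[p]) for p in ids}
    weight = {c: 0 for c in clusters}
    for rec in dataset.records:
        ca, cb = cluster_of[rec.idA], cluster_of[rec.idB]
        weight[ca] += 1
        if cb != ca:
            weight[cb] += 1

    train_clusters: set[int] = set()
    total = len(dataset.records)
    got = 0
    for c in sorted(clusters, key=lambda c: (-weight[c], min(clusters[c]))):
        if got / total < target_fraction:
            train_clusters.add(c)
            got += weight[c]

    train_idx, test_idx, dropped = [], [], 0
    for i, rec in enumerate(dataset.records):
        ca, cb = cluster_of[rec.idA], cluster_of[rec.idB]
        a_in, b_in = ca in train_clusters, cb in train_clusters
        if a_in and b_in:
            train_idx.append(i)
        elif not a_in and not b_in:
            test_idx.append(i)
        else:
            dropped += 1
    frac = len(train_idx) / max(1, len(train_idx) + len(test_idx))
    info = {"dropped_bridging": dropped, "train_fraction": frac}
    if not test_idx:
        info["warning"] = "one identity cluster dominates; split is best-effort"
    return train_idx, test_idx, info
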