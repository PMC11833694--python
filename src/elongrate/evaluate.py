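"""Model evaluation: windowed prediction r2, k-mer clustering, rate tracks.

Per-nucleotide read counts are too sparse to score directly, so predicted
and observed tracks are averaged in non-overlapping windows before
computing a pooled squared Pearson correlation.  Fitted 5-mer coefficients
are summarized by sign-stratified K-means clusters with per-cluster
position-frequency matrices suitable for sequence-logo rendering.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import pearsonr

from elongrate.core_io import TranscriptionUnit, write_bedgraph
from elongrate.features import FeatureMatrix
from elongrate.glm import GLMFit, predict_zeta

__all__ = [
    "pooled_r2",
    "windowed_r2",
    "cluster_kmers",
    "export_rate_track",
    "heldout_zeta_r2",
    "evaluate_kmer_replicate",
]

_BASES = "ACGT"


def pooled_r2(pred: list[np.ndarray], obs: list[np.ndarray]) -> float:
    """Squared Pearson correlation pooling all sites across TUs."""
    p = np.concatenate([np.asarray(x, dtype=float).ravel() for x in pred])
    o = np.concatenate([np.asarray(x, dtype=float).ravel() for x in obs])
    if p.size != o.size:
        raise ValueError("prediction and observation sizes differ")
    if np.std(p) == 0 or np.std(o) == 0:
        return 0.0
    return float(pearsonr(p, o).statistic ** 2)


def windowed_r2(
    predicted: list[np.ndarray],
    observed: list[np.ndarray],
    window_sizes: list[int],
    per_gene: bool = False,
) -> dict[int, float]:
    """r2 between window-averaged predicted and observed tracks.

    For each window size both tracks are averaged in non-overlapping
    windows per TU (final partial window dropped), pooled across TUs, and
    scored by squared Pearson correlation.  ``per_gene=True`` instead
    averages per-TU r2 values.
    """
    out = {}
    for w in window_sizes:
        if w <= 0:
            raise ValueError("window size must be positive")
        pooled_p, pooled_o, gene_r2 = [], [], []
        for p, o in zip(predicted, observed):
            p = np.asarray(p, dtype=float)
            o = np.asarray(o, dtype=float)
            nw = p.size // w
            if nw == 0:
                continue
            pw = p[: nw * w].reshape(nw, w).mean(axis=1)
            ow = o[: nw * w].reshape(nw, w).mean(axis=1)
            pooled_p.append(pw)
            pooled_o.append(ow)
            if per_gene and nw >= 2 and np.std(pw) > 0 and np.std(ow) > 0:
                gene_r2.append(float(pearsonr(pw, ow).statistic ** 2))
        if not pooled_p:
            raise ValueError(f"window size {w} larger than every TU")
        if per_gene:
            out[w] = float(np.mean(gene_r2)) if gene_r2 else 0.0
        else:
            out[w] = pooled_r2(pooled_p, pooled_o)
    return out


def _pfm(kmers: list[str]) -> np.ndarray:
    """Position-frequency matrix (positions x ACGT), rows summing to 1."""
    k = len(kmers[0])
    counts = np.zeros((k, 4))
    for kmer in kmers:
        for pos, base in enumerate(kmer):
            counts[pos, _BASES.index(base)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def cluster_kmers(
    kappa_table: dict[str, float],
    top_n: int = 50,
    n_clusters: int = 2,
    seed: int = 0,
) -> dict[str, list[dict]]:
    """Sign-stratified K-means clusters of k-mer coefficients with PFMs.

    k-mers are split by coefficient sign; within each group the ``top_n``
    by absolute coefficient are clustered on the scalar coefficient values
    (K = ``n_clusters``).  Each cluster carries its member k-mers, mean
    coefficient, and position-frequency matrix for logo rendering.  Groups
    with fewer than two distinct members fall back to a single cluster.
    """
    from sklearn.cluster import KMeans

    out: dict[str, list[dict]] = {}
    for sign_name, sign in (("positive", 1), ("negative", -1)):
        items = [
            (kmer, k) for kmer, k in kappa_table.items() if np.sign(k) == sign
        ]
        items.sort(key=lambda kv: -abs(kv[1]))
        items = items[:top_n]
        if not items:
            out[sign_name] = []
            continue
        values = np.array([k for _, k in items]).reshape(-1, 1)
        if len(items) < 2 or np.unique(values).size < n_clusters:
            warnings.warn(
                f"{sign_name} group too small/degenerate for K-means; "
                "returning a single cluster",
                stacklevel=2,
            )
            labels = np.zeros(len(items), dtype=int)
        else:
            km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
            labels = km.fit_predict(values)
        clusters = []
        for lab in sorted(set(labels)):
            members = [items[i][0] for i in np.flatnonzero(labels == lab)]
            coefs = [items[i][1] for i in np.flatnonzero(labels == lab)]
            clusters.append(
                {
                    "kmers": members,
                    "mean_kappa": float(np.mean(coefs)),
                    "pfm": _pfm(members),
                }
            )
        clusters.sort(key=lambda c: -abs(c["mean_kappa"]))
        out[sign_name] = clusters
    return out


def export_rate_track(
    fit: GLMFit,
    features: FeatureMatrix,
    tus: list[TranscriptionUnit],
    path,
) -> None:
    """Write predicted zeta per nucleotide as bedGraph.

    Minus-strand rates are emitted as negative values (positive = plus
    strand, negative = minus strand).
    """
    zetas = predict_zeta(fit.kappa, features)
    values = {tu.id: z for tu, z in zip(tus, zetas)}
    write_bedgraph(values, tus, path)


def heldout_zeta_r2(datasets, fit_config=None) -> dict:
    """Train/test evaluation of the GLM on synthetic benchmark replicates.

    For each replicate the GLM is fitted on the training TUs; zeta is
    predicted on the held-out TUs and compared with the replicate's true
    local rates, pooling sites across replicates.  Returns the pooled r2
    plus the per-replicate fitted coefficients.
    """
    from elongrate import glm as _glm

    preds, truths, kappas = [], [], []
    for ds in datasets:
        tr = list(ds.train_idx)
        te = list(ds.test_idx)
        f = _glm.fit(
            [ds.tus[i] for i in tr], ds.features.subset_tus(tr), fit_config
        )
        zhat = predict_zeta(f.kappa, ds.features.subset_tus(te))
        preds.extend(zhat)
        truths.extend(ds.zeta_true[i] for i in te)
        kappas.append(f.kappa)
    return {
        "r2": pooled_r2(preds, truths),
        "kappa": np.vstack(kappas),
        "feature_names": list(datasets[0].features.names),
        "n_test_sites": int(sum(t.size for t in truths)),
    }


def evaluate_kmer_replicate(
    ds, nu_grid, fit_config=None, seed: int = 0
) -> dict:
    """L1-penalized 5-mer fit with AIC-selected penalty on one replicate.

    The penalty strength is chosen by held-out AIC within the training
    TUs; zeta is then predicted on the replicate's held-out TUs.  Reports
    the pooled r2 against the true rates, the nonzero-coefficient count,
    and the overlap with the true nonzero 5-mer set.
    """
    from elongrate import glm as _glm

    tr = list(ds.train_idx)
    te = list(ds.test_idx)
    nu, f = _glm.select_nu(
        [ds.tus[i] for i in tr],
        ds.features.subset_tus(tr),
        nu_grid,
        config=fit_config,
        seed=seed,
    )
    zhat = predict_zeta(f.kappa, ds.features.subset_tus(te))
    truth = [ds.zeta_true[i] for i in te]
    nonzero = set(f.nonzero_features())
    true_set = set(ds.true_feature_names or [])
    overlap = len(nonzero & true_set) / max(len(true_set), 1)
    return {
        "r2": pooled_r2(zhat, truth),
        "nu": nu,
        "fit": f,
        "n_nonzero": f.nonzero_count(),
        "overlap_with_true": overlap,
        "n_test_sites": int(sum(t.size for t in truth)),
    }
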