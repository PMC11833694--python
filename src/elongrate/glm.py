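"""Poisson GLM for local elongation rates, fitted by gradient ascent.

Model: read counts at site *i* of gene *j* are Poisson with mean
``lam * chi_j / zeta_ij`` where ``zeta_ij = exp(kappa . Y_ij)`` is the local
relative elongation rate, ``chi_j`` is a per-gene compound parameter
(initiation-to-elongation ratio) and ``lam`` is the average read depth over
all analyzed sites.  Dropping terms constant in the parameters, the joint
log likelihood over M genes is

    l = sum_j [ s_j log chi_j - kappa . T_j - lam * chi_j * U_j ]

with sufficient statistics ``s_j = sum_i X_ij``, ``T_j = sum_i X_ij Y_ij``
(fixed) and ``U_j = sum_i exp(-kappa . Y_ij)`` (recomputed each iteration).
For fixed ``kappa`` the optimum in ``chi_j`` is analytic,
``chi_j = s_j / (lam * U_j)``; ``kappa`` is improved by gradient steps with
component ``sum_j [lam * chi_j * V_jn - T_jn]`` where
``V_j = sum_i exp(-kappa . Y_ij) Y_ij``.  An optional L1 penalty
``-nu * sum_n |kappa_n|`` induces sparsity for high-dimensional k-mer
features, with the penalty strength chosen by held-out AIC.

Indicator features are kept in raw (mostly zero) sparse form; ``U_j`` and
``V_j`` are computed from the raw values and mapped to their standardized
counterparts through the affine standardization transform, so per-iteration
cost is proportional to the number of nonzero raw entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from elongrate.core_io import TranscriptionUnit
from elongrate.features import FeatureMatrix

__all__ = [
    "FitConfig",
    "GLMFit",
    "SeqBias",
    "log_likelihood",
    "gradient_kappa",
    "update_chi",
    "fit",
    "fit_batches",
    "select_nu",
    "predict_zeta",
    "expected_counts",
    "sufficient_stats_sparse",
    "estimate_rho",
    "log_likelihood_biased",
]


@dataclass
class FitConfig:
    """Settings for the gradient-ascent fit.

    ``learning_rate`` is the multiplier for the gradient at the first
    iteration; with ``adapt_lr`` it grows by ``lr_growth`` after each
    accepted step and halves whenever a step would decrease the (penalized)
    objective, which keeps the objective trace monotone.  With
    ``adapt_lr=False`` the rate is fixed and ten consecutive objective
    decreases abort the fit.
    """

    learning_rate: float = 1e-7
    adapt_lr: bool = True
    lr_growth: float = 1.05
    tol: float = 1e-8
    max_iter: int = 50_000
    penalty: str = "none"  # none | l1 | l2 | elasticnet
    nu: float = 0.0
    l1_ratio: float = 0.5  # elasticnet mix
    zero_threshold: float = 1e-6
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.penalty not in ("none", "l1", "l2", "elasticnet"):
            raise ValueError(f"unknown penalty {self.penalty!r}")


@dataclass
class GLMFit:
    """Result of a GLM fit."""

    feature_names: list[str]
    kappa: np.ndarray
    chi: np.ndarray
    tu_ids: list[str]
    lam: float
    nu: float
    penalty: str
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    se: np.ndarray | None = None
    zero_threshold: float = 1e-6
    diagnostics: dict = field(default_factory=dict)

    def nonzero_count(self) -> int:
        return int(np.sum(np.abs(self.kappa) > self.zero_threshold))

    def nonzero_features(self) -> list[str]:
        idx = np.flatnonzero(np.abs(self.kappa) > self.zero_threshold)
        return [self.feature_names[i] for i in idx]

    def kappa_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "kappa": self.kappa,
                "se": self.se if self.se is not None else np.nan,
            }
        )


@dataclass
class SeqBias:
    """3'-nucleotide composition bias: bulk frequencies pi and rho = 4 pi."""

    pi: np.ndarray  # order A, C, G, T

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or np.any(self.pi < 0):
            raise ValueError("pi must be four non-negative frequencies")
        s = self.pi.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"pi must sum to 1, got {s}")

    @property
    def rho(self) -> np.ndarray:
        return 4.0 * self.pi

    def log_rho_track(self, seq: str) -> np.ndarray:
        """Per-site log rho for a transcription-strand sequence (N sites: 0)."""
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        with np.errstate(divide="ignore"):
            logr = np.log(self.rho)
        out = np.zeros(len(seq))
        for i, c in enumerate(seq):
            if c in code:
                out[i] = logr[code[c]]
        return out


# ---------------------------------------------------------------------------
# internal design (concatenated, masked sites)


class _Design:
    """Masked, concatenated view of counts and features for fast iteration."""

    def __init__(
        self,
        tus: list[TranscriptionUnit],
        fm: FeatureMatrix,
        offsets: list[np.ndarray] | None = None,
        lam: float | None = None,
    ):
        if len(tus) != fm.n_tus:
            raise ValueError("number of TUs does not match feature matrix")
        self.names = fm.names
        self.n_features = fm.n_features
        self.sparse = fm.is_sparse
        self.means = fm.means
        self.sds = fm.sds

        blocks, xs, offs, kept = [], [], [], []
        for t, tu in enumerate(tus):
            if fm.n_sites(t) != tu.length:
                raise ValueError(f"TU {tu.id}: feature block length mismatch")
            m = tu.mask
            x = tu.counts[m]
            if x.sum() <= 0:
                continue  # degenerate gene: chi would be 0
            kept.append(t)
            xs.append(x)
            if self.sparse:
                blocks.append(fm.raw[t][m].tocsr())
            else:
                blocks.append(fm.values(t)[m])
            if offsets is not None:
                o = np.asarray(offsets[t], dtype=float)[m]
                if np.any(np.isneginf(o) & (x > 0)):
                    raise ValueError(
                        f"TU {tu.id}: zero 3'-base frequency at sites with counts"
                    )
                offs.append(o)
        if not kept:
            raise ValueError("no gene with positive read counts")
        dropped = len(tus) - len(kept)
        if dropped:
            warnings.warn(f"excluded {dropped} gene(s) with zero counts", stacklevel=3)

        self.tu_ids = [tus[t].id for t in kept]
        self.kept = kept
        self.x = np.concatenate(xs)
        self.bounds = np.concatenate(([0], np.cumsum([x.size for x in xs])))
        self.starts = self.bounds[:-1]
        self.M = len(kept)
        self.n_sites_total = self.x.size
        self.offsets = np.concatenate(offs) if offs else None

        if self.sparse:
            self.Yraw = sp.vstack(blocks, format="csr")
            self.mu_over_sd = self.means / self.sds
        else:
            self.Y = np.vstack(blocks)

        self.s = np.add.reduceat(self.x, self.starts)
        # T_j on standardized features
        if self.sparse:
            Traw = np.vstack(
                [
                    np.asarray((blocks[j].T @ xs[j])).ravel()
                    for j in range(self.M)
                ]
            )
            self.T = (Traw - np.outer(self.s, self.means)) / self.sds
        else:
            self.T = np.vstack([blocks[j].T @ xs[j] for j in range(self.M)])
        self.T_sum = self.T.sum(axis=0)
        self.N = np.diff(self.bounds).astype(float)
        self.lam = lam if lam is not None else float(self.x.sum() / self.x.size)
        self.bias_const = (
            float(self.x @ self.offsets) if self.offsets is not None else 0.0
        )

    def eta(self, kappa: np.ndarray) -> np.ndarray:
        """Per-site exponent kappa . Y_i minus any sequence-bias offset."""
        if self.sparse:
            a = kappa / self.sds
            e = self.Yraw @ a - float(kappa @ self.mu_over_sd)
        else:
            e = self.Y @ kappa
        if self.offsets is not None:
            e = e - self.offsets
        return e

    def site_weights(self, kappa: np.ndarray) -> np.ndarray:
        w = np.exp(-self.eta(kappa))
        if not np.all(np.isfinite(w)):
            n = int(np.argmax(np.abs(kappa)))
            raise FloatingPointError(
                f"non-finite intermediate in U/V computation "
                f"(largest |kappa| at feature {self.names[n]!r})"
            )
        return w

    def U(self, w: np.ndarray) -> np.ndarray:
        return np.add.reduceat(w, self.starts)

    def UV(self, kappa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene U_j and V_j (on the standardized feature scale)."""
        w = self.site_weights(kappa)
        U = self.U(w)
        V = np.empty((self.M, self.n_features))
        for j in range(self.M):
            lo, hi = self.bounds[j], self.bounds[j + 1]
            if self.sparse:
                vraw = np.asarray(self.Yraw[lo:hi].T @ w[lo:hi]).ravel()
                V[j] = (vraw - self.means * U[j]) / self.sds
            else:
                V[j] = w[lo:hi] @ self.Y[lo:hi]
        return U, V

    def weighted_feature_sum(self, c: np.ndarray) -> np.ndarray:
        """sum_i c_i * Y_i over all sites (standardized scale)."""
        if self.sparse:
            vraw = np.asarray(self.Yraw.T @ c).ravel()
            return (vraw - self.means * c.sum()) / self.sds
        return c @ self.Y


def _penalty_value(kappa: np.ndarray, cfg: FitConfig) -> float:
    if cfg.penalty == "none" or cfg.nu == 0:
        return 0.0
    l1 = np.abs(kappa).sum()
    l2 = float(kappa @ kappa)
    if cfg.penalty == "l1":
        return cfg.nu * l1
    if cfg.penalty == "l2":
        return cfg.nu * l2
    return cfg.nu * (cfg.l1_ratio * l1 + (1 - cfg.l1_ratio) * l2)


def _profile_objective(design: _Design, kappa: np.ndarray):
    """Objective with chi at its analytic optimum; returns (obj, U, chi, w).

    An overflowing exponent yields a -inf objective (handled by the fit's
    step control) rather than an exception.
    """
    with np.errstate(over="ignore"):
        w = np.exp(-design.eta(kappa))
    if not np.all(np.isfinite(w)):
        return -np.inf, None, None, None
    U = design.U(w)
    chi = design.s / (design.lam * U)
    obj = (
        float(design.s @ np.log(chi))
        - float(kappa @ design.T_sum)
        - float(design.s.sum())
        + design.bias_const
    )
    return obj, U, chi, w


# ---------------------------------------------------------------------------
# public operations


def _as_design(tus, features, offsets=None, lam=None) -> _Design:
    if isinstance(tus, _Design):
        return tus
    return _Design(list(tus), features, offsets=offsets, lam=lam)


def log_likelihood(
    tus,
    features: FeatureMatrix | None,
    kappa: np.ndarray,
    chi: np.ndarray,
    lam: float = 1.0,
    nu: float = 0.0,
) -> float:
    """Joint log likelihood (constants dropped) at given kappa and chi.

    Masked sites are excluded from all sums.  ``chi`` must be positive.
    """
    design = _as_design(tus, features)
    kappa = np.asarray(kappa, dtype=float)
    chi = np.broadcast_to(np.asarray(chi, dtype=float), (design.M,))
    if np.any(chi <= 0):
        raise ValueError("chi must be positive for all genes")
    w = design.site_weights(kappa)
    U = design.U(w)
    value = (
        float(design.s @ np.log(chi))
        - float(kappa @ design.T_sum)
        - lam * float(chi @ U)
        + design.bias_const
    )
    if nu:
        value -= nu * float(np.abs(kappa).sum())
    return value


def gradient_kappa(
    tus,
    features: FeatureMatrix | None,
    kappa: np.ndarray,
    chi: np.ndarray,
    nu: float = 0.0,
    lam: float = 1.0,
) -> np.ndarray:
    """Gradient of the (optionally L1-penalized) log likelihood in kappa.

    Component n is ``sum_j [lam * chi_j * V_jn - T_jn] - nu * sgn(kappa_n)``
    with ``sgn(0) = 0``.
    """
    design = _as_design(tus, features)
    kappa = np.asarray(kappa, dtype=float)
    chi = np.broadcast_to(np.asarray(chi, dtype=float), (design.M,))
    w = design.site_weights(kappa)
    c = lam * np.repeat(chi, np.diff(design.bounds)) * w
    grad = design.weighted_feature_sum(c) - design.T_sum
    if nu:
        grad = grad - nu * np.sign(kappa)
    return grad


def update_chi(s_j, lam: float, U_j):
    """Analytic conditional optimum ``chi_j = s_j / (lam * U_j)``.

    Genes with ``s_j = 0`` get ``chi_j = 0`` (degenerate; excluded from
    fitting).  ``U_j <= 0`` is an error.
    """
    s = np.asarray(s_j, dtype=float)
    U = np.asarray(U_j, dtype=float)
    if np.any(s < 0):
        raise ValueError("s_j must be non-negative")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if np.any(U <= 0):
        raise ValueError("U_j must be positive")
    out = s / (lam * U)
    return float(out) if np.isscalar(s_j) else out


def sufficient_stats_sparse(
    raw_blocks, means: np.ndarray, sds: np.ndarray, kappa: np.ndarray
):
    """Per-gene ``U_j`` and ``V_j`` from raw sparse features plus stats.

    Equivalent (to ~1e-10) to computing ``sum_i exp(-kappa . Y_i)`` and
    ``sum_i exp(-kappa . Y_i) Y_i`` on the dense standardized matrix, but
    with cost proportional to the nonzero raw entries: the exponent uses
    ``kappa . Y_i = (kappa/sd) . Yraw_i - kappa . (mean/sd)`` and V is
    recovered as ``(Vraw_j - mean * U_j) / sd``.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1:
        raise ValueError("means and sds must be matching 1-D arrays")
    kappa = np.asarray(kappa, dtype=float)
    a = kappa / sds
    const = float(kappa @ (means / sds))
    U = np.empty(len(raw_blocks))
    V = np.empty((len(raw_blocks), means.size))
    for j, block in enumerate(raw_blocks):
        eta = np.asarray(block @ a).ravel() - const
        w = np.exp(-eta)
        U[j] = w.sum()
        vraw = np.asarray(block.T @ w).ravel()
        V[j] = (vraw - means * U[j]) / sds
    return U, V


def _l1_step(kappa, grad, nu, lr):
    """One L1 subgradient step with exact zeros.

    Coefficients at 0 move only if the data gradient beats the penalty
    (sgn(0) = 0 at the kink); moving coefficients that cross 0 are clipped
    to exactly 0.
    """
    step = np.where(
        kappa != 0,
        grad - nu * np.sign(kappa),
        np.where(np.abs(grad) > nu, grad - nu * np.sign(grad), 0.0),
    )
    new = kappa + lr * step
    crossed = (kappa != 0) & (np.sign(new) != np.sign(kappa))
    new[crossed] = 0.0
    return new


def fit(
    tus,
    features: FeatureMatrix | None = None,
    config: FitConfig | None = None,
    kappa0: np.ndarray | None = None,
    offsets: list[np.ndarray] | None = None,
) -> GLMFit:
    """Fit the GLM by gradient ascent with analytic per-gene chi updates.

    ``features`` should be standardized.  ``offsets`` optionally carries a
    per-TU, per-site log-rho track for the 3'-nucleotide sequence-bias
    variant; with uniform base composition (rho = 1) the fit is identical
    to the unbiased model.
    """
    cfg = config or FitConfig()
    design = _as_design(tus, features, offsets=offsets, lam=cfg.lam)
    F = design.n_features
    kappa = np.zeros(F) if kappa0 is None else np.asarray(kappa0, dtype=float).copy()

    lr = cfg.learning_rate
    obj, U, chi, w = _profile_objective(design, kappa)
    if not np.isfinite(obj):
        raise ValueError("non-finite objective at the initial kappa")
    obj_pen = obj - _penalty_value(kappa, cfg)
    trace = [obj_pen]
    converged = False
    n_bad = 0
    it = 0
    while it < cfg.max_iter:
        it += 1
        c = design.lam * np.repeat(chi, np.diff(design.bounds)) * w
        grad = design.weighted_feature_sum(c) - design.T_sum
        if cfg.penalty == "l2":
            grad = grad - 2 * cfg.nu * kappa
        elif cfg.penalty == "elasticnet":
            grad = grad - 2 * cfg.nu * (1 - cfg.l1_ratio) * kappa

        if cfg.penalty == "l1":
            new_kappa = _l1_step(kappa, grad, cfg.nu, lr)
        elif cfg.penalty == "elasticnet":
            new_kappa = _l1_step(kappa, grad, cfg.nu * cfg.l1_ratio, lr)
        else:
            new_kappa = kappa + lr * grad

        new_obj, new_U, new_chi, new_w = _profile_objective(design, new_kappa)
        new_pen = (
            new_obj - _penalty_value(new_kappa, cfg)
            if np.isfinite(new_obj)
            else -np.inf
        )

        if not np.isfinite(new_pen) and not cfg.adapt_lr:
            raise RuntimeError(
                "objective diverged; use a smaller learning rate"
            )
        if new_pen < obj_pen - 1e-9:
            if cfg.adapt_lr:
                lr /= 2.0
                trace.append(obj_pen)
                if lr < 1e-300:
                    break
                continue
            n_bad += 1
            if n_bad >= 10:
                raise RuntimeError(
                    "objective decreased for 10 consecutive iterations; "
                    "use a smaller learning rate"
                )
        else:
            n_bad = 0
            if cfg.adapt_lr:
                lr *= cfg.lr_growth

        delta = np.max(np.abs(new_kappa - kappa)) if F else 0.0
        kappa, obj_pen, U, chi, w = new_kappa, new_pen, new_U, new_chi, new_w
        trace.append(obj_pen)
        if delta < cfg.tol:
            converged = True
            break

    return GLMFit(
        feature_names=list(design.names),
        kappa=kappa,
        chi=chi,
        tu_ids=list(design.tu_ids),
        lam=design.lam,
        nu=cfg.nu if cfg.penalty != "none" else 0.0,
        penalty=cfg.penalty,
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        zero_threshold=cfg.zero_threshold,
        diagnostics={"final_lr": lr},
    )


def _heldout_loglik(design: _Design, kappa: np.ndarray) -> float:
    """Unpenalized log likelihood on a gene set with chi re-optimized."""
    obj, _, _, _ = _profile_objective(design, kappa)
    return obj


def default_nu_grid(tus, n_points: int = 6) -> list[float]:
    """Log-spaced L1 strengths scaled to the data.

    Under the null, per-feature score components fluctuate with sd of
    order ``sqrt(total reads)`` (standardized features have unit second
    moment), so useful penalties bracket that scale.  The grid spans
    ``[0.25, 8] * sqrt(sum_j s_j)``.
    """
    total = float(sum(tu.counts[tu.mask].sum() for tu in tus))
    if total <= 0:
        raise ValueError("no reads in the gene set")
    scale = np.sqrt(total)
    return list(scale * np.geomspace(0.25, 8.0, n_points))


def select_nu(
    tus,
    features: FeatureMatrix,
    nu_grid,
    config: FitConfig | None = None,
    seed: int = 0,
    train_frac: float = 0.8,
    offsets: list[np.ndarray] | None = None,
) -> tuple[float, GLMFit]:
    """Choose the L1 strength by AIC on held-out genes.

    Genes are split once (seeded) into train/test.  For each ``nu`` in the
    grid (visited from strongest to weakest, warm-starting each fit from
    the previous solution) the model is fitted on the training genes and
    scored on the test genes by ``AIC = 2 k - 2 l_test`` where ``k`` counts
    coefficients above the zero threshold and ``l_test`` re-optimizes the
    held-out genes' chi analytically.  Returns the winning ``nu`` and its
    training fit.
    """
    nu_grid = sorted({float(v) for v in nu_grid}, reverse=True)
    if not nu_grid:
        raise ValueError("empty nu grid")
    tus = list(tus)
    if len(tus) < 5:
        raise ValueError("need at least 5 genes for the train/test split")
    cfg = config or FitConfig(penalty="l1")
    if cfg.penalty not in ("l1", "elasticnet"):
        cfg = replace(cfg, penalty="l1")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tus))
    n_train = max(1, int(round(train_frac * len(tus))))
    tr, te = order[:n_train], order[n_train:]
    fm_tr = features.subset_tus(tr)
    fm_te = features.subset_tus(te)
    des_tr = _Design(
        [tus[i] for i in tr],
        fm_tr,
        offsets=None if offsets is None else [offsets[i] for i in tr],
    )
    des_te = _Design(
        [tus[i] for i in te],
        fm_te,
        offsets=None if offsets is None else [offsets[i] for i in te],
    )

    best = None
    kappa_warm = None
    curve = []
    for nu in nu_grid:
        cfg_nu = replace(cfg, nu=nu)
        f = fit(des_tr, config=cfg_nu, kappa0=kappa_warm)
        kappa_warm = f.kappa
        k_hat = f.nonzero_count()
        ll_test = _heldout_loglik(des_te, f.kappa)
        aic = 2.0 * k_hat - 2.0 * ll_test
        curve.append((nu, aic, k_hat))
        if best is None or aic < best[1]:
            best = (nu, aic, f)
    nu_best, _, fit_best = best
    fit_best.diagnostics["aic_curve"] = curve
    fit_best.diagnostics["train_tus"] = [tus[i].id for i in tr]
    fit_best.diagnostics["test_tus"] = [tus[i].id for i in te]
    return nu_best, fit_best


def fit_batches(
    tus,
    features: FeatureMatrix,
    config: FitConfig | None = None,
    n_batches: int = 10,
    batch_size: int | None = None,
    seed: int = 0,
    offsets: list[np.ndarray] | None = None,
) -> GLMFit:
    """Fit on random gene subsets; report mean kappa and across-batch SE.

    With a single batch the SE is undefined and reported as missing.
    """
    tus = list(tus)
    if batch_size is None:
        batch_size = len(tus)
    if batch_size > len(tus):
        raise ValueError("batch size exceeds number of genes")
    rng = np.random.default_rng(seed)
    kappas = []
    for _ in range(n_batches):
        idx = rng.choice(len(tus), size=batch_size, replace=False)
        f = fit(
            [tus[i] for i in idx],
            features.subset_tus(idx),
            config=config,
            offsets=None if offsets is None else [offsets[i] for i in idx],
        )
        kappas.append(f.kappa)
    kappas = np.vstack(kappas)
    kappa_mean = kappas.mean(axis=0)
    se = kappas.std(axis=0, ddof=1) if n_batches > 1 else None

    design = _as_design(tus, features, offsets=offsets)
    _, U, chi, _ = _profile_objective(design, kappa_mean)
    cfg = config or FitConfig()
    return GLMFit(
        feature_names=list(features.names),
        kappa=kappa_mean,
        chi=chi,
        tu_ids=list(design.tu_ids),
        lam=design.lam,
        nu=cfg.nu,
        penalty=cfg.penalty,
        objective_trace=np.empty(0),
        n_iter=0,
        converged=True,
        se=se,
        zero_threshold=cfg.zero_threshold,
        diagnostics={"n_batches": n_batches, "batch_size": batch_size},
    )


def predict_zeta(kappa: np.ndarray, features: FeatureMatrix) -> list[np.ndarray]:
    """Per-nucleotide zeta = exp(kappa . Y) for every TU in the matrix."""
    kappa = np.asarray(kappa, dtype=float)
    out = []
    for t in range(features.n_tus):
        if features.is_sparse and features.standardized:
            a = kappa / features.sds
            eta = np.asarray(features.raw[t] @ a).ravel() - float(
                kappa @ (features.means / features.sds)
            )
        else:
            eta = features.values(t) @ kappa
        out.append(np.exp(eta))
    return out


def expected_counts(fit_result: GLMFit, features: FeatureMatrix) -> list[np.ndarray]:
    """Predicted mean read counts ``lam * chi_j / zeta_ij`` per TU.

    TU order must match the fit's ``tu_ids``.
    """
    zetas = predict_zeta(fit_result.kappa, features)
    if len(zetas) != len(fit_result.chi):
        raise ValueError("feature matrix does not match fitted TUs")
    return [
        fit_result.lam * chi / z for chi, z in zip(fit_result.chi, zetas)
    ]


def estimate_rho(tus, sequences: list[str]) -> SeqBias:
    """Bulk 3'-nucleotide frequencies, weighted by read counts.

    ``sequences`` are transcription-strand TU sequences.  Only analyzed
    (unmasked) sites contribute.
    """
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    totals = np.zeros(4)
    for tu, seq in zip(tus, sequences):
        if len(seq) != tu.length:
            raise ValueError(f"TU {tu.id}: sequence length mismatch")
        for i in np.flatnonzero(tu.mask & (tu.counts > 0)):
            b = seq[i]
            if b in code:
                totals[code[b]] += tu.counts[i]
    if totals.sum() <= 0:
        raise ValueError("no reads at A/C/G/T sites")
    return SeqBias(pi=totals / totals.sum())


def log_likelihood_biased(
    tus,
    features: FeatureMatrix,
    kappa: np.ndarray,
    chi: np.ndarray,
    seqbias: SeqBias,
    sequences: list[str],
    lam: float = 1.0,
) -> float:
    """Log likelihood of the 3'-nucleotide bias variant.

    Adds ``sum_i X_i log rho_i`` and replaces ``U_j`` with
    ``U'_j = sum_i rho_i exp(-kappa . Y_ij)``; equivalently each exponent
    gains a per-site offset ``-log rho_i``.  With uniform base frequencies
    (rho = 1 everywhere) this equals the unbiased log likelihood exactly.
    """
    offsets = [seqbias.log_rho_track(seq) for seq in sequences]
    design = _Design(list(tus), features, offsets=offsets)
    return log_likelihood(design, None, kappa, chi, lam=lam)
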