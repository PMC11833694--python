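"""SimPol: stochastic per-cell polymerase simulation and synthetic benchmarks.

The simulator tracks individual RNA polymerases on a DNA template in a
population of independent cells.  A polymerase at site *i* advances one
nucleotide at rate ``zeta_bar * zeta_i`` (events/min) unless the next
position is occupied by the polymerase ahead; new polymerases initiate at
the first site at rate ``alpha`` when it is free; polymerases leave at the
template end.  Occupancy is the time-and-cell-averaged presence of an
active site per position, which at steady state in the rare-collision
regime equals ``alpha / (zeta_bar * zeta_i)`` — the 1/zeta law the GLM
inverts.

Two exact-equivalent integrators are provided: the discrete time-slice
scheme (one Bernoulli move attempt per slice of ``time_slice`` minutes)
and an event-driven scheme that samples exponential waiting times per
site, exploiting the fact that polymerases cannot pass one another so each
one's trajectory depends only on the one ahead.

Synthetic read counts are Poisson samples proportional to occupancy with a
target mean depth.  The module also houses the two benchmark generators:
an epigenomic benchmark (six correlated block-sampled covariates,
``zeta = exp(kappa . Y) + noise``) and a 5-mer sequence benchmark (100
random 5-mers with nonzero coefficients on random sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from elongrate.core_io import TranscriptionUnit
from elongrate.features import FeatureMatrix, FilterSpec, KmerSpec, apply_filter, kmer_indicators, standardize

__all__ = [
    "SimPolConfig",
    "SimResult",
    "simulate_occupancy",
    "sample_reads",
    "sample_covariates",
    "make_block_library",
    "make_zeta",
    "SyntheticDataset",
    "EpigenomicBenchmarkConfig",
    "KmerBenchmarkConfig",
    "generate_epigenomic_benchmark",
    "generate_kmer_benchmark",
    "DEFAULT_EPIGENOMIC_KAPPA",
]


@dataclass
class SimPolConfig:
    """Simulator settings.

    ``zeta_bar`` is the absolute per-site stepping rate in moves/min
    (default 2000, i.e. the ~2 kb/min mammalian average); ``zeta`` is the
    dimensionless per-site multiplier.  ``alpha`` is the initiation rate in
    events/min.  The discrete scheme uses slices of ``time_slice`` minutes
    with at most one movement per slice, so ``zeta_bar * max(zeta) *
    time_slice`` must not exceed 1.
    """

    n_cells: int
    gene_length: int
    alpha: float
    zeta: np.ndarray | None = None
    zeta_bar: float = 2000.0
    time_slice: float = 1e-4
    total_time: float = 20.0
    footprint: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zeta is None:
            self.zeta = np.ones(self.gene_length)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.zeta.shape != (self.gene_length,):
            raise ValueError("zeta length must equal gene_length")
        if np.any(self.zeta < 0) or self.alpha < 0 or self.zeta_bar < 0:
            raise ValueError("rates must be non-negative")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        pmax = self.zeta_bar * float(self.zeta.max(initial=0.0)) * self.time_slice
        if pmax > 1.0:
            raise ValueError(
                f"per-slice move probability {pmax:.3f} exceeds 1; "
                "reduce time_slice or rates"
            )
        if self.alpha * self.time_slice > 1.0:
            raise ValueError("per-slice initiation probability exceeds 1")

    @property
    def rates(self) -> np.ndarray:
        """Absolute per-site stepping rates (moves/min)."""
        return self.zeta_bar * self.zeta


@dataclass
class SimResult:
    """Simulation output: occupancy density and (optionally) read counts."""

    occupancy: np.ndarray
    counts: np.ndarray | None = None
    true_zeta: np.ndarray | None = None
    true_kappa: np.ndarray | None = None
    covariates: np.ndarray | None = None


@njit(cache=True)
def _slice_kernel(p_move, p_init, n_slices, eq_start, n_cells, footprint, seed):
    np.random.seed(seed)
    n = p_move.size
    occ = np.zeros(n)
    pos = np.empty(n, dtype=np.int64)  # active polymerases, front first
    for _cell in range(n_cells):
        npol = 0
        for s in range(n_slices):
            k = 0
            while k < npol:
                i = pos[k]
                if i == n - 1:
                    if np.random.random() < p_move[i]:
                        for m in range(k, npol - 1):
                            pos[m] = pos[m + 1]
                        npol -= 1
                        continue
                else:
                    blocked = k > 0 and (pos[k - 1] - i) <= footprint
                    if not blocked and np.random.random() < p_move[i]:
                        pos[k] = i + 1
                k += 1
            if np.random.random() < p_init:
                if npol == 0 or pos[npol - 1] >= footprint:
                    pos[npol] = 0
                    npol += 1
            if s >= eq_start:
                for k2 in range(npol):
                    occ[pos[k2]] += 1.0
    return occ / (n_cells * (n_slices - eq_start))


@njit(cache=True)
def _event_kernel(rates, alpha, total_time, t_eq, n_cells, footprint, seed):
    np.random.seed(seed)
    n = rates.size
    occ = np.zeros(n)
    dep_prev = np.empty(n)
    dep_cur = np.empty(n)
    window = total_time - t_eq
    for _cell in range(n_cells):
        for i in range(n):
            dep_prev[i] = -1e30
        t0 = np.random.exponential(1.0 / alpha)
        while t0 < total_time:
            # initiation succeeds only if the first footprint sites are free
            if t0 >= dep_prev[footprint - 1]:
                a = t0
                for i in range(n):
                    bi = i + footprint
                    block = dep_prev[bi] if bi < n else -1e30
                    start = a if a > block else block
                    # memoryless: residual wait after unblocking is fresh
                    d = start + np.random.exponential(1.0 / rates[i])
                    lo = a if a > t_eq else t_eq
                    hi = d if d < total_time else total_time
                    if hi > lo:
                        occ[i] += hi - lo
                    dep_cur[i] = d
                    a = d
                tmp = dep_prev
                dep_prev = dep_cur
                dep_cur = tmp
            t0 += np.random.exponential(1.0 / alpha)
    return occ / (n_cells * window)


def simulate_occupancy(
    config: SimPolConfig, method: str = "slices", equilibration: str = "half"
) -> SimResult:
    """Run the polymerase simulation and return the occupancy density.

    ``method`` selects the discrete time-slice integrator (``"slices"``)
    or the statistically equivalent event-driven one (``"event"``).
    Occupancy is averaged over the second half of the simulated time
    (``equilibration="half"``); ``"end"`` instead snapshots the final state
    (slice method only).
    """
    if config.alpha == 0:
        return SimResult(occupancy=np.zeros(config.gene_length))
    rates = config.rates
    if np.any(rates <= 0):
        raise ValueError("all per-site rates must be positive to simulate")
    seed = int(config.seed) % (2**31 - 1)
    if method == "event":
        if equilibration != "half":
            raise ValueError("event-driven method supports equilibration='half'")
        occ = _event_kernel(
            rates,
            float(config.alpha),
            float(config.total_time),
            float(config.total_time) / 2.0,
            int(config.n_cells),
            int(config.footprint),
            seed,
        )
    elif method == "slices":
        n_slices = int(round(config.total_time / config.time_slice))
        eq_start = n_slices - 1 if equilibration == "end" else n_slices // 2
        occ = _slice_kernel(
            rates * config.time_slice,
            float(config.alpha * config.time_slice),
            n_slices,
            eq_start,
            int(config.n_cells),
            int(config.footprint),
            seed,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return SimResult(occupancy=occ, true_zeta=config.zeta.copy())


def sample_reads(
    occupancy: np.ndarray, target_depth: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Poisson read counts with mean proportional to occupancy.

    The proportionality constant is chosen so the mean expected count per
    site equals ``target_depth``.
    """
    occ = np.asarray(occupancy, dtype=float)
    if np.any(occ < 0):
        raise ValueError("occupancy must be non-negative")
    if target_depth < 0:
        raise ValueError("target depth must be non-negative")
    if target_depth == 0:
        return np.zeros(occ.size, dtype=np.int64)
    mean_occ = occ.mean()
    if mean_occ <= 0:
        raise ValueError("cannot scale all-zero occupancy to a positive depth")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.poisson(occ * (target_depth / mean_occ))


# ---------------------------------------------------------------------------
# synthetic covariates


#: Feature names with (annotation width nt, block-level frequency, filter)
_LIBRARY_FEATURES: list[tuple[str, int, float, FilterSpec]] = [
    ("CTCF", 20, 0.10, FilterSpec("gaussian", r=400, sigma=100.0)),
    ("H3K36me3", 1000, 0.40, FilterSpec("gaussian", r=400, sigma=100.0)),
    ("H3K9me1", 1000, 0.30, FilterSpec("gaussian", r=400, sigma=100.0)),
    ("H4K20me1", 1000, 0.30, FilterSpec("gaussian", r=400, sigma=100.0)),
    ("H3K79me2", 1000, 0.25, FilterSpec("gaussian", r=400, sigma=100.0)),
    ("stemloop", 30, 0.15, FilterSpec("gaussian", r=500, sigma=200.0)),
]

#: Latent-factor correlations between block-level feature presences:
#: histone marks mutually correlated, CTCF and stem-loops weakly coupled.
_LIBRARY_CORR = np.array(
    [
        # CTCF  K36me3 K9me1 K20me1 K79me2 stem
        [1.00, 0.10, 0.10, 0.10, 0.10, 0.05],
        [0.10, 1.00, 0.60, 0.60, 0.30, 0.10],
        [0.10, 0.60, 1.00, 0.50, 0.30, 0.10],
        [0.10, 0.60, 0.50, 1.00, 0.30, 0.10],
        [0.10, 0.30, 0.30, 0.30, 1.00, 0.10],
        [0.05, 0.10, 0.10, 0.10, 0.10, 1.00],
    ]
)

#: Coefficients reported for the corresponding six K562 features, used as
#: the ground truth of the epigenomic benchmark.
DEFAULT_EPIGENOMIC_KAPPA = np.array(
    [-0.022, -0.095, -0.067, -0.041, 0.030, -0.051]
)


def make_block_library(
    n_blocks: int = 200,
    block_size: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], np.ndarray]:
    """Built-in synthetic 1-kb covariate block library.

    Emulates block-sampling of real epigenomic tracks: a shared latent
    Gaussian field is thresholded per feature to match target block-level
    frequencies (preserving a positive correlation structure among histone
    marks), present features are painted as annotation-width indicator runs
    at random positions, and each profile is smoothed with the feature's
    standard filter.  Returns feature names and an array of shape
    ``(n_blocks, block_size, n_features)``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    names = [f[0] for f in _LIBRARY_FEATURES]
    nf = len(names)
    chol = np.linalg.cholesky(_LIBRARY_CORR)
    z = rng.standard_normal((n_blocks, nf)) @ chol.T
    from scipy.stats import norm

    thresholds = norm.ppf(1.0 - np.array([f[2] for f in _LIBRARY_FEATURES]))
    present = z > thresholds

    library = np.zeros((n_blocks, block_size, nf))
    for b in range(n_blocks):
        for f, (name, width, _freq, filt) in enumerate(_LIBRARY_FEATURES):
            if not present[b, f]:
                continue
            w = min(width, block_size)
            start = int(rng.integers(0, block_size - w + 1))
            raw = np.zeros(block_size)
            raw[start : start + w] = 1.0
            library[b, :, f] = apply_filter(raw, filt)
    return names, library


def sample_covariates(
    block_library: np.ndarray,
    n_sites: int,
    block_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Tile randomly chosen library blocks (jointly across features).

    Sampling whole blocks preserves the library's cross-feature correlation
    structure.  Returns an ``(n_sites, n_features)`` array.
    """
    lib = np.asarray(block_library)
    if lib.ndim != 3 or lib.shape[0] == 0:
        raise ValueError("block library must be a non-empty (blocks, size, features) array")
    bs = lib.shape[1] if block_size is None else block_size
    if bs != lib.shape[1]:
        raise ValueError("block_size does not match library")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_blocks_needed = -(-n_sites // bs)
    idx = rng.integers(0, lib.shape[0], size=n_blocks_needed)
    tiled = lib[idx].reshape(n_blocks_needed * bs, lib.shape[2])
    return tiled[:n_sites].copy()


def make_zeta(
    kappa: np.ndarray,
    covariates: np.ndarray,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
    floor: float = 1e-3,
) -> np.ndarray:
    """Local rates ``zeta_i = exp(kappa . Y_i) + delta_i``.

    ``delta_i ~ N(0, noise_sd^2)``; the result is floored at a small
    positive value since additive noise can push the rate non-positive.
    ``noise_sd=0`` gives the exact GLM surface.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    zeta = np.exp(np.asarray(covariates) @ np.asarray(kappa, dtype=float))
    if noise_sd > 0:
        zeta = zeta + rng.normal(0.0, noise_sd, size=zeta.shape)
    return np.maximum(zeta, floor)


# ---------------------------------------------------------------------------
# benchmark generators


@dataclass
class SyntheticDataset:
    """One benchmark replicate: TUs with counts, features, and the truth."""

    tus: list[TranscriptionUnit]
    features: FeatureMatrix
    zeta_true: list[np.ndarray]
    kappa_true: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    alpha: np.ndarray
    sequences: list[str] | None = None
    true_feature_names: list[str] | None = None


@dataclass
class EpigenomicBenchmarkConfig:
    n_replicates: int = 10
    n_tus: int = 100
    tu_length: int = 10_000
    n_cells: int = 5000
    noise_sd: float = 0.1
    target_depth: float = 0.5
    alpha_median: float = 1.0
    alpha_log_sd: float = 0.8
    zeta_bar: float = 2000.0
    total_time: float = 20.0
    footprint: int = 1
    test_frac: float = 0.2
    n_library_blocks: int = 200
    simulator: str = "event"
    seed: int = 0
    kappa_true: np.ndarray = field(
        default_factory=lambda: DEFAULT_EPIGENOMIC_KAPPA.copy()
    )


@dataclass
class KmerBenchmarkConfig:
    n_replicates: int = 1
    n_tus: int = 200
    tu_length: int = 10_000
    n_cells: int = 5000
    target_depth: float = 0.5
    n_true_kmers: int = 100
    coef_low: float = -0.3
    coef_high: float = 0.3
    k: int = 5
    alpha_median: float = 1.0
    alpha_log_sd: float = 0.8
    zeta_bar: float = 2000.0
    total_time: float = 20.0
    footprint: int = 1
    test_frac: float = 0.2
    simulator: str = "event"
    seed: int = 0


def _sample_alpha(rng, n, median, log_sd):
    """Long-tailed per-gene initiation rates (log-normal, given median)."""
    return median * np.exp(log_sd * rng.standard_normal(n))


def _split(n: int, test_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    order = rng.permutation(n)
    n_test = max(1, int(round(test_frac * n)))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


def _simulate_tu_counts(zeta, alpha, cfg, rng, simulator):
    sim_cfg = SimPolConfig(
        n_cells=cfg.n_cells,
        gene_length=zeta.size,
        alpha=float(alpha),
        zeta=zeta,
        zeta_bar=cfg.zeta_bar,
        total_time=cfg.total_time,
        footprint=cfg.footprint,
        seed=int(rng.integers(2**31 - 1)),
    )
    occ = simulate_occupancy(sim_cfg, method=simulator).occupancy
    return sample_reads(occ, cfg.target_depth, rng)


def generate_epigenomic_benchmark(
    config: EpigenomicBenchmarkConfig | None = None,
) -> list[SyntheticDataset]:
    """Replicated epigenomic benchmark datasets.

    Per replicate: six correlated covariates are block-sampled along each
    TU and standardized across the replicate; true local rates are
    ``exp(kappa . Y) + N(0, noise_sd^2)``; per-TU initiation rates are
    log-normal with the configured median; occupancy is simulated and
    Poisson reads are sampled at the target depth.  TUs are split 80/20
    into train/test.
    """
    cfg = config or EpigenomicBenchmarkConfig()
    datasets = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng([cfg.seed, rep])
        names, library = make_block_library(
            n_blocks=cfg.n_library_blocks, seed=rng
        )
        raw_blocks = [
            sample_covariates(library, cfg.tu_length, seed=rng)
            for _ in range(cfg.n_tus)
        ]
        fm = standardize(
            FeatureMatrix(
                names=names,
                raw=raw_blocks,
                tu_ids=[f"rep{rep}_tu{t}" for t in range(cfg.n_tus)],
            )
        )
        # features absent from every sampled block are dropped at
        # standardization (tiny configs only); keep kappa aligned
        kappa_true = np.asarray(cfg.kappa_true, dtype=float)[
            [names.index(n) for n in fm.names]
        ]
        alpha = _sample_alpha(rng, cfg.n_tus, cfg.alpha_median, cfg.alpha_log_sd)
        zetas, tus = [], []
        for t in range(cfg.n_tus):
            zeta = make_zeta(
                kappa_true, fm.values(t), noise_sd=cfg.noise_sd, seed=rng
            )
            counts = _simulate_tu_counts(zeta, alpha[t], cfg, rng, cfg.simulator)
            zetas.append(zeta)
            tus.append(
                TranscriptionUnit(
                    id=fm.tu_ids[t],
                    chrom=f"synth_rep{rep}",
                    strand="+",
                    body_start=t * cfg.tu_length,
                    body_end=(t + 1) * cfg.tu_length,
                    counts=counts,
                )
            )
        train_idx, test_idx = _split(cfg.n_tus, cfg.test_frac, rng)
        datasets.append(
            SyntheticDataset(
                tus=tus,
                features=fm,
                zeta_true=zetas,
                kappa_true=kappa_true,
                train_idx=train_idx,
                test_idx=test_idx,
                alpha=alpha,
                true_feature_names=list(fm.names),
            )
        )
    return datasets


def _random_sequence(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_kmer_benchmark(
    config: KmerBenchmarkConfig | None = None,
) -> list[SyntheticDataset]:
    """Replicated 5-mer benchmark datasets.

    Random uniform sequences; ``n_true_kmers`` randomly chosen 5-mers get
    coefficients uniform in ``[coef_low, coef_high]`` applied to the raw
    0/1 indicators (all other 5-mers 0), so the true local rate at a site
    is ``exp(kappa)`` of the 5-mer centered there; no Gaussian noise.
    """
    cfg = config or KmerBenchmarkConfig()
    spec = KmerSpec.all_kmers(kmax=cfg.k, kmin=cfg.k)
    n_kmers = len(spec.kmers)
    datasets = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng([cfg.seed + 1_000_000, rep])
        true_idx = np.sort(rng.choice(n_kmers, size=cfg.n_true_kmers, replace=False))
        kappa_raw = np.zeros(n_kmers)
        kappa_raw[true_idx] = rng.uniform(
            cfg.coef_low, cfg.coef_high, size=cfg.n_true_kmers
        )
        alpha = _sample_alpha(rng, cfg.n_tus, cfg.alpha_median, cfg.alpha_log_sd)
        seqs, raw_blocks, zetas, tus = [], [], [], []
        for t in range(cfg.n_tus):
            seq = _random_sequence(rng, cfg.tu_length)
            _, mat = kmer_indicators(seq, spec)
            zeta = np.exp(np.asarray(mat @ kappa_raw).ravel())
            counts = _simulate_tu_counts(zeta, alpha[t], cfg, rng, cfg.simulator)
            seqs.append(seq)
            raw_blocks.append(mat)
            zetas.append(zeta)
            tus.append(
                TranscriptionUnit(
                    id=f"kmer_rep{rep}_tu{t}",
                    chrom=f"synthk_rep{rep}",
                    strand="+",
                    body_start=t * cfg.tu_length,
                    body_end=(t + 1) * cfg.tu_length,
                    counts=counts,
                )
            )
        fm = standardize(
            FeatureMatrix(
                names=list(spec.kmers),
                raw=raw_blocks,
                tu_ids=[tu.id for tu in tus],
            )
        )
        # 5-mers absent from every sequence are dropped at standardization
        # (tiny configs only); keep the truth vector aligned with fm.names
        col = {k: i for i, k in enumerate(spec.kmers)}
        kappa_kept = kappa_raw[[col[n] for n in fm.names]]
        train_idx, test_idx = _split(cfg.n_tus, cfg.test_frac, rng)
        datasets.append(
            SyntheticDataset(
                tus=tus,
                features=fm,
                zeta_true=zetas,
                kappa_true=kappa_kept,
                train_idx=train_idx,
                test_idx=test_idx,
                alpha=alpha,
                sequences=seqs,
                true_feature_names=[spec.kmers[i] for i in true_idx],
            )
        )
    return datasets
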