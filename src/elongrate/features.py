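"""Covariate construction: k-mer indicators, smoothing filters, standardization.

The GLM requires one covariate vector per nucleotide.  Narrowly annotated
features (splice sites, CTCF motifs) influence polymerase movement over a
broader region than their annotation, so a smoothing filter can spread an
indicator track over adjacent positions before regression.  All features are
then standardized to mean 0 / sd 1 over the analyzed sites so coefficients
are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "FilterSpec",
    "KmerSpec",
    "FeatureMatrix",
    "kmer_indicators",
    "apply_filter",
    "estimate_generalized_filter",
    "standardize",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class FilterSpec:
    """Smoothing-filter definition.

    ``kind`` is ``"gaussian"`` (weight ``(1/sigma) exp(-0.5 (k/sigma)^2)`` for
    lag ``k`` in ``[-r, r]``) or ``"generalized"`` (an explicit non-negative
    weight per lag, ``weights[k + r]``).  ``delta`` shifts the window by a
    fixed offset in nucleotides.
    """

    kind: str
    r: int
    sigma: float | None = None
    delta: int = 0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "generalized"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.r <= 0:
            raise ValueError("filter radius r must be positive")
        if self.kind == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian filter requires sigma > 0")
        else:
            if self.weights is None:
                raise ValueError("generalized filter requires weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (2 * self.r + 1,):
                raise ValueError(
                    f"generalized filter needs 2r+1 = {2 * self.r + 1} weights"
                )
            if np.any(self.weights < 0):
                raise ValueError("generalized filter weights must be non-negative")
            if not np.any(self.weights > 0):
                raise ValueError("all-zero generalized filter weights")

    def kernel(self) -> np.ndarray:
        """Unnormalized weights F(k) for k = -r..r."""
        if self.kind == "gaussian":
            k = np.arange(-self.r, self.r + 1)
            return np.exp(-0.5 * (k / self.sigma) ** 2) / self.sigma
        return self.weights

    @property
    def normalizer(self) -> float:
        z = float(self.kernel().sum())
        if z <= 0:
            raise ValueError("filter normalizer must be positive")
        return z


# Defaults used in the analyses: ChIP-seq-scale features (histone marks,
# CTCF) and the broader RNA stem-loop annotation.
CHIP_FILTER = FilterSpec(kind="gaussian", r=400, sigma=100.0)
STEMLOOP_FILTER = FilterSpec(kind="gaussian", r=500, sigma=200.0)


@dataclass
class KmerSpec:
    """A set of k-mer indicator features with an alignment shift.

    ``shift = 0`` centers each k-mer on the polymerase active site: for odd
    k the middle base (1-based position ``(k+1)/2``) is aligned with the
    site, for even k position ``k/2``, so the active site falls slightly
    left of center.  Negative shifts move the k-mer window upstream (the
    indicator pattern moves downstream in index space).
    """

    kmers: list[str]
    shift: int = 0

    def __post_init__(self) -> None:
        cleaned = []
        for kmer in self.kmers:
            kmer = kmer.upper()
            if not kmer or set(kmer) - set("ACGT"):
                raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
            cleaned.append(kmer)
        self.kmers = cleaned
        if not -25 <= self.shift <= 25:
            raise ValueError("shift must lie in [-25, 25]")

    @classmethod
    def all_kmers(cls, kmax: int = 5, kmin: int = 1, shift: int = 0) -> "KmerSpec":
        """All k-mers for k in [kmin, kmax] (1364 features for k <= 5)."""
        from itertools import product

        kmers = [
            "".join(p)
            for k in range(kmin, kmax + 1)
            for p in product("ACGT", repeat=k)
        ]
        return cls(kmers=kmers, shift=shift)


def _active_site_pos(k: int) -> int:
    """1-based position within a k-mer aligned with the active site."""
    return (k + 1) // 2 if k % 2 else k // 2


def _encode(seq: str) -> np.ndarray:
    enc = np.full(len(seq), 4, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        enc[arr == ord(base)] = code
    return enc


def kmer_indicators(seq: str, spec: KmerSpec) -> tuple[list[str], sp.csr_matrix]:
    """Indicator features for each k-mer of ``spec`` along a TU sequence.

    Returns feature names and a sparse (n_sites x n_kmers) 0/1 matrix in the
    order of ``spec.kmers``.  The indicator at site ``i`` is 1 iff the k-mer
    matches the window whose active-site position aligns with ``i + shift``;
    windows overrunning the sequence ends or containing N score 0.
    """
    n = len(seq)
    enc = _encode(seq)
    cols_by_k: dict[int, dict[int, int]] = {}
    for j, kmer in enumerate(spec.kmers):
        code = 0
        for c in kmer:
            code = code * 4 + _BASE_CODE[c]
        cols_by_k.setdefault(len(kmer), {})[code] = j

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for k, code_to_col in cols_by_k.items():
        if n < k:
            continue
        # rolling k-mer codes over all windows, with N-validity
        codes = np.zeros(n - k + 1, dtype=np.int64)
        valid = np.ones(n - k + 1, dtype=bool)
        for t in range(k):
            part = enc[t : t + n - k + 1]
            codes = codes * 4 + np.where(part < 4, part, 0)
            valid &= part < 4
        lookup = np.full(4**k, -1, dtype=np.int64)
        for code, col in code_to_col.items():
            lookup[code] = col
        col_of_window = np.where(valid, lookup[codes], -1)
        # window start for site i: w = i + shift - (p - 1)
        offset = spec.shift - (_active_site_pos(k) - 1)
        w = np.arange(n) + offset
        in_range = (w >= 0) & (w <= n - k)
        i_ok = np.flatnonzero(in_range)
        c = col_of_window[w[i_ok]]
        hit = c >= 0
        rows.append(i_ok[hit])
        cols.append(c[hit])

    row = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    col = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    mat = sp.csr_matrix(
        (np.ones(row.size), (row, col)), shape=(n, len(spec.kmers))
    )
    return list(spec.kmers), mat


def apply_filter(raw_track: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Smooth a per-nucleotide track with a filter.

    ``filtered[i] = (1/Z) * sum_{k=-r..r} raw[i + k + delta] * F(k)`` with
    out-of-range raw values treated as 0 and ``Z = sum_k F(k)``.
    """
    raw = np.asarray(raw_track, dtype=float)
    kernel = spec.kernel()
    z = spec.normalizer
    r, delta = spec.r, spec.delta
    pad = r + abs(delta)
    ext = np.zeros(raw.size + 2 * pad)
    ext[pad : pad + raw.size] = raw
    out = np.zeros(raw.size)
    for k in range(-r, r + 1):
        w = kernel[k + r]
        if w == 0:
            continue
        start = pad + k + delta
        out += w * ext[start : start + raw.size]
    return out / z


def estimate_generalized_filter(
    metaplot_profile: np.ndarray, r: int, delta: int = 0
) -> FilterSpec:
    """Build a generalized filter from an averaged read-depth metaplot.

    The profile covers lags ``[-r, r]`` around the feature anchor.  Weights
    are the profile's excess over its median, floored at zero; a profile
    with no excess signal is an error.
    """
    profile = np.asarray(metaplot_profile, dtype=float)
    if profile.size < 2 * r + 1:
        raise ValueError(
            f"metaplot window of {profile.size} shorter than 2r+1 = {2 * r + 1}"
        )
    profile = profile[: 2 * r + 1]
    weights = np.clip(profile - np.median(profile), 0.0, None)
    if not np.any(weights > 0):
        raise ValueError("flat metaplot: no signal above baseline")
    return FilterSpec(kind="generalized", r=r, delta=delta, weights=weights)


class FeatureMatrix:
    """Per-TU, per-nucleotide covariates with standardization bookkeeping.

    ``raw`` holds one block per TU: a dense ``(n_sites, n_features)`` array
    or a scipy.sparse matrix (indicator features).  Standardization stats
    (per-feature mean/sd over defined, analyzed sites) are stored alongside
    the raw values, so sparse blocks stay sparse: standardized values are an
    affine transform ``(raw - mean) / sd`` materialized on demand, and the
    GLM exploits the same transform to compute its sufficient statistics
    from the raw (mostly zero) entries.

    ``defined`` optionally marks, per TU and feature, the sites where the
    raw feature is meaningful (e.g. CpG sites for DNA methylation); sites
    outside it are exactly 0 after standardization so they carry no signal.
    """

    def __init__(
        self,
        names: list[str],
        raw: list,
        tu_ids: list[str] | None = None,
        defined: list[np.ndarray] | None = None,
        means: np.ndarray | None = None,
        sds: np.ndarray | None = None,
    ):
        self.names = list(names)
        self.raw = list(raw)
        self.tu_ids = list(tu_ids) if tu_ids is not None else [
            str(i) for i in range(len(raw))
        ]
        f = len(self.names)
        for block in self.raw:
            if block.shape[1] != f:
                raise ValueError("feature block width does not match names")
        if defined is not None:
            for block, d in zip(self.raw, defined):
                if sp.issparse(block):
                    raise ValueError(
                        "defined masks are only supported for dense blocks"
                    )
                if d.shape != block.shape:
                    raise ValueError("defined mask shape mismatch")
        self.defined = defined
        self.means = None if means is None else np.asarray(means, dtype=float)
        self.sds = None if sds is None else np.asarray(sds, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def n_tus(self) -> int:
        return len(self.raw)

    @property
    def standardized(self) -> bool:
        return self.means is not None

    @property
    def is_sparse(self) -> bool:
        return any(sp.issparse(b) for b in self.raw)

    def n_sites(self, t: int) -> int:
        return self.raw[t].shape[0]

    def values(self, t: int) -> np.ndarray:
        """Dense (standardized, if stats are set) values for TU ``t``."""
        block = self.raw[t]
        dense = block.toarray() if sp.issparse(block) else np.array(block, dtype=float)
        if not self.standardized:
            return dense
        out = (dense - self.means) / self.sds
        if self.defined is not None:
            out[~self.defined[t]] = 0.0
        return out

    def value_at(self, feature: int | str, t: int, site: int) -> float:
        """Dense value at one (feature, TU, site) triple."""
        if isinstance(feature, str):
            feature = self.names.index(feature)
        block = self.raw[t]
        v = float(block[site, feature])
        if not self.standardized:
            return v
        if self.defined is not None and not self.defined[t][site, feature]:
            return 0.0
        return (v - self.means[feature]) / self.sds[feature]

    def subset_tus(self, indices) -> "FeatureMatrix":
        return FeatureMatrix(
            names=self.names,
            raw=[self.raw[i] for i in indices],
            tu_ids=[self.tu_ids[i] for i in indices],
            defined=None if self.defined is None else [self.defined[i] for i in indices],
            means=self.means,
            sds=self.sds,
        )


def standardize(
    fm: FeatureMatrix, analysis_masks: list[np.ndarray] | None = None
) -> FeatureMatrix:
    """Standardize each feature to mean 0 / sd 1 over analyzed, defined sites.

    Stats use the population sd (divide by n).  Sites outside a feature's
    defined mask are exactly 0 afterwards.  Constant features (sd == 0) are
    dropped with a warning.  Standardizing an already standardized matrix is
    a no-op up to floating point (the transforms compose).
    """
    f = fm.n_features
    total = np.zeros(f)
    total_sq = np.zeros(f)
    count = np.zeros(f)
    for t in range(fm.n_tus):
        block = fm.raw[t]
        if sp.issparse(block):
            # stats on raw entries, mapped through any existing transform below
            if analysis_masks is not None:
                block = block[analysis_masks[t]]
            total += np.asarray(block.sum(axis=0)).ravel()
            total_sq += np.asarray(block.multiply(block).sum(axis=0)).ravel()
            count += block.shape[0]
            continue
        vals = fm.values(t)  # standardized values if stats already set
        if analysis_masks is not None:
            vals = vals[analysis_masks[t]]
            dmask = (
                fm.defined[t][analysis_masks[t]] if fm.defined is not None else None
            )
        else:
            dmask = fm.defined[t] if fm.defined is not None else None
        if dmask is None:
            total += vals.sum(axis=0)
            total_sq += (vals**2).sum(axis=0)
            count += vals.shape[0]
        else:
            total += np.where(dmask, vals, 0.0).sum(axis=0)
            total_sq += np.where(dmask, vals**2, 0.0).sum(axis=0)
            count += dmask.sum(axis=0)

    with np.errstate(invalid="ignore"):
        mean = total / count
        var = total_sq / count - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    if fm.is_sparse and fm.standardized:
        # sparse stats above were computed on raw values; express them on the
        # current (already standardized) scale so composition below is right
        mean = (mean - fm.means) / fm.sds
        sd = sd / fm.sds

    keep = np.flatnonzero((sd > 0) & (count > 0))
    dropped = [fm.names[i] for i in range(f) if i not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping constant/undefined features: {dropped}", stacklevel=2
        )

    # Compose with any existing affine transform so stats stay relative to
    # the raw values (required by the sparse sufficient-statistic path).
    if fm.standardized:
        new_means = fm.means[keep] + mean[keep] * fm.sds[keep]
        new_sds = fm.sds[keep] * sd[keep]
    else:
        new_means = mean[keep]
        new_sds = sd[keep]

    def _take_cols(block):
        return block[:, keep].copy() if not sp.issparse(block) else block[:, keep].tocsr()

    return FeatureMatrix(
        names=[fm.names[i] for i in keep],
        raw=[_take_cols(b) for b in fm.raw],
        tu_ids=fm.tu_ids,
        defined=None
        if fm.defined is None
        else [d[:, keep].copy() for d in fm.defined],
        means=new_means,
        sds=new_sds,
    )
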