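"""Turn raw per-nucleotide counts and annotations into model-ready TUs.

Gene bodies are trimmed to exclude the promoter-proximal pause region
(first 2250 bp after the TSS) and the termination region (last 250 bp);
bodies under 6 kb are discarded.  Windows around internal transcription
initiation signals (regulatory-element peaks, capped-RNA peaks) are masked
since their read density reflects initiation, not elongation.  A LOESS
adjustment removes the gentle U-shaped read-depth profile shared across
gene bodies.  The module also provides the non-model validation summaries:
pausing-location windows, covered/uncovered relative-depth ratios, and
feature-anchored metaplots.
"""

from __future__ import annotations

import warnings

import numpy as np

from elongrate.core_io import IntervalSet, TranscriptionUnit

__all__ = [
    "define_gene_body",
    "mask_internal_signals",
    "loess_flatten",
    "pausing_locations",
    "coverage_ratio",
    "metaplot",
]

TSS_TRIM = 2250
TTS_TRIM = 250
MIN_BODY_LENGTH = 6000


def define_gene_body(
    tss: int, tts: int, strand: str
) -> tuple[int, int] | None:
    """Trimmed gene-body interval, or None if under the length cutoff.

    The body runs from ``TSS + 2250`` to ``TTS - 250`` in transcription
    orientation (mirrored on the minus strand, where ``tss > tts``).
    Bodies shorter than 6 kb are omitted.
    """
    if strand == "+":
        if tss >= tts:
            raise ValueError("plus-strand gene requires tss < tts")
        start, end = tss + TSS_TRIM, tts - TTS_TRIM
    elif strand == "-":
        if tss <= tts:
            raise ValueError("minus-strand gene requires tss > tts")
        start, end = tts + TTS_TRIM, tss - TSS_TRIM
    else:
        raise ValueError(f"bad strand {strand!r}")
    if end - start < MIN_BODY_LENGTH:
        return None
    return start, end


def mask_internal_signals(
    tu: TranscriptionUnit,
    peak_intervals: IntervalSet | None = None,
    cap_sites: list[tuple[str, int, float]] | None = None,
    cap_count_threshold: float = 10,
    cap_radius: int = 1000,
) -> np.ndarray:
    """Validity mask excluding internal transcription-initiation signals.

    Sites inside any peak interval and within ``cap_radius`` nt of a
    capped-RNA site with read count strictly greater than the threshold are
    marked unusable.  ``cap_sites`` are (chrom, position, count) triples in
    genomic coordinates.  Returns the mask in TU-local (5'->3') order.
    """
    mask = np.ones(tu.length, dtype=bool)
    if peak_intervals is not None:
        for iv in peak_intervals.overlapping(tu.chrom, tu.body_start, tu.body_end):
            lo = max(iv.start, tu.body_start)
            hi = min(iv.end, tu.body_end)
            a = tu.genomic_to_local(lo)
            b = tu.genomic_to_local(hi - 1)
            mask[min(a, b) : max(a, b) + 1] = False
    if cap_sites:
        for chrom, pos, count in cap_sites:
            if chrom != tu.chrom or count <= cap_count_threshold:
                continue
            lo = max(pos - cap_radius, tu.body_start)
            hi = min(pos + cap_radius, tu.body_end)
            if lo >= hi:
                continue
            a = tu.genomic_to_local(lo)
            b = tu.genomic_to_local(hi - 1)
            mask[min(a, b) : max(a, b) + 1] = False
    return mask


def loess_flatten(
    tus: list[TranscriptionUnit],
    n_bins: int = 1000,
    span: float = 0.3,
    curve_floor: float = 0.1,
) -> tuple[list[TranscriptionUnit], np.ndarray]:
    """Remove the shared U-shaped read-depth profile along gene bodies.

    Each TU is mapped to a common relative-position scale and
    median-normalized; a LOESS curve is fitted to the cross-gene mean
    profile and rescaled to average height 1; raw counts are divided by the
    curve height at their relative position.  TUs with a zero median are
    excluded with a warning.  Returns the adjusted TUs and the curve (one
    height per bin).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    usable = []
    for tu in tus:
        med = float(np.median(tu.counts))
        if med <= 0:
            warnings.warn(
                f"TU {tu.id}: zero median count, excluded from flattening",
                stacklevel=2,
            )
            continue
        usable.append((tu, med))
    if len(usable) < 2:
        raise ValueError("need at least 2 TUs with positive median counts")

    bin_sum = np.zeros(n_bins)
    bin_n = np.zeros(n_bins)
    for tu, med in usable:
        rel = (np.arange(tu.length) + 0.5) / tu.length
        b = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        np.add.at(bin_sum, b, tu.counts / med)
        np.add.at(bin_n, b, 1.0)
    profile = np.where(bin_n > 0, bin_sum / np.maximum(bin_n, 1), 1.0)

    centers = (np.arange(n_bins) + 0.5) / n_bins
    curve = lowess(profile, centers, frac=span, return_sorted=False)
    curve = curve / curve.mean()
    curve = np.maximum(curve, curve_floor)

    adjusted = []
    for tu, _med in usable:
        rel = (np.arange(tu.length) + 0.5) / tu.length
        height = np.interp(rel, centers, curve)
        adjusted.append(
            TranscriptionUnit(
                id=tu.id,
                chrom=tu.chrom,
                strand=tu.strand,
                body_start=tu.body_start,
                body_end=tu.body_end,
                counts=tu.counts / height,
                mask=tu.mask.copy(),
            )
        )
    return adjusted, curve


def pausing_locations(
    tu: TranscriptionUnit, window: int = 200, top_k: int = 5
) -> list[tuple[int, int]]:
    """Top-k windows by summed read count, as putative pausing locations.

    The body is tiled with non-overlapping windows from the 5' end (a final
    partial window is dropped); windows are ranked by summed count with
    ties broken by the 5'-most start.  Returns TU-local (start, end) pairs.
    """
    n_windows = tu.length // window
    if n_windows < top_k:
        warnings.warn(
            f"TU {tu.id}: only {n_windows} windows of {window} nt fit; "
            f"returning fewer than {top_k}",
            stacklevel=2,
        )
    if n_windows == 0:
        return []
    sums = tu.counts[: n_windows * window].reshape(n_windows, window).sum(axis=1)
    order = np.lexsort((np.arange(n_windows), -sums))
    picked = order[: min(top_k, n_windows)]
    return [(int(w * window), int((w + 1) * window)) for w in picked]


def coverage_ratio(
    tus: list[TranscriptionUnit], feature_masks: list[np.ndarray]
) -> float:
    """Pooled relative read depth in feature-covered vs uncovered sites.

    Each TU's counts are first divided by the TU mean (so initiation-rate
    differences cancel); the ratio of the pooled mean over covered sites to
    the pooled mean over uncovered sites is returned.  A value above 1
    indicates elevated read depth (slower polymerase) at covered sites.
    """
    cov_sum = cov_n = unc_sum = unc_n = 0.0
    for tu, fmask in zip(tus, feature_masks):
        fmask = np.asarray(fmask, dtype=bool)
        if fmask.shape != (tu.length,):
            raise ValueError(f"TU {tu.id}: feature mask length mismatch")
        use = tu.mask
        mean = tu.counts[use].mean() if use.any() else 0.0
        if mean <= 0:
            continue
        rel = tu.counts / mean
        c = fmask & use
        u = ~fmask & use
        cov_sum += rel[c].sum()
        cov_n += c.sum()
        unc_sum += rel[u].sum()
        unc_n += u.sum()
    if cov_n == 0 or unc_n == 0:
        raise ValueError("empty covered or uncovered site set")
    return (cov_sum / cov_n) / (unc_sum / unc_n)


def metaplot(
    tus: list[TranscriptionUnit],
    anchors: list[np.ndarray],
    radius: int,
) -> np.ndarray:
    """Average relative read depth at offsets [-radius, radius] from anchors.

    ``anchors`` holds TU-local anchor positions per TU (strand orientation
    is already baked into local coordinates).  Window positions outside the
    body are skipped.  The profile feeds
    :func:`elongrate.features.estimate_generalized_filter`.
    """
    width = 2 * radius + 1
    total = np.zeros(width)
    n = np.zeros(width)
    any_anchor = False
    for tu, pos_list in zip(tus, anchors):
        mean = tu.counts[tu.mask].mean() if tu.mask.any() else 0.0
        if mean <= 0:
            continue
        rel = tu.counts / mean
        for p in np.asarray(pos_list, dtype=int):
            any_anchor = True
            lo = max(p - radius, 0)
            hi = min(p + radius + 1, tu.length)
            sl = slice(lo - (p - radius), width - ((p + radius + 1) - hi))
            total[sl] += rel[lo:hi]
            n[sl] += 1
    if not any_anchor:
        raise ValueError("no anchors supplied")
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)
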