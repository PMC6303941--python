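"""CpG-density bias estimation and absolute-methylation inference.

MeDIP enrichment of a bin is modeled as the product of its methylation
signal and a CpG-density effect, ``y = M * f(n_CpG)``. Because sparse-CpG
regions of a mammalian genome are almost fully methylated, the mean bin
reads of low-density bins trace ``f`` itself; antibody binding saturates at
high CpG density, so ``f`` is sigmoidal:

    f(n) = expit(b0 + b1 * n)

The fit groups bins by exact CpG count, normalizes the group means by the
maximum group mean (the empirical upper asymptote), and regresses the logit
of the normalized means on n by ordinary least squares:

    logit(ybar_n / y_max) = b0 + b1 * n

Groups at and beyond the argmax of the group means belong to the
hypomethylated high-density regime and are excluded, as are groups whose
mean is so close to the asymptote that the logit becomes numerically
unstable. Correction divides counts by f, log-transforms, and min-max
scales to [0, 1]; the whole procedure runs on each strand separately and
the per-strand tracks are averaged.

A linear baseline (line fitted through the low-density group means and
extrapolated) reproduces the classical MEDIPS-style calibration for
comparison; it over-corrects saturated high-density bins by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import linregress

from .binning import StrandBinCounts, combine_strands, count_bin_reads
from .genome import BinScheme, bin_cpg_counts, scan_cpg_sites

logger = logging.getLogger(__name__)

ModelKind = Literal["sigmoid", "linear"]


class InsufficientDynamicRangeError(ValueError):
    """Too few usable CpG-count groups to constrain the bias curve."""


@dataclass
class CpGGroupProfile:
    """Bin-read summaries of bins grouped by exact CpG count.

    Arrays are aligned and sorted ascending by ``n_cpg``. ``usable`` marks
    groups with at least the configured minimum number of bins; only usable
    groups inform a fit, but every group is corrected by the fitted curve.
    """

    n_cpg: np.ndarray
    mean_reads: np.ndarray
    n_bins: np.ndarray
    var_reads: np.ndarray
    usable: np.ndarray
    min_bins_per_group: int

    def __len__(self) -> int:
        return len(self.n_cpg)


@dataclass
class BiasFit:
    """Fitted CpG-density bias curve.

    For ``kind == 'sigmoid'``: ``f(n) = expit(beta0 + beta1*n)``, an
    estimate of the density effect relative to the asymptote ``y_max``.
    For ``kind == 'linear'``: ``f(n) = max(beta0 + beta1*n, eps_floor)``
    in units of bin reads (the baseline has no asymptote).
    """

    kind: ModelKind
    beta0: float
    beta1: float
    y_max: float | None = None
    n_fit: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    stderr_beta1: float = float("nan")
    eps_floor: float = 0.0

    def bias(self, n_cpg: np.ndarray | float) -> np.ndarray:
        """Evaluate the fitted density effect at CpG count(s) *n_cpg*."""
        n = np.asarray(n_cpg, dtype=float)
        if self.kind == "sigmoid":
            return expit(self.beta0 + self.beta1 * n)
        return np.maximum(self.beta0 + self.beta1 * n, self.eps_floor)


@dataclass
class MethylationTrack:
    """Per-bin inferred absolute methylation in [0, 1].

    ``plus``/``minus`` are None for combined-strand (strand-blind) runs;
    ``merged`` is always present. Missing bins are NaN.
    """

    scheme: BinScheme
    merged: np.ndarray
    plus: np.ndarray | None = None
    minus: np.ndarray | None = None
    model_kind: ModelKind = "sigmoid"
    fits: dict[str, BiasFit] = field(default_factory=dict)
    strand_split: bool = True


def group_by_cpg(
    counts_one_strand: np.ndarray,
    n_cpg_vector: np.ndarray,
    min_bins_per_group: int = 10,
) -> CpGGroupProfile:
    """Group bins by exact CpG count and summarize their read counts.

    Group means include zero-count bins. CpG counts that occur in no bin
    simply have no group. Groups smaller than ``min_bins_per_group`` are
    kept (for correction) but flagged unusable for fitting.
    """
    y = np.asarray(counts_one_strand, dtype=float)
    n = np.asarray(n_cpg_vector)
    if y.shape != n.shape:
        raise ValueError("counts and CpG vectors differ in length")
    df = pd.DataFrame({"n": n, "y": y})
    g = df.groupby("n", sort=True)["y"]
    agg = g.agg(["mean", "count", "var"])
    return CpGGroupProfile(
        n_cpg=agg.index.to_numpy(),
        mean_reads=agg["mean"].to_numpy(),
        n_bins=agg["count"].to_numpy(dtype=np.int64),
        var_reads=np.nan_to_num(agg["var"].to_numpy(), nan=0.0),
        usable=agg["count"].to_numpy() >= min_bins_per_group,
        min_bins_per_group=min_bins_per_group,
    )


def _argmax_cut(n_cpg: np.ndarray, means: np.ndarray) -> tuple[float, int]:
    """(max group mean, n_cpg of the first group attaining it)."""
    i = int(np.argmax(means))  # first (= smallest-n) argmax on ties
    return float(means[i]), int(n_cpg[i])


def fit_sigmoid_bias(
    profile: CpGGroupProfile,
    y_max: float | None = None,
    saturation_guard: float = 0.95,
) -> BiasFit:
    """Fit the logit-linear bias model to the usable group means.

    ``y_max`` defaults to the maximum usable group mean (the empirical
    asymptote); pass the true asymptote when it is known. Groups at and
    beyond the argmax group are excluded, as are groups with mean <= 0,
    >= y_max, or above ``saturation_guard * y_max`` — the logit's slope
    diverges as the mean approaches the asymptote, so near-saturated groups
    would dominate the regression with unbounded leverage.
    """
    m = profile.usable
    if m.sum() < 3:
        raise InsufficientDynamicRangeError(
            f"need >=3 usable groups, have {int(m.sum())}"
        )
    n = profile.n_cpg[m].astype(float)
    ybar = profile.mean_reads[m]
    obs_max, n_at_max = _argmax_cut(n, ybar)
    asymptote = obs_max if y_max is None else float(y_max)
    ratio = ybar / asymptote
    keep = (n < n_at_max) & (ratio > 0.0) & (ratio < 1.0)
    keep &= ratio <= saturation_guard
    if keep.sum() < 3:
        raise InsufficientDynamicRangeError(
            f"only {int(keep.sum())} groups below the saturation regime"
        )
    x, z = n[keep], logit(ratio[keep])
    res = linregress(x, z)
    if res.slope <= 0:
        logger.warning(
            "fitted bias slope %.4g <= 0; enrichment should increase with "
            "CpG density",
            res.slope,
        )
    fitted = res.intercept + res.slope * x
    return BiasFit(
        kind="sigmoid",
        beta0=float(res.intercept),
        beta1=float(res.slope),
        y_max=asymptote,
        n_fit=x.astype(np.int64),
        residuals=z - fitted,
        stderr_beta1=float(res.stderr),
    )


def fit_linear_bias(
    profile: CpGGroupProfile,
    low_cpg_quantile: float | None = None,
) -> BiasFit:
    """Fit the linear baseline through the low-density group means.

    The line is fitted to usable groups below the argmax of the group means
    (the rising, fully-methylated regime) — or, when ``low_cpg_quantile`` is
    given, to the lowest such fraction of the CpG-count range — and
    extrapolated everywhere, floored at a tiny positive constant.
    """
    m = profile.usable
    n = profile.n_cpg[m].astype(float)
    ybar = profile.mean_reads[m]
    if len(n) < 2:
        raise InsufficientDynamicRangeError("need >=2 usable groups")
    _, n_at_max = _argmax_cut(n, ybar)
    keep = n < n_at_max
    if low_cpg_quantile is not None:
        cut = np.quantile(n, low_cpg_quantile)
        keep = n <= cut
    if keep.sum() < 2:
        keep = np.ones_like(keep)  # degenerate profile: use all groups
    x, z = n[keep], ybar[keep]
    if np.allclose(x, x[0]):
        raise InsufficientDynamicRangeError("single CpG count in fit window")
    res = linregress(x, z)
    eps = np.finfo(float).eps * max(float(np.max(ybar)), 1.0)
    fitted = res.intercept + res.slope * x
    return BiasFit(
        kind="linear",
        beta0=float(res.intercept),
        beta1=float(res.slope),
        n_fit=x.astype(np.int64),
        residuals=z - fitted,
        stderr_beta1=float(res.stderr),
        eps_floor=eps,
    )


def correct_and_scale(
    counts_one_strand: np.ndarray,
    n_cpg_vector: np.ndarray,
    bias_fit: BiasFit,
) -> np.ndarray:
    """Divide by the fitted bias, log-transform, and min-max scale to [0, 1].

    Bins with zero reads get methylation 0 directly: zero enrichment is the
    model's strongest evidence of absent methylation and has no logarithm.
    The scaling minimum and maximum are taken over the non-zero bins of the
    vector; with a single distinct transformed value the non-zero bins all
    map to 1 (degenerate scale, warned).
    """
    y = np.asarray(counts_one_strand, dtype=float)
    n = np.asarray(n_cpg_vector, dtype=float)
    f = bias_fit.bias(n)
    if np.any(f <= 0):
        raise ValueError("bias curve non-positive at some observed CpG count")
    out = np.zeros_like(y)
    nz = y > 0
    if not nz.any():
        warnings.warn("all bins have zero reads; returning all-zero track")
        return out
    ypp = np.log(y[nz] / f[nz])
    lo, hi = float(ypp.min()), float(ypp.max())
    if hi == lo:
        warnings.warn("degenerate scale: single transformed value; set to 1")
        out[nz] = 1.0
        return out
    out[nz] = np.clip((ypp - lo) / (hi - lo), 0.0, 1.0)
    return out


def merge_strands(
    plus_track: np.ndarray, minus_track: np.ndarray
) -> np.ndarray:
    """Elementwise mean of the two strand tracks.

    Where exactly one strand is missing (NaN) the other strand's value is
    reported; both missing stays missing.
    """
    p = np.asarray(plus_track, dtype=float)
    m = np.asarray(minus_track, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        merged = np.nanmean(np.vstack([p, m]), axis=0)
    return merged


def infer_from_counts(
    counts: StrandBinCounts,
    n_cpg_vector: np.ndarray,
    model_kind: ModelKind = "sigmoid",
    strand_split: bool = True,
    min_bins_per_group: int = 10,
    saturation_guard: float = 0.95,
) -> MethylationTrack:
    """Run bias fitting, correction and scaling on pre-computed bin counts.

    With ``strand_split`` the full procedure runs independently on each
    strand's counts and the merged track is the per-bin mean; otherwise the
    strands are summed first and processed once (the strand-blind classical
    pipeline).
    """

    def one(y: np.ndarray) -> tuple[np.ndarray, BiasFit]:
        profile = group_by_cpg(y, n_cpg_vector, min_bins_per_group)
        if model_kind == "sigmoid":
            fit = fit_sigmoid_bias(profile, saturation_guard=saturation_guard)
        elif model_kind == "linear":
            fit = fit_linear_bias(profile)
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        return correct_and_scale(y, n_cpg_vector, fit), fit

    if strand_split:
        plus, fit_p = one(counts.plus)
        minus, fit_m = one(counts.minus)
        merged = merge_strands(plus, minus)
        return MethylationTrack(
            scheme=counts.scheme,
            merged=merged,
            plus=plus,
            minus=minus,
            model_kind=model_kind,
            fits={"plus": fit_p, "minus": fit_m},
            strand_split=True,
        )
    total = combine_strands(counts)
    merged, fit = one(total)
    return MethylationTrack(
        scheme=counts.scheme,
        merged=merged,
        model_kind=model_kind,
        fits={"combined": fit},
        strand_split=False,
    )


def infer_methylation(
    alignments,
    fasta,
    bin_size: int = 100,
    model_kind: ModelKind = "sigmoid",
    strand_split: bool = True,
    chromosomes: Sequence[str] | None = None,
    fragment_extension: int = 200,
    mapq_min: int = 0,
    dedup: bool = False,
    min_bins_per_group: int = 10,
) -> MethylationTrack:
    """End-to-end inference from aligned reads and a reference genome.

    Scans the reference for CpG sites, tiles it into ``bin_size`` bins,
    counts extended reads per strand, and runs :func:`infer_from_counts`.
    Deterministic given inputs and flags.
    """
    index = scan_cpg_sites(fasta, chromosomes)
    scheme = index.bin_scheme(bin_size)
    n_cpg = bin_cpg_counts(index, scheme)
    counts = count_bin_reads(
        alignments,
        scheme,
        fragment_extension=fragment_extension,
        mapq_min=mapq_min,
        dedup=dedup,
    )
    return infer_from_counts(
        counts,
        n_cpg,
        model_kind=model_kind,
        strand_split=strand_split,
        min_bins_per_group=min_bins_per_group,
    )
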