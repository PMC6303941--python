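"""Bisulfite truth tracks and concordance scoring.

Bisulfite sequencing (RRBS/WGBS) reports a methylation fraction per
cytosine; binning those calls gives the per-bin "true" methylation a
MeDIP-derived track is judged against. Bins are retained only when enough
sufficiently-covered CpGs fall in them (defaults: depth >= 10 reads per
CpG, >= 4 covered CpGs per bin), and agreement is measured with Pearson
(PCC) and Spearman (SCC) correlation, overall and stratified by CpG-density
quartile. A separate report correlates plus-only with minus-only truth
tracks per chromosome to quantify strand asymmetry of CpG methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .genome import BinScheme, CpGIndex

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "fraction", "depth"]


@dataclass
class TruthTrack:
    """Per-bin mean bisulfite methylation with CpG coverage counts.

    ``values`` holds the arithmetic mean of the covered CpG fractions per
    bin (NaN where fewer than ``min_cpgs_per_bin`` CpGs survive the depth
    filter — missing, never zero). ``n_cpgs`` counts the covered CpGs that
    entered each mean.
    """

    scheme: BinScheme
    values: np.ndarray
    n_cpgs: np.ndarray
    min_cpgs_per_bin: int
    min_depth: int
    strand_mode: str = "combined"


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table lacks columns {missing}")
    frac = calls["fraction"].to_numpy(dtype=float)
    bad = ~((frac >= 0.0) & (frac <= 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"methylation fraction outside [0,1] at call row {row}: "
            f"{frac[row]!r}"
        )
    return calls


def read_bismark_cov(path: str, cpg_index: CpGIndex | None = None) -> pd.DataFrame:
    """Read a Bismark coverage file into the internal call table.

    Columns: chrom, 1-based start, 1-based end, methylation percentage,
    count methylated, count unmethylated. Converted to 0-based positions
    and fractions. Strand is inferred from ``cpg_index`` when given (a call
    at a CpG's C position is '+', at the following G position '-'),
    otherwise left as '.'.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "percent", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    calls = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64) - 1,
            "strand": ".",
            "fraction": df["percent"].astype(float) / 100.0,
            "depth": (df["n_meth"] + df["n_unmeth"]).astype(np.int64),
        }
    )
    if cpg_index is not None:
        calls["strand"] = _infer_strand(calls, cpg_index)
    return _validate_calls(calls)


def read_cpg_bedgraph(path: str) -> pd.DataFrame:
    """Read a per-CpG bedGraph: chrom, start, end, fraction[, depth[, strand]].

    Coordinates are 0-based half-open and the value column is a fraction in
    [0, 1]. A missing depth column is treated as unlimited coverage; a
    missing strand column as unknown ('.').
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 columns")
            frac = float(parts[3])
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: fraction {frac} outside [0,1]"
                )
            depth = int(float(parts[4])) if len(parts) > 4 else np.iinfo(np.int64).max
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], int(parts[1]), strand, frac, depth))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _infer_strand(calls: pd.DataFrame, cpg_index: CpGIndex) -> np.ndarray:
    out = np.full(len(calls), ".", dtype=object)
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = cpg_index.positions.get(chrom)
        if pos is None:
            continue
        p = sub["pos"].to_numpy()
        plus = np.isin(p, pos)
        minus = np.isin(p - 1, pos) & ~plus
        out[sub.index[plus]] = "+"
        out[sub.index[minus]] = "-"
    return out


def build_truth(
    per_cpg_calls: pd.DataFrame,
    bin_scheme: BinScheme,
    min_cpgs_per_bin: int = 4,
    min_depth: int = 10,
    strand_mode: str = "combined",
) -> TruthTrack:
    """Aggregate per-CpG bisulfite calls into a per-bin truth track.

    The depth filter applies per CpG before binning; ``strand_mode`` selects
    which cytosines enter the bin mean ('combined', 'plus' or 'minus').
    """
    calls = _validate_calls(per_cpg_calls)
    if strand_mode == "plus":
        calls = calls[calls["strand"] == "+"]
    elif strand_mode == "minus":
        calls = calls[calls["strand"] == "-"]
    elif strand_mode != "combined":
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    calls = calls[calls["depth"] >= min_depth]
    known = calls["chrom"].isin(bin_scheme.chrom_lengths)
    if (~known).any():
        logger.info("build_truth: dropped %d calls on unknown chromosomes",
                    int((~known).sum()))
        calls = calls[known]

    values = np.full(bin_scheme.total_bins, np.nan)
    n_cpgs = np.zeros(bin_scheme.total_bins, dtype=np.int64)
    if len(calls):
        offsets = {c: bin_scheme.offset(c) for c in bin_scheme.chromosomes}
        gbin = (
            calls["pos"].to_numpy() // bin_scheme.bin_size
            + calls["chrom"].map(offsets).to_numpy()
        )
        df = pd.DataFrame({"bin": gbin, "f": calls["fraction"].to_numpy()})
        agg = df.groupby("bin")["f"].agg(["mean", "count"])
        idx = agg.index.to_numpy()
        n_cpgs[idx] = agg["count"].to_numpy()
        ok = agg["count"].to_numpy() >= min_cpgs_per_bin
        values[idx[ok]] = agg["mean"].to_numpy()[ok]
    return TruthTrack(
        scheme=bin_scheme,
        values=values,
        n_cpgs=n_cpgs,
        min_cpgs_per_bin=min_cpgs_per_bin,
        min_depth=min_depth,
        strand_mode=strand_mode,
    )


def score(inferred: np.ndarray, truth: np.ndarray) -> dict:
    """Pearson and Spearman correlation over pairwise-complete bins."""
    x = np.asarray(inferred, dtype=float)
    y = np.asarray(truth, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 2 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
        return {"pcc": float("nan"), "scc": float("nan"), "n_bins": n}
    pcc = pearsonr(x[mask], y[mask]).statistic
    scc = spearmanr(x[mask], y[mask]).statistic
    return {"pcc": float(pcc), "scc": float(scc), "n_bins": n}


QUARTILE_LABELS = ("low", "lower-medium", "higher-medium", "high")


def score_by_cpg_quartile(
    inferred: np.ndarray,
    truth: np.ndarray,
    n_cpg_vector: np.ndarray,
) -> list[dict]:
    """Correlations within four CpG-density strata of the evaluated bins.

    Quartile boundaries are nearest-rank quantiles of the CpG counts of the
    pairwise-complete bins; a bin whose count ties a boundary goes to the
    lower stratum. Empty strata score NaN with a zero bin count.
    """
    x = np.asarray(inferred, dtype=float)
    y = np.asarray(truth, dtype=float)
    n = np.asarray(n_cpg_vector)
    mask = np.isfinite(x) & np.isfinite(y)
    records: list[dict] = []
    if not mask.any():
        return [
            {"category": lab, "pcc": float("nan"), "scc": float("nan"),
             "n_bins": 0}
            for lab in QUARTILE_LABELS
        ]
    q1, q2, q3 = np.percentile(
        n[mask], [25, 50, 75], method="inverted_cdf"
    )
    bounds = [(None, q1), (q1, q2), (q2, q3), (q3, None)]
    for lab, (lo, hi) in zip(QUARTILE_LABELS, bounds):
        sel = mask.copy()
        if lo is not None:
            sel &= n > lo
        if hi is not None:
            sel &= n <= hi
        rec = score(x[sel], y[sel])
        rec["category"] = lab
        rec["n_cpg_range"] = (None if lo is None else int(lo),
                              None if hi is None else int(hi))
        records.append(rec)
    return records


def strand_concordance(
    per_cpg_calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_sizes: Sequence[int],
    min_depth: int = 10,
    min_cpgs_per_bin: int = 1,
) -> pd.DataFrame:
    """Per-chromosome PCC between plus- and minus-strand bin methylation.

    For each requested bin size, plus-only and minus-only truth tracks are
    built and correlated over bins where both are present. Chromosomes with
    fewer than two such bins (or constant tracks) report NaN.
    """
    rows = []
    for bin_size in bin_sizes:
        scheme = BinScheme(dict(chrom_lengths), int(bin_size))
        plus = build_truth(per_cpg_calls, scheme, min_cpgs_per_bin,
                           min_depth, "plus")
        minus = build_truth(per_cpg_calls, scheme, min_cpgs_per_bin,
                            min_depth, "minus")
        for chrom in scheme.chromosomes:
            off, nb = scheme.offset(chrom), scheme.n_bins(chrom)
            sl = slice(off, off + nb)
            rec = score(plus.values[sl], minus.values[sl])
            rows.append(
                {"bin_size": int(bin_size), "chrom": chrom,
                 "pcc": rec["pcc"], "n_bins": rec["n_bins"]}
            )
    return pd.DataFrame(rows, columns=["bin_size", "chrom", "pcc", "n_bins"])
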