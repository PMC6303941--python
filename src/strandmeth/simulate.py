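"""Synthetic MeDIP-seq generator with strand-resolved methylation truth.

The generator realizes the multiplicative enrichment law the inference
assumes: the expected bin read count on strand s is

    lambda_s(b) = (depth / 2) * M_s(b) * f*(n_CpG(b)),
    f*(n) = expit(beta0* + beta1* * n),

with Poisson-distributed realized counts. Methylation truth follows the
empirical pattern of mammalian genomes — sparse-CpG regions almost fully
methylated, dense regions (CpG islands) hypomethylated: the mean bin
methylation is ``plateau * expit(-rate * (n - halfway))`` in the bin CpG
count n, per-bin levels are Beta-distributed around that mean, and per-CpG
values jitter around the bin level with a Gaussian-copula correlation
``strand_rho`` between the two strands (asymmetric CpG methylation).

The read-level path additionally builds a reference sequence whose per-bin
CpG counts are exact, places each fragment uniformly *inside* its bin, and
emits FASTA + SAM (or BED6) + per-CpG bisulfite-like call tables, so the
binning module's recount reproduces the realized truth counts exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import pysam
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .binning import StrandBinCounts
from .genome import BinScheme, CpGIndex

CHROM = "chrSim"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a 2 Mb single-chromosome genome tiled into 100 bp
    bins with CpG counts spread uniformly over 1..20, a sigmoidal density
    effect (beta0*=-2, beta1*=0.5), genome-wide mean methylation ~0.8
    declining with CpG density, strand correlation 0.9, and a sequencing
    depth of 30 expected reads (both strands together) for a fully
    methylated bin at bias saturation.
    """

    n_bins: int = 20_000
    bin_size: int = 100
    cpg_min: int = 1
    cpg_max: int = 20
    cpg_placement: Literal["random", "gradient"] = "random"
    beta0: float = -2.0
    beta1: float = 0.5
    meth_plateau: float = 0.85
    meth_decline_rate: float = 1.5
    meth_halfway_cpg: float = 17.0
    bin_beta_concentration: float = 2.0
    cpg_beta_concentration: float = 8.0
    strand_rho: float = 0.9
    depth: float = 30.0
    read_length: int = 50
    fragment_length: int = 50
    truth_call_depth_mean: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strand_rho <= 1.0:
            raise ValueError("strand_rho must lie in [0, 1]")
        if not 0.0 <= self.meth_plateau <= 1.0:
            raise ValueError("meth_plateau must lie in [0, 1]")
        if self.fragment_length > self.bin_size:
            raise ValueError("fragment_length must not exceed bin_size")
        if self.read_length > self.fragment_length:
            raise ValueError("read_length must not exceed fragment_length")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @property
    def genome_length(self) -> int:
        return self.n_bins * self.bin_size

    def scheme(self) -> BinScheme:
        return BinScheme({CHROM: self.genome_length}, self.bin_size)


@dataclass
class SimulatedData:
    """Everything one synthetic run produced, truth included."""

    config: SimulationConfig
    scheme: BinScheme
    n_cpg: np.ndarray
    bin_meth_plus: np.ndarray
    bin_meth_minus: np.ndarray
    bin_meth_combined: np.ndarray
    counts: StrandBinCounts
    expected_plus: np.ndarray
    expected_minus: np.ndarray
    cpg_meth_plus: np.ndarray
    cpg_meth_minus: np.ndarray
    cpg_bin_index: np.ndarray
    cpg_index: CpGIndex | None = None
    sequence: str | None = None
    calls: pd.DataFrame | None = None

    @property
    def f_true(self) -> np.ndarray:
        c = self.config
        return expit(c.beta0 + c.beta1 * self.n_cpg.astype(float))


def _draw_bin_cpg_counts(config: SimulationConfig, rng: np.random.Generator
                         ) -> np.ndarray:
    lo, hi = config.cpg_min, config.cpg_max
    if config.cpg_placement == "gradient":
        # deterministic ramp of density along the chromosome
        ramp = np.linspace(lo, hi, config.n_bins)
        return np.rint(ramp).astype(np.int64)
    return rng.integers(lo, hi + 1, size=config.n_bins)


def simulate_methylation(
    config: SimulationConfig,
    n_cpg: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-CpG, per-strand methylation truth.

    Returns ``(meth_plus, meth_minus, cpg_bin_index)`` with one entry per
    CpG site, bin-ordered. Strands share each bin's latent level and their
    per-CpG values are coupled through a Gaussian copula with correlation
    ``strand_rho``; the marginal mean decreases with bin CpG density.
    """
    c = config
    n = np.asarray(n_cpg, dtype=np.int64)
    mu = c.meth_plateau * expit(-c.meth_decline_rate * (n - c.meth_halfway_cpg))
    kb = c.bin_beta_concentration
    a = np.clip(mu * kb, 1e-3, None)
    b = np.clip((1.0 - mu) * kb, 1e-3, None)
    bin_level = rng.beta(a, b)
    bin_level[mu <= 0.0] = 0.0  # degenerate edges, not clipped Beta draws
    bin_level[mu >= 1.0] = 1.0

    cpg_bin = np.repeat(np.arange(len(n)), n)
    level = bin_level[cpg_bin]
    kc = c.cpg_beta_concentration
    aa = np.clip(level * kc, 1e-3, None)
    bb = np.clip((1.0 - level) * kc, 1e-3, None)

    m = len(cpg_bin)
    rho = c.strand_rho
    z_common = rng.standard_normal(m)
    if rho >= 1.0:
        z_plus = z_minus = z_common
    else:
        z_plus = np.sqrt(rho) * z_common + np.sqrt(1 - rho) * rng.standard_normal(m)
        z_minus = np.sqrt(rho) * z_common + np.sqrt(1 - rho) * rng.standard_normal(m)
    from scipy.stats import norm

    u_plus = norm.cdf(z_plus)
    u_minus = norm.cdf(z_minus)
    meth_plus = beta_dist.ppf(u_plus, aa, bb)
    meth_minus = beta_dist.ppf(u_minus, aa, bb)
    degenerate = (level <= 0.0) | (level >= 1.0)
    meth_plus[degenerate] = level[degenerate]
    meth_minus[degenerate] = level[degenerate]
    return meth_plus, meth_minus, cpg_bin


def _bin_means(values: np.ndarray, cpg_bin: np.ndarray, n_bins: int
               ) -> np.ndarray:
    sums = np.bincount(cpg_bin, weights=values, minlength=n_bins)
    cnts = np.bincount(cpg_bin, minlength=n_bins)
    out = np.zeros(n_bins)
    nz = cnts > 0
    out[nz] = sums[nz] / cnts[nz]
    return out


def simulate_dataset(
    config: SimulationConfig,
    emit: Literal["counts", "reads"] = "counts",
    out_dir: str | None = None,
    alignment_format: Literal["sam", "bed"] = "sam",
) -> SimulatedData:
    """Generate one synthetic dataset under *config*.

    ``emit='counts'`` draws per-bin CpG counts, methylation truth and
    Poisson bin counts without materializing sequence or reads (fast path
    for large parameter-recovery runs). ``emit='reads'`` additionally
    builds the reference FASTA, per-read alignments and per-CpG call
    tables in ``out_dir``.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    scheme = c.scheme()
    n_cpg = _draw_bin_cpg_counts(c, rng)

    meth_p, meth_m, cpg_bin = simulate_methylation(c, n_cpg, rng)
    bin_p = _bin_means(meth_p, cpg_bin, c.n_bins)
    bin_m = _bin_means(meth_m, cpg_bin, c.n_bins)
    bin_comb = 0.5 * (bin_p + bin_m)

    f = expit(c.beta0 + c.beta1 * n_cpg.astype(float))
    lam_p = 0.5 * c.depth * bin_p * f
    lam_m = 0.5 * c.depth * bin_m * f
    y_p = rng.poisson(lam_p).astype(float)
    y_m = rng.poisson(lam_m).astype(float)
    counts = StrandBinCounts(
        scheme=scheme,
        plus=y_p,
        minus=y_m,
        fragment_extension=c.fragment_length,
        n_reads_plus=int(y_p.sum()),
        n_reads_minus=int(y_m.sum()),
    )

    data = SimulatedData(
        config=c,
        scheme=scheme,
        n_cpg=n_cpg,
        bin_meth_plus=bin_p,
        bin_meth_minus=bin_m,
        bin_meth_combined=bin_comb,
        counts=counts,
        expected_plus=lam_p,
        expected_minus=lam_m,
        cpg_meth_plus=meth_p,
        cpg_meth_minus=meth_m,
        cpg_bin_index=cpg_bin,
    )
    if emit == "reads":
        if out_dir is None:
            raise ValueError("emit='reads' requires out_dir")
        _emit_files(data, rng, out_dir, alignment_format)
    return data


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator, n_cpg: np.ndarray
) -> tuple[str, CpGIndex]:
    """Build a reference whose per-bin CpG counts equal *n_cpg* exactly.

    The background sequence contains no CG dinucleotide (a G is never
    drawn directly after a C); the requested CpGs are then planted at
    random non-adjacent in-bin offsets, which neither creates nor destroys
    other CpGs. A bin with target 0 therefore contains no CpG at all.
    """
    c = config
    length = c.genome_length
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    cg = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
    seq[1:][cg] = ord("A")  # break background CGs; cannot create new ones

    positions: list[np.ndarray] = []
    slots = c.bin_size - 1  # C may sit anywhere but the bin's last base
    for b, k in enumerate(np.asarray(n_cpg, dtype=int)):
        if k == 0:
            continue
        if k > (slots + 1) // 2:
            raise ValueError(f"bin {b}: cannot place {k} non-adjacent CpGs")
        picks = np.sort(rng.choice(slots - k + 1, size=k, replace=False))
        offs = picks + np.arange(k)  # enforces spacing >= 2
        pos = b * c.bin_size + offs
        seq[pos] = ord("C")
        seq[pos + 1] = ord("G")
        positions.append(pos)
    all_pos = (
        np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    )
    index = CpGIndex(
        positions={CHROM: np.sort(all_pos).astype(np.int64)},
        chrom_lengths={CHROM: length},
    )
    return seq.tobytes().decode("ascii"), index


def _emit_files(
    data: SimulatedData,
    rng: np.random.Generator,
    out_dir: str,
    alignment_format: str,
) -> None:
    c = data.config
    os.makedirs(out_dir, exist_ok=True)
    sequence, index = simulate_reference(c, rng, data.n_cpg)
    data.sequence = sequence
    data.cpg_index = index

    fasta_path = os.path.join(out_dir, "reference.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")
    if os.path.exists(fasta_path + ".fai"):
        os.remove(fasta_path + ".fai")

    _emit_reads(data, rng, out_dir, alignment_format)
    _emit_truth_tables(data, rng, out_dir, index)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(c.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _emit_reads(
    data: SimulatedData, rng: np.random.Generator, out_dir: str, fmt: str
) -> None:
    """Place each counted fragment uniformly inside its bin and write reads.

    Fragments never cross a bin boundary (fragment_length <= bin_size), so
    recounting the emitted file with extension = fragment_length reproduces
    the realized truth counts exactly.
    """
    c = data.config
    B, L, R = c.bin_size, c.fragment_length, c.read_length
    records: list[tuple[int, int, str]] = []  # (read_start, read_end, strand)
    for strand, vec in (("+", data.counts.plus), ("-", data.counts.minus)):
        bins = np.flatnonzero(vec > 0)
        for b in bins:
            k = int(vec[b])
            lo, hi = b * B, min((b + 1) * B, c.genome_length)
            frag_starts = rng.integers(lo, hi - L + 1, size=k)
            for fs in frag_starts.tolist():
                if strand == "+":
                    records.append((fs, fs + R, strand))
                else:
                    fe = fs + L
                    records.append((fe - R, fe, strand))
    records.sort()

    if fmt == "bed":
        path = os.path.join(out_dir, "reads.bed")
        with open(path, "w") as fh:
            for i, (s, e, strand) in enumerate(records):
                fh.write(f"{CHROM}\t{s}\t{e}\tread{i}\t60\t{strand}\n")
        return
    path = os.path.join(out_dir, "reads.sam")
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": CHROM, "LN": c.genome_length}],
        }
    )
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for i, (s, e, strand) in enumerate(records):
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{i}"
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = 60
            a.cigarstring = f"{e - s}M"
            a.flag = 16 if strand == "-" else 0
            a.query_sequence = "A" * (e - s)
            fh.write(a)


def _emit_truth_tables(
    data: SimulatedData,
    rng: np.random.Generator,
    out_dir: str,
    index: CpGIndex,
) -> None:
    """Per-CpG bisulfite-like calls (both strands) and per-bin truth TSVs."""
    c = data.config
    pos = index.positions[CHROM]  # bin-ordered == simulation order
    depth_p = rng.poisson(c.truth_call_depth_mean, size=len(pos))
    depth_m = rng.poisson(c.truth_call_depth_mean, size=len(pos))
    with np.errstate(invalid="ignore"):
        frac_p = np.where(
            depth_p > 0,
            rng.binomial(np.maximum(depth_p, 1), data.cpg_meth_plus) /
            np.maximum(depth_p, 1),
            0.0,
        )
        frac_m = np.where(
            depth_m > 0,
            rng.binomial(np.maximum(depth_m, 1), data.cpg_meth_minus) /
            np.maximum(depth_m, 1),
            0.0,
        )
    calls = pd.DataFrame(
        {
            "chrom": CHROM,
            "pos": np.concatenate([pos, pos + 1]),
            "strand": ["+"] * len(pos) + ["-"] * len(pos),
            "fraction": np.concatenate([frac_p, frac_m]),
            "depth": np.concatenate([depth_p, depth_m]),
        }
    ).sort_values(["pos", "strand"], kind="mergesort", ignore_index=True)
    data.calls = calls
    out = calls.copy()
    out.insert(2, "end", out["pos"] + 1)
    out.to_csv(
        os.path.join(out_dir, "cpg_calls.bedgraph.tsv"),
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "pos", "end", "fraction", "depth", "strand"],
        float_format="%.6f",
    )

    bins = pd.DataFrame(
        {
            "bin": np.arange(c.n_bins),
            "start": np.arange(c.n_bins) * c.bin_size,
            "n_cpg": data.n_cpg,
            "meth_plus": data.bin_meth_plus,
            "meth_minus": data.bin_meth_minus,
            "meth_combined": data.bin_meth_combined,
            "expected_plus": data.expected_plus,
            "expected_minus": data.expected_minus,
            "reads_plus": data.counts.plus.astype(int),
            "reads_minus": data.counts.minus.astype(int),
        }
    )
    bins.to_csv(
        os.path.join(out_dir, "bin_truth.tsv"),
        sep="\t",
        index=False,
        float_format="%.6f",
    )
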