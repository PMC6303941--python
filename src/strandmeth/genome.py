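"""Reference-genome indexing: fixed-width bin tiling and CpG site scanning.

All coordinates are 0-based, half-open. Bins tile each chromosome as
``[k*bin_size, (k+1)*bin_size)``; the last bin of a chromosome may be short.
A CpG dinucleotide is located by the position of its C on the forward
reference strand, and a CpG straddling a bin boundary belongs to the bin
containing the C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)


class UnknownChromosomeError(KeyError):
    """A requested chromosome is absent from the reference or scheme."""


@dataclass(frozen=True)
class BinScheme:
    """Non-overlapping, exhaustive tiling of chromosomes into fixed-width bins.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bases. Insertion order defines
        the global bin order used by all vectorized per-bin arrays.
    bin_size
        Bin width in bases (>= 1).
    """

    chrom_lengths: dict[str, int]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        for name, length in self.chrom_lengths.items():
            if length < 0:
                raise ValueError(f"negative length for chromosome {name!r}")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    def n_bins(self, chrom: str) -> int:
        try:
            length = self.chrom_lengths[chrom]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None
        return -(-length // self.bin_size)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chromosomes)

    def offset(self, chrom: str) -> int:
        """Global index of the first bin of *chrom*."""
        off = 0
        for c in self.chromosomes:
            if c == chrom:
                return off
            off += self.n_bins(c)
        raise UnknownChromosomeError(chrom)

    def global_bin(self, chrom: str, pos: int) -> int:
        """Global bin index of base position *pos* on *chrom*."""
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offset(chrom) + pos // self.bin_size

    def bin_intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of the bins of *chrom*; last end is clipped."""
        n = self.n_bins(chrom)
        starts = np.arange(n, dtype=np.int64) * self.bin_size
        ends = np.minimum(starts + self.bin_size, self.chrom_lengths[chrom])
        return starts, ends

    def iter_bins(self) -> Iterable[tuple[str, int, int]]:
        for chrom in self.chromosomes:
            starts, ends = self.bin_intervals(chrom)
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e


@dataclass
class CpGIndex:
    """Sorted forward-strand C positions of CpG dinucleotides per chromosome."""

    positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(len(self.positions[chrom]))
        return int(sum(len(p) for p in self.positions.values()))

    def bin_scheme(self, bin_size: int) -> BinScheme:
        return BinScheme(dict(self.chrom_lengths), bin_size)


def scan_cpg_sites(
    fasta: str | Mapping[str, str],
    chromosomes: Sequence[str] | None = None,
) -> CpGIndex:
    """Locate every CpG dinucleotide on the forward reference strand.

    Matching is case-insensitive; dinucleotides containing ambiguous bases
    (e.g. N) never match. ``fasta`` may be a path to a FASTA file (a .fai
    index is created if absent) or an in-memory name -> sequence mapping.

    Returns a :class:`CpGIndex` with one sorted position array per requested
    chromosome. An empty sequence yields an empty array, not an error.
    """
    if isinstance(fasta, (str, bytes)):
        ref = Fasta(str(fasta), sequence_always_upper=False)
        names = list(ref.keys())
        get = lambda c: str(ref[c][:])  # noqa: E731
    else:
        names = list(fasta)
        get = lambda c: fasta[c]  # noqa: E731

    if chromosomes is None:
        chromosomes = names
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom in chromosomes:
        if chrom not in names:
            raise UnknownChromosomeError(chrom)
        seq = get(chrom)
        lengths[chrom] = len(seq)
        positions[chrom] = _find_cg(seq)
    return CpGIndex(positions=positions, chrom_lengths=lengths)


def _find_cg(seq: str) -> np.ndarray:
    if len(seq) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hits).astype(np.int64)


def bin_cpg_counts(cpg_index: CpGIndex, bin_scheme: BinScheme) -> np.ndarray:
    """Per-bin CpG counts (global vector in the scheme's bin order).

    A CpG whose C lies in bin b is counted in bin b even when its G falls in
    bin b+1.
    """
    counts = np.zeros(bin_scheme.total_bins, dtype=np.int64)
    for chrom in bin_scheme.chromosomes:
        if chrom not in cpg_index.positions:
            raise UnknownChromosomeError(chrom)
        pos = cpg_index.positions[chrom]
        n = bin_scheme.n_bins(chrom)
        off = bin_scheme.offset(chrom)
        if len(pos):
            counts[off : off + n] = np.bincount(
                pos // bin_scheme.bin_size, minlength=n
            )
    return counts


def write_cpg_bed(cpg_index: CpGIndex, path: str) -> None:
    """BED4 of CpG sites (C position, half-open)."""
    with open(path, "w") as fh:
        for chrom, pos in cpg_index.positions.items():
            for p in pos.tolist():
                fh.write(f"{chrom}\t{p}\t{p + 2}\tCpG\n")
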