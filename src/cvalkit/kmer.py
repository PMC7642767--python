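"""K-mer spectrum genome profiling.

A k-mer spectrum is the histogram N_d of how many distinct canonical
k-mers of the reads occur at each depth d.  For a diploid genome
sequenced to per-k-mer coverage lambda, homozygous single-copy k-mers
pile up at depth ~lambda, haplotype-specific (heterozygous) k-mers at
~lambda/2, repeats at multiples of lambda, and sequencing-error k-mers
at depth 1-2.  Genome size follows from the ratio

    genome size = total k-mer occurrences above the error cutoff
                  / homozygous peak depth

and repeat content / heterozygosity from how the occurrence mass splits
between the peaks.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import EstimationError, ValidationError
from .units import bp_to_pg

DEFAULT_K = 21
REPEAT_THRESHOLD_MULT = 1.5          # repeats live above 1.5x the 1x peak
HET_WINDOW = (0.35, 0.65)            # het mass window, in units of d_hom
HOM_WINDOW = (0.65, 1.5)             # hom mass window, in units of d_hom

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


@dataclass
class Spectrum:
    """Depth -> distinct-canonical-k-mer-count histogram for one k."""

    k: int
    counts: dict[int, int]
    provenance: str = ""

    def __post_init__(self):
        if self.k % 2 == 0 or self.k < 3:
            raise ValidationError("k: must be an odd integer >= 3")
        if any(d < 1 for d in self.counts):
            raise ValidationError("counts: depths must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("counts: counts must be >= 0")

    @property
    def max_depth(self) -> int:
        return max(self.counts, default=0)

    def dense(self) -> np.ndarray:
        """Counts as an array indexed by depth (index 0 unused)."""
        arr = np.zeros(self.max_depth + 1, dtype=float)
        for d, c in self.counts.items():
            arr[d] = c
        return arr

    def total_mass(self, cutoff: int = 1) -> float:
        """Total occurrence mass T(c) = sum_{d >= c} d * N_d."""
        return float(sum(d * c for d, c in self.counts.items() if d >= cutoff))

    def write(self, path) -> None:
        """Two-column whitespace text 'depth count', ascending depth."""
        with open(path, "w") as fh:
            for d in sorted(self.counts):
                fh.write(f"{d} {self.counts[d]}\n")

    @classmethod
    def read(cls, path, k: int = DEFAULT_K) -> "Spectrum":
        """Read a two-column 'depth count' histogram (k-mer-counter dialect)."""
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                d, c = line.split()[:2]
                counts[int(d)] = int(float(c))
        return cls(k=k, counts=counts, provenance=str(path))


@dataclass
class KmerEstimate:
    """Chained spectrum estimates for one sample."""

    k: int
    error_cutoff: int
    d_hom: float
    genome_size_bp: float
    genome_size_pg: float
    repeat_fraction: float
    heterozygosity: float


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValidationError("k: must be odd (even k admits palindromic k-mers)")
    if not (3 <= k <= 31):
        raise ValidationError("k: must satisfy 3 <= k <= 31 (64-bit packing)")


def count_kmers(seqs: Iterable[str], k: int = DEFAULT_K) -> Spectrum:
    """Count canonical k-mers across ``seqs`` and return their spectrum.

    A canonical k-mer is the lexicographic minimum of a window and its
    reverse complement; windows containing non-ACGT symbols are skipped.
    k is capped at 31 so each k-mer packs into a 64-bit integer code.
    """
    _validate_k(k)
    chunks = []
    for seq in seqs:
        chunks.append(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
        chunks.append(np.array([0], dtype=np.uint8))  # read separator
    if not chunks:
        return Spectrum(k=k, counts={}, provenance="empty input")
    arr = np.concatenate(chunks)
    codes = _CODE[arr]
    valid = codes != 255
    b = np.where(valid, codes, 0).astype(np.float64)
    if b.size < k:
        return Spectrum(k=k, counts={}, provenance="reads shorter than k")

    # rolling 2-bit packing via exact integer convolution in float64
    # (max value 4^31 - 1 < 2^62? no: k<=31 -> 4^31 = 2^62 exceeds float53.)
    # For k > 26 the code no longer fits float64 exactly, so fall back to
    # an int64 Horner scan in that regime.
    if k <= 26:
        w = (4.0 ** np.arange(k))
        fwd = np.convolve(b, w, mode="valid")
        rc = np.convolve(3.0 - b, w[::-1], mode="valid")
    else:
        bi = b.astype(np.int64)
        n_win = bi.size - k + 1
        fwd = np.zeros(n_win, dtype=np.int64)
        rc = np.zeros(n_win, dtype=np.int64)
        for j in range(k):
            fwd += bi[j:j + n_win] * (4 ** (k - 1 - j))
            rc += (3 - bi[j:j + n_win]) * (4 ** j)
    win_valid = np.convolve(valid.astype(np.int64), np.ones(k, np.int64),
                            mode="valid") == k
    canon = np.minimum(fwd, rc)[win_valid].astype(np.int64)
    if canon.size == 0:
        return Spectrum(k=k, counts={}, provenance="no valid windows")
    _, occ = np.unique(canon, return_counts=True)
    depths, n_distinct = np.unique(occ, return_counts=True)
    return Spectrum(k=k,
                    counts=dict(zip(depths.tolist(), n_distinct.tolist())),
                    provenance="counted in memory")


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path, fmt: Optional[str] = None) -> list[str]:
    """Load sequences from a FASTA/FASTQ file (optionally gzipped)."""
    from Bio import SeqIO

    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_maybe_gzip(path) as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]


def count_kmers_in_file(path, k: int = DEFAULT_K,
                        fmt: Optional[str] = None) -> Spectrum:
    spec = count_kmers(read_sequences(path, fmt=fmt), k=k)
    spec.provenance = str(path)
    return spec


def filter_reads(records, min_mean_quality: Optional[float] = 20.0,
                 drop_duplicate_pairs: bool = False):
    """Pre-filter (id, seq, qual) read tuples.

    Drops reads whose mean Phred quality falls below ``min_mean_quality``
    and, when requested, exact duplicate consecutive read pairs.
    """
    out = []
    seen = set()
    pending = None
    for rec in records:
        rid, seq, qual = rec
        if min_mean_quality is not None and qual:
            mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
            if mean_q < min_mean_quality:
                continue
        if not drop_duplicate_pairs:
            out.append(rec)
            continue
        if pending is None:
            pending = rec
            continue
        key = (pending[1], seq)
        if key not in seen:
            seen.add(key)
            out.extend([pending, rec])
        pending = None
    if drop_duplicate_pairs and pending is not None:
        out.append(pending)
    return out


# ---------------------------------------------------------------------------
# spectrum estimators
# ---------------------------------------------------------------------------

def error_cutoff(spec: Spectrum) -> int:
    """Depth separating error k-mers from genomic k-mers.

    Returns the first valley: the smallest d >= 2 with N_{d-1} > N_d and
    N_d <= N_{d+1}, provided some later depth rises above the valley
    (otherwise there is no genomic peak and the cutoff falls back to 1).
    """
    if not spec.counts:
        raise EstimationError("empty spectrum")
    arr = spec.dense()
    n = np.concatenate([arr, [0.0, 0.0]])  # depths beyond max are zero
    if len(n) < 4 or n[1] <= n[2]:
        return 1  # no initial descent: no error k-mers to cut away
    for d in range(2, len(n) - 1):
        if n[d - 1] > n[d] and n[d] <= n[d + 1]:
            if np.max(n[d + 1:], initial=0.0) > n[d]:
                return d
            warnings.warn("no genomic peak beyond the descending head "
                          "of the spectrum; error cutoff falls back to 1",
                          stacklevel=2)
            return 1
    return 1


def _refine_peak(arr: np.ndarray, d0: int, halfwidth: int = 3) -> float:
    """Parabolic refinement of the mode on log counts.

    A least-squares parabola over up to +-``halfwidth`` depths around the
    mode (all with positive counts) smooths Poisson counting noise; with
    fewer than three usable points the integer mode is returned.
    """
    lo = max(d0 - halfwidth, 1)
    hi = min(d0 + halfwidth, len(arr) - 1)
    ds = np.arange(lo, hi + 1)
    ys = arr[lo:hi + 1]
    mask = ys > 0
    if mask.sum() < 3 or arr[d0] <= 0:
        return float(d0)
    coeffs = np.polyfit(ds[mask].astype(float), np.log(ys[mask]), 2)
    if coeffs[0] >= 0:
        return float(d0)
    vertex = -coeffs[1] / (2.0 * coeffs[0])
    if not (lo - 1 <= vertex <= hi + 1):
        return float(d0)
    return float(vertex)


def genome_size(spec: Spectrum, cutoff: int) -> tuple[float, float]:
    """Homozygous peak depth and genome size from a spectrum.

    d_hom is the modal depth at or above the cutoff (ties break to the
    smaller depth), refined by parabolic interpolation on log counts;
    genome size = T(cutoff) / d_hom with T the occurrence mass.
    """
    arr = spec.dense()
    if cutoff >= len(arr) or not np.any(arr[cutoff:] > 0):
        raise EstimationError(f"no k-mers at or above depth {cutoff}")
    d0 = cutoff + int(np.argmax(arr[cutoff:]))
    d_hom = _refine_peak(arr, d0)
    d_hom = max(d_hom, float(cutoff))
    total = spec.total_mass(cutoff)
    return d_hom, total / d_hom


def repeat_fraction(spec: Spectrum, cutoff: int, d_hom: float,
                    mult: float = REPEAT_THRESHOLD_MULT) -> float:
    """Share of occurrence mass at depths above ``mult * d_hom``.

    mult = 1.5 puts the threshold midway between the single-copy and
    two-copy peaks.
    """
    total = spec.total_mass(cutoff)
    if total == 0:
        return 0.0
    threshold = mult * d_hom
    above = sum(d * c for d, c in spec.counts.items()
                if d >= cutoff and d > threshold)
    return above / total


def _poisson_mass_capture(mu: float, lo: float, hi: float) -> float:
    """Fraction of a Poisson(mu) component's occurrence mass (sum of
    d * pmf) falling at integer depths in [lo, hi]."""
    from scipy.stats import poisson

    d_lo, d_hi = math.ceil(lo), math.floor(hi)
    if d_hi < d_lo:
        return 0.0
    ds = np.arange(max(d_lo, 0), d_hi + 1)
    return float(np.sum(ds * poisson.pmf(ds, mu)) / mu)


def heterozygosity(spec: Spectrum, cutoff: int, d_hom: float, k: int,
                   depth_correction: bool = True) -> float:
    """Per-site heterozygosity from the half-depth peak.

    The occurrence mass in the het window [0.35, 0.65) * d_hom relative
    to the het + hom mass gives the fraction f of single-copy k-mers
    that are haplotype-specific; a k-mer spans k sites, so
    h = 1 - (1 - f)^(1/k).

    With ``depth_correction`` (default) the two window masses are
    unmixed against the Poisson depth spread of both components (means
    d_hom/2 and d_hom): each window captures only part of its own
    component's mass and some of the other's tail, so the observed
    masses are a known 2x2 linear mix of the true component masses.
    Without it f is the raw window-mass ratio.
    """
    if d_hom < 4:
        raise EstimationError(
            f"homozygous peak depth {d_hom:.2f} < 4: het peak unresolvable")
    het_win = (HET_WINDOW[0] * d_hom, HET_WINDOW[1] * d_hom - 1e-9)
    hom_win = (HOM_WINDOW[0] * d_hom, HOM_WINDOW[1] * d_hom)
    m_het = sum(d * c for d, c in spec.counts.items()
                if d >= cutoff and het_win[0] <= d <= het_win[1])
    m_hom = sum(d * c for d, c in spec.counts.items()
                if d >= cutoff and hom_win[0] <= d <= hom_win[1])
    if m_het + m_hom == 0:
        raise EstimationError("no occurrence mass in the het/hom windows")
    if depth_correction:
        mu_het, mu_hom = d_hom / 2.0, d_hom
        mix = np.array([
            [_poisson_mass_capture(mu_het, *het_win),
             _poisson_mass_capture(mu_hom, *het_win)],
            [_poisson_mass_capture(mu_het, *hom_win),
             _poisson_mass_capture(mu_hom, *hom_win)],
        ])
        if abs(np.linalg.det(mix)) > 1e-6:
            a, b = np.linalg.solve(mix, [m_het, m_hom])
            m_het, m_hom = max(a, 0.0), max(b, 0.0)
            if m_het + m_hom == 0:
                return 0.0
    f = m_het / (m_het + m_hom)
    return 1.0 - (1.0 - f) ** (1.0 / k)


def kmer_report(spec: Spectrum, k: Optional[int] = None) -> KmerEstimate:
    """Chain cutoff -> peak -> genome size -> repeat -> heterozygosity."""
    k = spec.k if k is None else k
    c = error_cutoff(spec)
    d_hom, size_bp = genome_size(spec, c)
    rep = repeat_fraction(spec, c, d_hom)
    try:
        het = heterozygosity(spec, c, d_hom, k)
    except EstimationError:
        het = float("nan")
    return KmerEstimate(k=k, error_cutoff=c, d_hom=d_hom,
                        genome_size_bp=size_bp,
                        genome_size_pg=bp_to_pg(size_bp),
                        repeat_fraction=rep, heterozygosity=het)


def method_difference(fcm_pg: float, kmer_pg: float) -> float:
    """Flow-cytometry minus k-mer C-value, pg (2 decimals)."""
    return round(fcm_pg - kmer_pg, 2)
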