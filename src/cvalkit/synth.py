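"""Synthetic data generators with known ground truth.

Every downstream stage of the toolkit is testable without instrument or
sequencing data: this module simulates

* flow-cytometry event tables — co-prepared sample + internal standard
  with Gaussian 2C/4C peaks of stated CV and an exponential debris tail,
* diploid k-mer depth spectra and read sets with error, heterozygous,
  homozygous and repeat components,
* pure-birth (Yule) trees and Brownian-motion tip traits with a known
  Pagel's lambda.

All generators are deterministic given the seed carried in their config;
seeds are explicit fields, never global state.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
from dendropy.simulate import treesim
from scipy.stats import norm

from .errors import ValidationError
from .fcm import EventTable
from .kmer import Spectrum

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class FcmSimConfig:
    """Ground truth for one simulated co-preparation run.

    Defaults emulate a routine acquisition: a large-genome sample run
    against the Locusta migratoria male standard (1C = 6.20 pg), 20,000
    ungated events, 2% CV on both 2C peaks, 5% debris and 10% of each
    population's nuclei at 4C.
    """

    true_1c: float = 9.64            # pg
    standard_name: str = "Locusta migratoria"
    standard_1c: float = 6.20        # pg
    gain: float = 10.0               # fluorescence units per pg
    cv_sample: float = 2.0           # percent
    cv_standard: float = 2.0         # percent
    n_events: int = 20000
    debris_fraction: float = 0.05
    tetraploid_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        _require(self.n_events >= 1, "n_events: must be >= 1")
        _require(self.true_1c > 0, "true_1c: must be > 0")
        _require(self.standard_1c > 0, "standard_1c: must be > 0")
        _require(self.gain > 0, "gain: must be > 0")
        _require(self.cv_sample >= 0, "cv_sample: must be >= 0")
        _require(self.cv_standard >= 0, "cv_standard: must be >= 0")
        _require(0 <= self.debris_fraction < 1, "debris_fraction: must be in [0,1)")
        _require(0 <= self.tetraploid_fraction < 1,
                 "tetraploid_fraction: must be in [0,1)")
        _require(self.debris_fraction + self.tetraploid_fraction < 1,
                 "debris_fraction: debris + tetraploid fractions must be < 1")


@dataclass
class KmerSimConfig:
    """Ground truth for a diploid k-mer spectrum / read set.

    ``coverage`` is the total (diploid-summed) sequencing depth, so a
    homozygous k-mer is expected at depth

        lambda_k = coverage * (read_length - k + 1) / read_length

    and a haplotype-specific (heterozygous) k-mer at lambda_k / 2.
    ``repeat_fraction`` is the share of genome length made of a segment
    present ``repeat_multiplicity`` times.
    """

    genome_length: int = 200_000     # bp
    coverage: float = 30.0           # fold
    k: int = 21
    heterozygosity: float = 0.005    # per-site
    repeat_fraction: float = 0.3
    repeat_multiplicity: int = 2
    error_rate: float = 0.001        # per base
    read_length: int = 150
    noise: bool = False              # Poisson-sample the expected spectrum
    seed: int = 0

    def __post_init__(self):
        _require(self.k >= 3 and self.k % 2 == 1,
                 "k: must be an odd integer >= 3 (even k admits palindromes)")
        _require(self.read_length > self.k, "read_length: must exceed k")
        _require(self.genome_length >= 1, "genome_length: must be >= 1")
        _require(self.coverage > 0, "coverage: must be > 0")
        _require(0 <= self.heterozygosity < 1, "heterozygosity: must be in [0,1)")
        _require(0 <= self.repeat_fraction < 1, "repeat_fraction: must be in [0,1)")
        _require(self.repeat_multiplicity >= 2,
                 "repeat_multiplicity: must be an integer >= 2")
        _require(0 <= self.error_rate < 1, "error_rate: must be in [0,1)")

    @property
    def lambda_k(self) -> float:
        """Expected depth of a homozygous k-mer."""
        return self.coverage * (self.read_length - self.k + 1) / self.read_length


@dataclass
class TreeSimConfig:
    n_tips: int = 19
    birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(self.n_tips >= 2, "n_tips: must be >= 2")
        _require(self.birth_rate > 0, "birth_rate: must be > 0")


@dataclass
class BmParams:
    """Brownian-motion trait model: tip values are multivariate normal
    with mean ``root_state`` and covariance sigma2 * C(lambda_true),
    where C is the shared-path-length matrix and lambda scales its
    off-diagonal entries."""

    sigma2: float = 1.0
    root_state: float = 10.0         # pg, a typical Caelifera 1C value
    lambda_true: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(self.sigma2 >= 0, "sigma2: must be >= 0")
        _require(0 <= self.lambda_true <= 1, "lambda_true: must be in [0,1]")


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

def simulate_fcm_events(cfg: FcmSimConfig, replicate_id: str = "sim",
                        species: str = "synthetic", sex: str = "F") -> EventTable:
    """Simulate ungated event-level fluorescence for one co-preparation.

    Sample 2C events are drawn around 2 * true_1c * gain with relative
    spread cv_sample/100 (standard likewise); 4C events sit at twice the
    2C centers; debris decays exponentially below the lowest 2C center.
    The returned table records per-event population truth and the config
    for test assertions only.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_events
    n_debris = int(round(cfg.debris_fraction * n))
    n_rest = n - n_debris
    n_sample = n_rest - n_rest // 2
    n_standard = n_rest // 2

    sample_2c = 2.0 * cfg.true_1c * cfg.gain
    standard_2c = 2.0 * cfg.standard_1c * cfg.gain

    def population(n_pop: int, center: float, cv: float) -> np.ndarray:
        n4 = int(round(cfg.tetraploid_fraction * n_pop))
        n2 = n_pop - n4
        sd2 = cv / 100.0 * center
        sd4 = cv / 100.0 * 2.0 * center
        g1 = rng.normal(center, sd2, size=n2) if n2 else np.empty(0)
        g2 = rng.normal(2.0 * center, sd4, size=n4) if n4 else np.empty(0)
        return np.concatenate([g1, g2])

    ev_sample = population(n_sample, sample_2c, cfg.cv_sample)
    ev_standard = population(n_standard, standard_2c, cfg.cv_standard)

    # debris: truncated exponential over (0, lowest 2C center)
    low = min(sample_2c, standard_2c)
    scale = low / 4.0
    u = rng.random(n_debris)
    ev_debris = -scale * np.log1p(-u * (1.0 - math.exp(-low / scale)))

    events = np.concatenate([ev_sample, ev_standard, ev_debris])
    events = np.clip(events, 0.0, None)
    truth = np.concatenate([
        np.full(ev_sample.size, "sample", dtype=object),
        np.full(ev_standard.size, "standard", dtype=object),
        np.full(ev_debris.size, "debris", dtype=object),
    ])
    return EventTable(
        replicate_id=replicate_id, species=species, sex=sex,
        standard_name=cfg.standard_name, standard_1c=cfg.standard_1c,
        events=events, population_truth=truth,
        truth={"config": cfg, "sample_2c": sample_2c, "standard_2c": standard_2c},
    )


# ---------------------------------------------------------------------------
# k-mer spectra and reads
# ---------------------------------------------------------------------------

def _discrete_normal_mass(depths: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Probability mass of a rounded Normal(mean, sd^2) at integer depths."""
    if sd == 0:
        out = np.zeros(depths.size)
        out[np.argmin(np.abs(depths - mean))] = 1.0
        return out
    return norm.cdf((depths + 0.5 - mean) / sd) - norm.cdf((depths - 0.5 - mean) / sd)


def simulate_kmer_spectrum(cfg: KmerSimConfig) -> Spectrum:
    """Expected (or Poisson-sampled) diploid k-mer depth spectrum.

    Mixture components, each a discretized Gaussian over depth with
    variance equal to its mean (Poisson-like spread):

    * homozygous single-copy k-mers at lambda_k,
    * heterozygous k-mers at lambda_k/2 carrying an occurrence-mass
      fraction 1 - (1 - h)^k of the single-copy mass,
    * repeat k-mers at repeat_multiplicity * lambda_k carrying
      repeat_fraction of the genomic mass,
    * error k-mers, geometric over depth starting at 1.

    Total genomic occurrence mass is genome_length * lambda_k.  With the
    ``noise`` flag set, each depth count is Poisson-sampled.
    """
    lam = cfg.lambda_k
    if lam < 4:
        warnings.warn(
            f"per-k-mer coverage lambda_k = {lam:.2f} < 4: spectrum peaks "
            "will not be resolvable", stacklevel=2)

    mass_total = cfg.genome_length * lam
    f_het = 1.0 - (1.0 - cfg.heterozygosity) ** cfg.k
    components = []  # (distinct k-mers, mean depth)
    mu_rep = cfg.repeat_multiplicity * lam
    if cfg.repeat_fraction > 0:
        components.append((cfg.repeat_fraction * mass_total / mu_rep, mu_rep))
    mass_sc = (1.0 - cfg.repeat_fraction) * mass_total
    if f_het > 0:
        components.append((f_het * mass_sc / (lam / 2.0), lam / 2.0))
    components.append(((1.0 - f_het) * mass_sc / lam, lam))

    max_depth = int(math.ceil(mu_rep + 8.0 * math.sqrt(mu_rep))) + 2
    depths = np.arange(1, max_depth + 1)
    expected = np.zeros(depths.size)
    for n_distinct, mu in components:
        expected += n_distinct * _discrete_normal_mass(depths, mu, math.sqrt(mu))

    if cfg.error_rate > 0:
        # each sequencing error spawns ~k novel k-mers, mostly depth 1-2
        n_err = cfg.genome_length * cfg.coverage * cfg.error_rate * cfg.k
        p = 0.8
        expected += n_err * p * (1.0 - p) ** (depths - 1)

    if cfg.noise:
        rng = np.random.default_rng(cfg.seed)
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)
    nz = counts > 0
    return Spectrum(k=cfg.k,
                    counts=dict(zip(depths[nz].tolist(), counts[nz].tolist())),
                    provenance="simulated expected spectrum"
                               + (" (Poisson noise)" if cfg.noise else ""))


_READ_SIZE_CAP = 10_000_000


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def simulate_genome(cfg: KmerSimConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Build the two haplotypes as uint8 base-code arrays (0..3).

    Haplotype A = unique sequence followed by repeat_multiplicity copies
    of one repeat unit, total length genome_length.  Haplotype B carries
    independent per-site substitutions at rate ``heterozygosity``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    g = cfg.genome_length
    unit_len = int(round(cfg.repeat_fraction * g / cfg.repeat_multiplicity))
    unique_len = g - unit_len * cfg.repeat_multiplicity
    unit = _random_seq(rng, unit_len)
    hap_a = np.concatenate([_random_seq(rng, unique_len)]
                           + [unit] * cfg.repeat_multiplicity)
    hap_b = hap_a.copy()
    if cfg.heterozygosity > 0:
        mask = rng.random(g) < cfg.heterozygosity
        n_mut = int(mask.sum())
        hap_b[mask] = (hap_b[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
    return hap_a, hap_b


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_reads(cfg: KmerSimConfig):
    """Simulate a diploid read set; returns (reads, haplotypes).

    ``reads`` is a list of (read_id, sequence, quality) tuples;
    ``haplotypes`` maps hap name -> sequence string.  Reads are sampled
    uniformly from both haplotypes (balanced halves, random strand) to a
    total of ceil(genome_length * coverage / read_length) reads, with
    independent per-base substitution errors at ``error_rate``.
    """
    if cfg.genome_length > _READ_SIZE_CAP:
        raise ValidationError(
            f"genome_length: read simulation capped at {_READ_SIZE_CAP} bp")
    rng = np.random.default_rng(cfg.seed)
    hap_a, hap_b = simulate_genome(cfg, rng)
    g, L = cfg.genome_length, cfg.read_length
    n_reads = math.ceil(g * cfg.coverage / L)
    n_a = n_reads - n_reads // 2

    reads = []
    qual = "I" * L
    for hap_name, hap, n_hap in (("hap_a", hap_a, n_a),
                                 ("hap_b", hap_b, n_reads - n_a)):
        if n_hap == 0:
            continue
        starts = rng.integers(0, g - L + 1, size=n_hap)
        windows = hap[starts[:, None] + np.arange(L)]
        if cfg.error_rate > 0:
            err = rng.random(windows.shape) < cfg.error_rate
            n_err = int(err.sum())
            windows[err] = (windows[err]
                            + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
        flip = rng.random(n_hap) < 0.5
        windows[flip] = (3 - windows[flip])[:, ::-1]  # reverse complement
        for i in range(n_hap):
            reads.append((f"{hap_name}_read{i}", _codes_to_str(windows[i]), qual))
    haplotypes = {"hap_a": _codes_to_str(hap_a), "hap_b": _codes_to_str(hap_b)}
    return reads, haplotypes


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def simulate_yule_tree(cfg: TreeSimConfig) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_tips`` leaves.

    The birth process stops at the final speciation event, which would
    leave two zero-length tip branches; every tip edge is therefore
    extended by one further exponential waiting time, keeping the tree
    ultrametric with strictly positive branch lengths.
    """
    rng = random.Random(cfg.seed)
    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=0.0,
        num_extant_tips=cfg.n_tips, rng=rng)
    extra = rng.expovariate(cfg.birth_rate * cfg.n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return tree


def simulate_bm_trait(tree: dendropy.Tree, params: BmParams) -> dict[str, float]:
    """Draw one Brownian-motion trait vector on the tips of ``tree``.

    Tip values ~ MVN(root_state * 1, sigma2 * C(lambda_true)) with C the
    shared-path-length matrix; lambda scales off-diagonal covariances.
    Returns a species -> value mapping.
    """
    from .comparative import lambda_transform, vcv  # local import, avoids cycle

    C, labels = vcv(tree)
    if params.sigma2 == 0:
        return {lab: params.root_state for lab in labels}
    cov = params.sigma2 * lambda_transform(C, params.lambda_true)
    rng = np.random.default_rng(params.seed)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    x = params.root_state + chol @ rng.standard_normal(len(labels))
    return dict(zip(labels, x.tolist()))


def write_trait_csv(traits: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("species,value\n")
        for sp, v in traits.items():
            fh.write(f"{sp},{v}\n")
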