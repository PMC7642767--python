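"""Internal-standard registry, suitability ranges, and group statistics.

An internal standard is a co-prepared reference organism of known 1C
content.  A standard can only calibrate samples whose genome is neither
far smaller nor far larger than its own: the packaged rule brackets each
standard's measurable range as a fixed ratio band around its 1C value.
The default bounds (0.33, 3.30) are calibrated so that the Locusta
migratoria male standard (1C = 6.20 pg) covers 2-20 Gb, the span over
which it resolves large insect genomes in practice.

The module also provides the classical group comparisons used on
replicate estimates: one-way ANOVA with Tukey's HSD across standards,
and Student's t between sexes or methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, ValidationError
from .units import pg_to_mb

DEFAULT_RATIO_LO = 0.33
DEFAULT_RATIO_HI = 3.30
DEFAULT_MIN_SEPARATION = 3.0   # multiples of combined peak sd
DEFAULT_NOMINAL_CV = 3.0       # percent, for peak-overlap checks


@dataclass(frozen=True)
class StandardSpec:
    """A reference organism of known haploid DNA content."""

    name: str
    sex: str
    one_c: float  # pg

    def __post_init__(self):
        if self.one_c <= 0:
            raise ValidationError("one_c: must be > 0")


@dataclass(frozen=True)
class SuitabilityRule:
    """Ratio band defining a standard's measurable genome-size range."""

    ratio_lo: float = DEFAULT_RATIO_LO
    ratio_hi: float = DEFAULT_RATIO_HI
    min_separation: float = DEFAULT_MIN_SEPARATION

    def __post_init__(self):
        if not (0 < self.ratio_lo <= 1 <= self.ratio_hi):
            raise ValidationError("SuitabilityRule: need 0 < ratio_lo <= 1 <= ratio_hi")


@dataclass
class GroupData:
    """A labelled set of replicate values (pg)."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValidationError(f"group {self.label!r}: needs >= 1 value")


@dataclass
class TukeyPair:
    label_a: str
    label_b: str
    mean_diff: float
    q: float
    p_value: float
    significant: bool


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    tukey_table: Optional[list[TukeyPair]] = None


@dataclass
class Recommendation:
    standard: StandardSpec
    lo_mb: float
    hi_mb: float
    log_distance: float
    overlap: bool
    note: str = ""


@dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    low_confidence: bool = False  # a group had n = 1 (pooled from the other)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def load_registry(path=None) -> list[StandardSpec]:
    """Load the standard registry (packaged CSV by default).

    The packaged registry carries the four standards used for large
    insect genomes: Periplaneta americana (3.41 pg), Locusta migratoria
    (6.20 pg), Gallus domesticus (1.165 pg), Mus musculus (3.30 pg),
    all males.
    """
    if path is None:
        source = resources.files("cvalkit.data").joinpath("standards.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [StandardSpec(name=row["name"], sex=row["sex"],
                         one_c=float(row["one_c_pg"]))
            for _, row in df.iterrows()]


def suitability_range(std: StandardSpec,
                      rule: SuitabilityRule = SuitabilityRule()
                      ) -> tuple[float, float]:
    """Measurable genome-size range (Mb) for one internal standard."""
    return (rule.ratio_lo * pg_to_mb(std.one_c),
            rule.ratio_hi * pg_to_mb(std.one_c))


def select_standards(target_pg: float,
                     registry: Optional[Sequence[StandardSpec]] = None,
                     rule: SuitabilityRule = SuitabilityRule(),
                     nominal_cv: float = DEFAULT_NOMINAL_CV
                     ) -> list[Recommendation]:
    """Rank internal standards for a target genome of ``target_pg`` pg.

    Standards whose range covers the target are ranked by log-1C
    proximity.  A standard whose 2C peak would sit within
    ``rule.min_separation`` combined standard deviations of the sample's
    (at a nominal CV) is flagged as overlapping, with advice to use an
    alternative.  Returns an empty list (with a warning diagnostic) when
    no standard covers the target.
    """
    if target_pg <= 0:
        raise ValidationError("target_pg: must be > 0")
    if registry is None:
        registry = load_registry()
    target_mb = pg_to_mb(target_pg)
    recs = []
    for std in registry:
        lo, hi = suitability_range(std, rule)
        if not (lo <= target_mb <= hi):
            continue
        # peak positions are proportional to 2 * 1C; compare in pg units
        sd_sample = nominal_cv / 100.0 * 2.0 * target_pg
        sd_std = nominal_cv / 100.0 * 2.0 * std.one_c
        separation = abs(2.0 * target_pg - 2.0 * std.one_c)
        overlap = separation < rule.min_separation * math.hypot(sd_sample, sd_std)
        recs.append(Recommendation(
            standard=std, lo_mb=lo, hi_mb=hi,
            log_distance=abs(math.log(target_pg / std.one_c)),
            overlap=overlap,
            note="overlap — use alternative" if overlap else ""))
    if not recs:
        warnings.warn(f"no suitable standard for a {target_pg} pg genome "
                      "in the registry", stacklevel=2)
        return []
    recs.sort(key=lambda r: r.log_distance)
    return recs


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _check_groups(groups: Sequence[GroupData]) -> None:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValidationError(f"group {g.label!r}: needs >= 2 values")


def one_way_anova(groups: Sequence[GroupData]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within from the sum-of-squares decomposition;
    the p-value comes from the F(k-1, N-k) distribution.
    """
    _check_groups(groups)
    all_values = np.concatenate([g.values for g in groups])
    grand = all_values.mean()
    n_total = all_values.size
    k = len(groups)
    ss_between = sum(g.values.size * (g.values.mean() - grand) ** 2
                     for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise DegenerateVarianceError("zero within-group variance")
    f = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(f_stat=float(f), df_between=df_between,
                       df_within=df_within, p_value=p, ms_within=ms_within)


def tukey_q(groups: Sequence[GroupData]
            ) -> list[tuple[str, str, float, float]]:
    """Pairwise Tukey q statistics (no p-values).

    q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j));
    returns (label_a, label_b, mean_diff, q) per pair.  Compare q against
    a studentized-range critical value at (k, df_within).
    """
    anova = one_way_anova(groups)
    msw = anova.ms_within
    pairs = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            ga, gb = groups[a], groups[b]
            diff = float(ga.values.mean() - gb.values.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / ga.values.size + 1.0 / gb.values.size))
            pairs.append((ga.label, gb.label, diff, abs(diff) / se))
    return pairs


def tukey_hsd(groups: Sequence[GroupData], alpha: float = 0.05
              ) -> list[TukeyPair]:
    """Tukey's honestly-significant-difference pairwise comparisons.

    q statistics from :func:`tukey_q`, with p-values from the
    studentized-range distribution at (k, df_within).
    """
    anova = one_way_anova(groups)
    k, dfw = len(groups), anova.df_within
    pairs = []
    for label_a, label_b, diff, q in tukey_q(groups):
        p = float(stats.studentized_range.sf(q, k, dfw))
        pairs.append(TukeyPair(label_a=label_a, label_b=label_b,
                               mean_diff=diff, q=q, p_value=p,
                               significant=p < alpha))
    return pairs


def students_t(a: GroupData, b: GroupData, welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled variance by default (Welch behind a flag).

    A group of n = 1 is allowed against a companion group of n >= 2: the
    pooled variance then comes entirely from the larger group and the
    result is flagged low-confidence.
    """
    na, nb = a.values.size, b.values.size
    if na + nb < 3 or min(na, nb) < 1 or max(na, nb) < 2:
        raise ValidationError("t-test needs n_a + n_b >= 3 with one group >= 2")
    mean_a, mean_b = a.values.mean(), b.values.mean()
    if welch:
        if min(na, nb) < 2:
            raise ValidationError("Welch t-test needs both groups >= 2")
        va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
        if va + vb == 0:
            raise DegenerateVarianceError("zero variance in both groups")
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (mean_a - mean_b) / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
        return TTestResult(t=float(t), df=int(df), p_value=p)
    ssa = ((a.values - mean_a) ** 2).sum() if na > 1 else 0.0
    ssb = ((b.values - mean_b) ** 2).sum() if nb > 1 else 0.0
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    if s2 == 0:
        raise DegenerateVarianceError("zero pooled variance")
    t = (mean_a - mean_b) / math.sqrt(s2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p_value=p,
                       low_confidence=min(na, nb) == 1)


def compare_standards(estimates: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-species ANOVA + Tukey across internal standards.

    ``estimates`` needs columns species, standard, one_c_pg.  Species
    with fewer than two standards (or fewer than two replicates per
    standard) are skipped with a warning.
    """
    out = {}
    for species, sub in estimates.groupby("species"):
        groups = [GroupData(label=str(std), values=vals["one_c_pg"].to_numpy())
                  for std, vals in sub.groupby("standard")
                  if len(vals) >= 2]
        if len(groups) < 2:
            warnings.warn(f"{species}: fewer than two standards with "
                          "replicates; skipped", stacklevel=2)
            continue
        anova = one_way_anova(groups)
        anova.tukey_table = tukey_hsd(groups, alpha=alpha)
        out[species] = anova
    return out
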