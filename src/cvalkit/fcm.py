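"""Flow-cytometry genome-size estimation.

Nuclei stained with a DNA-intercalating dye fluoresce in proportion to
their DNA content, so a co-prepared internal standard of known 1C value
calibrates the fluorescence axis.  The genome size of the sample follows
from the ratio of the fitted 2C (G1 diploid) peak positions:

    sample 1C = standard 1C * (sample 2C position / standard 2C position)

This module turns event-level fluorescence into QC-passed per-replicate
estimates and aggregates replicates into per species-and-sex summaries
(mean 1C in pg, Mb equivalent via 1 pg = 978 Mb, SE, n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import (
    AmbiguityError,
    ClassificationError,
    EmptyInputError,
    NoPeakError,
    ValidationError,
)
from .units import MB_PER_PG, pg_to_mb

DEFAULT_N_CHANNELS = 1024
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_PEAK_FRACTION = 0.005  # min peak area, as a fraction of events
DEFAULT_CV_MAX = 5.0  # percent; QC requires CV strictly below this


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-replicate fluorescence events with sample/standard metadata.

    ``population_truth`` (sample|standard|debris per event) is only ever
    populated by the simulator for test assertions; estimators must not
    read it.
    """

    replicate_id: str
    species: str
    sex: str
    standard_name: str
    standard_1c: float
    events: np.ndarray
    population_truth: Optional[np.ndarray] = None
    truth: Optional[dict] = None  # simulator ground truth, tests only

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size < 1:
            raise ValidationError("events: at least one event required")
        if not np.all(np.isfinite(self.events)):
            raise ValidationError("events: all fluorescence values must be finite")
        if np.any(self.events < 0):
            raise ValidationError("events: fluorescence values must be >= 0")
        if self.standard_1c <= 0:
            raise ValidationError("standard_1c: must be > 0")

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass
class Histogram:
    """Binned fluorescence: equal-width channels spanning [0, max event]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValidationError("bin_edges: must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return int(self.counts.size)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class Peak:
    """A fitted fluorescence peak (Gaussian mean/sd over one mode)."""

    position: float
    sd: float
    area: float
    ploidy_label: str = "2C"  # 2C | 4C
    source: str = "unknown"   # sample | standard | unknown

    def __post_init__(self):
        if self.position <= 0:
            raise ValidationError("position: must be > 0")
        if self.sd < 0:
            raise ValidationError("sd: must be >= 0")

    @property
    def cv(self) -> float:
        """Coefficient of variation, percent (100 * sd / position)."""
        return 100.0 * self.sd / self.position


@dataclass
class PeakAssignment:
    """Result of resolving which peak is sample vs standard 2C."""

    sample: Peak
    standard: Peak
    tetraploid: list
    peaks: list


@dataclass
class RatioEstimate:
    """One replicate's genome-size estimate from the 2C peak-position ratio."""

    one_c: float
    sample_peak: Peak
    standard_peak: Peak
    qc_pass: bool
    replicate_id: str = ""
    species: Optional[str] = None
    sex: Optional[str] = None
    standard_name: Optional[str] = None

    def __post_init__(self):
        if self.one_c <= 0:
            raise ValidationError("one_c: must be > 0")

    @property
    def genome_mb(self) -> float:
        return self.one_c * MB_PER_PG


@dataclass
class SpeciesSummary:
    """One reporting row: per species-and-sex mean 1C (pg), Mb, SE, n.

    Rounding happens only here: pg at 2 decimals, Mb at integers; the Mb
    value is converted from the unrounded pg mean.  SE is omitted (None)
    for n = 1.
    """

    species: str
    sex: str
    mean_1c: float
    genome_mb: int
    se_mb: Optional[int]
    n: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_histogram(events: EventTable | np.ndarray,
                    n_channels: int = DEFAULT_N_CHANNELS) -> Histogram:
    """Bin events into ``n_channels`` equal-width channels over [0, max]."""
    values = events.events if isinstance(events, EventTable) else np.asarray(events, float)
    if values.size == 0:
        raise EmptyInputError("no events to bin")
    if n_channels < 64:
        raise ValidationError("n_channels: must be >= 64")
    top = float(values.max())
    if top <= 0:
        top = 1.0
    counts, edges = np.histogram(values, bins=n_channels, range=(0.0, top))
    return Histogram(bin_edges=edges, counts=counts.astype(float))


def _gaussian(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _fit_window(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Gaussian mean/sd over one histogram window; moment fallback."""
    total = counts.sum()
    mu0 = float((centers * counts).sum() / total)
    var0 = float(((centers - mu0) ** 2 * counts).sum() / total)
    sd0 = math.sqrt(max(var0, 0.0))
    nonzero = int((counts > 0).sum())
    if nonzero <= 2 or sd0 == 0.0:
        return mu0, sd0
    try:
        popt, _ = curve_fit(
            _gaussian, centers, counts,
            p0=(float(counts.max()), mu0, sd0),
            maxfev=5000,
        )
        _, mu, sd = popt
        sd = abs(float(sd))
        lo, hi = centers[0], centers[-1]
        if not (lo <= mu <= hi) or not np.isfinite(mu):
            return mu0, sd0
        return float(mu), sd
    except RuntimeError:
        return mu0, sd0


def detect_and_fit_peaks(hist: Histogram,
                         min_peak_events: Optional[float] = None,
                         smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> list[Peak]:
    """Locate and fit fluorescence peaks in a histogram.

    The counts are smoothed with a moving average, local maxima are
    found, each candidate's window is expanded to the valley floor on
    both sides, and a Gaussian is fitted to the raw counts inside the
    window.  Candidates whose event count (area) falls below
    ``min_peak_events`` (default 0.5% of all events) are discarded.
    """
    counts = hist.counts
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("histogram holds no events")
    if min_peak_events is None:
        min_peak_events = DEFAULT_MIN_PEAK_FRACTION * total

    w = max(1, int(smooth_window))
    kernel = np.ones(w)
    # normalize by the actual in-range window size so the edges are not
    # biased low (a fake head rise would masquerade as a peak)
    coverage = np.convolve(np.ones_like(counts), kernel, mode="same")
    smoothed = np.convolve(counts, kernel, mode="same") / coverage

    # prominence filtering suppresses counting-noise wiggles riding on
    # broad peaks and on the debris tail; a wiggle's prominence scales
    # like sqrt(height) (Poisson counting noise), a real peak's like its
    # full height
    idx, props = find_peaks(smoothed, prominence=1e-9)
    keep = props["prominences"] >= np.maximum(0.05 * smoothed.max(),
                                              4.0 * np.sqrt(smoothed[idx]))
    idx = idx[keep]
    centers = hist.centers
    peaks: list[Peak] = []
    for pos_in_list, i in enumerate(idx):
        height = smoothed[i]
        # half-height crossings give a width estimate; the fit window is
        # symmetric around the mode, clipped at neighbouring peaks
        left = i
        while left > 0 and smoothed[left - 1] > height / 2:
            left -= 1
        right = i
        while right < len(smoothed) - 1 and smoothed[right + 1] > height / 2:
            right += 1
        half_width = max(right - i, i - left, 1)
        sigma0 = max(half_width / 1.177, 1.0)  # FWHM/2 = 1.177 sigma
        lo = int(max(i - 3 * sigma0, 0))
        hi = int(min(i + 3 * sigma0, len(smoothed) - 1))
        if pos_in_list > 0:
            lo = max(lo, (idx[pos_in_list - 1] + i) // 2 + 1)
        if pos_in_list < len(idx) - 1:
            hi = min(hi, (idx[pos_in_list + 1] + i) // 2 - 1)
        window = slice(lo, hi + 1)
        area = float(counts[window].sum())
        if area < min_peak_events:
            continue
        mu, sd = _fit_window(centers[window], counts[window])
        if mu <= 0:
            continue
        peaks.append(Peak(position=mu, sd=sd, area=area))
    if not peaks:
        raise NoPeakError(
            f"no peak with at least {min_peak_events:.0f} events found"
        )
    peaks.sort(key=lambda p: p.position)
    return peaks


def _is_double(upper: Peak, lower: Peak, n_sd: float = 3.0) -> bool:
    """Is ``upper`` at twice ``lower``'s position, within n_sd combined sd?"""
    tol = n_sd * math.sqrt((2.0 * lower.sd) ** 2 + upper.sd ** 2)
    tol += 1e-9 * lower.position  # float safety for noiseless fixtures
    return abs(upper.position - 2.0 * lower.position) <= tol


def classify_peaks(peaks: Sequence[Peak], standard_1c: float,
                   expected_sample_range: tuple[float, float]) -> PeakAssignment:
    """Resolve which peak is the sample 2C and which the standard 2C.

    Every ordered pair (standard candidate, sample candidate) is scored:
    the implied sample 1C (standard 1C times the position ratio) must lie
    inside ``expected_sample_range`` (pg), and every remaining peak must
    be explainable as the 4C doubling of one of the two.  Exactly one
    surviving assignment is required; several raise :class:`AmbiguityError`
    rather than guessing, and none raises :class:`ClassificationError`.
    """
    if len(peaks) < 2:
        raise ClassificationError("need at least 2 peaks to classify")
    lo, hi = expected_sample_range
    if not (0 < lo < hi):
        raise ValidationError("expected_sample_range: need 0 < lo < hi")

    candidates = []
    for i, anchor in enumerate(peaks):
        for j, samp in enumerate(peaks):
            if i == j:
                continue
            implied = standard_1c * samp.position / anchor.position
            if not (lo <= implied <= hi):
                continue
            others = [p for k_, p in enumerate(peaks) if k_ not in (i, j)]
            if all(_is_double(p, anchor) or _is_double(p, samp) for p in others):
                candidates.append((i, j))
    if not candidates:
        raise ClassificationError(
            "no peak assignment yields a sample 1C inside "
            f"({lo}, {hi}) pg with standard 1C = {standard_1c} pg"
        )
    if len(candidates) > 1:
        raise AmbiguityError(
            "sample and standard peaks cannot be told apart; "
            "re-run with a different internal standard"
        )
    i, j = candidates[0]
    labeled = []
    anchor, samp = peaks[i], peaks[j]
    standard = replace(anchor, ploidy_label="2C", source="standard")
    sample = replace(samp, ploidy_label="2C", source="sample")
    tetraploid = []
    for k_, p in enumerate(peaks):
        if k_ == i:
            labeled.append(standard)
        elif k_ == j:
            labeled.append(sample)
        else:
            source = "standard" if _is_double(p, anchor) else "sample"
            q = replace(p, ploidy_label="4C", source=source)
            tetraploid.append(q)
            labeled.append(q)
    return PeakAssignment(sample=sample, standard=standard,
                          tetraploid=tetraploid, peaks=labeled)


def qc_cv(peak: Peak, cv_max: float = DEFAULT_CV_MAX) -> bool:
    """QC rule for a fitted peak: CV strictly below ``cv_max`` percent."""
    return peak.cv < cv_max


def estimate_gs(sample_peak: Peak, standard_peak: Peak, standard_1c: float,
                cv_max: float = DEFAULT_CV_MAX,
                replicate_id: str = "", **meta) -> RatioEstimate:
    """Genome size from the 2C peak-position ratio.

    1C = standard 1C * sample position / standard position; the estimate
    passes QC iff both peaks have CV < ``cv_max``.
    """
    if sample_peak.position <= 0 or standard_peak.position <= 0:
        raise ValidationError("peak positions must be > 0")
    if standard_1c <= 0:
        raise ValidationError("standard_1c: must be > 0")
    one_c = standard_1c * sample_peak.position / standard_peak.position
    qc = qc_cv(sample_peak, cv_max) and qc_cv(standard_peak, cv_max)
    return RatioEstimate(one_c=one_c, sample_peak=sample_peak,
                         standard_peak=standard_peak, qc_pass=qc,
                         replicate_id=replicate_id, **meta)


def estimate_from_events(table: EventTable,
                         expected_sample_range: tuple[float, float],
                         n_channels: int = DEFAULT_N_CHANNELS,
                         smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                         min_peak_events: Optional[float] = None,
                         cv_max: float = DEFAULT_CV_MAX) -> RatioEstimate:
    """Full single-replicate chain: bin, fit, classify, estimate."""
    hist = build_histogram(table, n_channels=n_channels)
    peaks = detect_and_fit_peaks(hist, min_peak_events=min_peak_events,
                                 smooth_window=smooth_window)
    assignment = classify_peaks(peaks, table.standard_1c, expected_sample_range)
    return estimate_gs(assignment.sample, assignment.standard,
                       table.standard_1c, cv_max=cv_max,
                       replicate_id=table.replicate_id,
                       species=table.species, sex=table.sex,
                       standard_name=table.standard_name)


def aggregate_replicates(estimates: Sequence[RatioEstimate]) -> SpeciesSummary:
    """Aggregate QC-passed replicate estimates into one summary row.

    mean 1C is reported at 2 decimals; the Mb value is the *unrounded*
    pg mean times 978, rounded to an integer; SE is sd/sqrt(n) of the
    replicate means in Mb, omitted when n = 1.
    """
    if not estimates:
        raise ValidationError("estimates: at least one estimate required")
    passed = [e for e in estimates if e.qc_pass]
    if not passed:
        raise ValidationError("estimates: no QC-passed estimate")
    species = {e.species for e in passed}
    sexes = {e.sex for e in passed}
    if len(species) > 1 or len(sexes) > 1:
        raise ValidationError(
            f"estimates: mixed groups (species={species}, sex={sexes})"
        )
    values = np.array([e.one_c for e in passed], dtype=float)
    n = values.size
    mean_pg = float(values.mean())
    genome_mb = int(round(pg_to_mb(mean_pg)))
    if n >= 2:
        se_pg = float(values.std(ddof=1)) / math.sqrt(n)
        se_mb: Optional[int] = int(round(pg_to_mb(se_pg)))
    else:
        se_mb = None
    return SpeciesSummary(species=species.pop() or "", sex=sexes.pop() or "",
                          mean_1c=round(mean_pg, 2), genome_mb=genome_mb,
                          se_mb=se_mb, n=n)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_events_csv(table: EventTable, path) -> None:
    truth = (table.population_truth if table.population_truth is not None
             else np.full(table.n_events, "", dtype=object))
    pd.DataFrame({
        "replicate_id": np.full(table.n_events, table.replicate_id, dtype=object),
        "population_truth": truth,
        "fluorescence": table.events,
    }).to_csv(path, index=False)


def read_events_csv(path, replicate_id: Optional[str] = None, species: str = "",
                    sex: str = "", standard_name: str = "",
                    standard_1c: float = 1.0) -> EventTable:
    df = pd.read_csv(path)
    if replicate_id is not None:
        df = df[df["replicate_id"].astype(str) == str(replicate_id)]
    elif "replicate_id" in df.columns and len(df):
        replicate_id = str(df["replicate_id"].iloc[0])
        df = df[df["replicate_id"].astype(str) == replicate_id]
    if not len(df):
        raise EmptyInputError(f"no events for replicate {replicate_id!r} in {path}")
    truth = None
    if "population_truth" in df.columns and df["population_truth"].notna().any():
        truth = df["population_truth"].to_numpy()
    return EventTable(replicate_id=str(replicate_id or ""), species=species,
                      sex=sex, standard_name=standard_name,
                      standard_1c=standard_1c,
                      events=df["fluorescence"].to_numpy(float),
                      population_truth=truth)


def estimates_to_frame(estimates: Sequence[RatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "replicate_id": e.replicate_id,
        "species": e.species,
        "sex": e.sex,
        "standard": e.standard_name,
        "one_c_pg": e.one_c,
        "genome_mb": e.genome_mb,
        "cv_sample": e.sample_peak.cv,
        "cv_standard": e.standard_peak.cv,
        "qc_pass": e.qc_pass,
    } for e in estimates])


def summaries_to_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": s.species, "sex": s.sex, "one_c_pg": s.mean_1c,
        "genome_mb": s.genome_mb, "se_mb": s.se_mb, "n": s.n,
    } for s in summaries])
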