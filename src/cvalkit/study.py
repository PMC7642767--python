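"""Study-level orchestration and summary statistics.

Packages the published flow-cytometry summary tables for 17 Caelifera
species as fixtures, computes study-level statistics from tables of
per species-and-sex 1C values (overall mean, fold range, sex and method
differences), runs per-species sex-difference t-tests on replicate
estimates, and orchestrates the full pipeline from a config file.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import comparative, fcm, kmer, standards
from .errors import PipelineError, ValidationError

__all__ = [
    "load_flow_table", "load_sex_table", "load_method_table",
    "StudyStats", "study_stats", "sex_difference_tests", "run_pipeline",
]


def _packaged_csv(name: str) -> pd.DataFrame:
    source = resources.files("cvalkit.data").joinpath(name)
    with resources.as_file(source) as p:
        return pd.read_csv(p)


def load_flow_table() -> pd.DataFrame:
    """Per species-and-sex flow-cytometry summaries (34 rows, 17 species):
    columns species, sex, one_c_pg, genome_mb, se_mb, n, standard."""
    return _packaged_csv("flow_cytometry_summaries.csv")


def load_sex_table() -> pd.DataFrame:
    """Per-species female/male mean 1C values with replicate counts and
    the published t-test p-values."""
    return _packaged_csv("sex_difference_tests.csv")


def load_method_table() -> pd.DataFrame:
    """Species with both flow-cytometry and k-mer C-values."""
    return _packaged_csv("method_comparison.csv")


@dataclass
class StudyStats:
    overall_mean_1c: float
    min_1c: float
    min_species: str
    max_1c: float
    max_species: str
    fold_range: float
    sex_differences: dict[str, float]       # species -> female - male, pg
    min_sex_difference: float
    min_sex_species: str
    max_sex_difference: float
    max_sex_species: str
    mean_sex_difference: float
    method_differences: dict[str, float]    # species -> FCM - k-mer, pg
    footnote: str = (
        "mean_sex_difference is the unweighted mean of per-species "
        "female-minus-male differences computed from the table values"
    )

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def study_stats(flow_table: Optional[pd.DataFrame] = None,
                method_table: Optional[pd.DataFrame] = None) -> StudyStats:
    """Study-level statistics from a per species-and-sex 1C table.

    Overall mean is the unweighted mean over all sex-specific 1C values
    (2 decimals); fold range is max/min (2 decimals); sex differences
    are female minus male per species (2 decimals); method differences
    are flow-cytometry minus k-mer where both exist.
    """
    table = flow_table if flow_table is not None else load_flow_table()
    if not len(table):
        raise ValidationError("empty study table")
    vals = table["one_c_pg"].astype(float)
    i_min, i_max = vals.idxmin(), vals.idxmax()

    diffs: dict[str, float] = {}
    for species, sub in table.groupby("species", sort=False):
        sexes = dict(zip(sub["sex"], sub["one_c_pg"].astype(float)))
        if "F" in sexes and "M" in sexes:
            diffs[species] = round(sexes["F"] - sexes["M"], 2)
        else:
            warnings.warn(f"{species}: only one sex in table; skipped from "
                          "sex differences", stacklevel=2)
    if not diffs:
        raise ValidationError("no species with both sexes in the table")
    min_sp = min(diffs, key=diffs.get)
    max_sp = max(diffs, key=diffs.get)

    method = method_table if method_table is not None else load_method_table()
    method_diffs = {
        row["species"]: kmer.method_difference(float(row["fcm_pg"]),
                                               float(row["kmer_pg"]))
        for _, row in method.iterrows()
    }

    return StudyStats(
        overall_mean_1c=round(float(vals.mean()), 2),
        min_1c=float(vals[i_min]), min_species=str(table.loc[i_min, "species"]),
        max_1c=float(vals[i_max]), max_species=str(table.loc[i_max, "species"]),
        fold_range=round(float(vals[i_max] / vals[i_min]), 2),
        sex_differences=diffs,
        min_sex_difference=diffs[min_sp], min_sex_species=min_sp,
        max_sex_difference=diffs[max_sp], max_sex_species=max_sp,
        mean_sex_difference=round(float(np.mean(list(diffs.values()))), 2),
        method_differences=method_diffs,
    )


def sex_difference_tests(estimates: pd.DataFrame, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Per-species female-vs-male comparison of replicate 1C estimates.

    ``estimates`` needs columns species, sex, one_c_pg.  The difference
    is mean(F) - mean(M); significance is a pooled-variance Student's t
    at ``alpha``.  An n = 1 group is tested against the pooled variance
    of the other and flagged low-confidence; species missing a sex are
    skipped with a warning.
    """
    rows = []
    for species, sub in estimates.groupby("species", sort=False):
        f = sub[sub["sex"] == "F"]["one_c_pg"].to_numpy(float)
        m = sub[sub["sex"] == "M"]["one_c_pg"].to_numpy(float)
        if f.size == 0 or m.size == 0:
            warnings.warn(f"{species}: missing a sex; skipped", stacklevel=2)
            continue
        res = standards.students_t(standards.GroupData("F", f),
                                   standards.GroupData("M", m))
        rows.append({
            "species": species,
            "mean_f_pg": round(float(f.mean()), 2),
            "n_f": f.size,
            "mean_m_pg": round(float(m.mean()), 2),
            "n_m": m.size,
            "difference_pg": round(float(f.mean() - m.mean()), 2),
            "t": res.t, "df": res.df, "p": res.p_value,
            "significant": res.p_value < alpha,
            "low_confidence": res.low_confidence,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_config(config) -> tuple[dict, Path, str]:
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        cfg = yaml.safe_load(text) or {}
        base = path.parent
    else:
        cfg = dict(config or {})
        text = yaml.safe_dump(cfg)
        base = Path.cwd()
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    return cfg, base, digest


def run_pipeline(config, outdir) -> dict:
    """Execute the configured stages and write a report bundle.

    Config keys (YAML mapping; paths relative to the config file):

    * ``fcm``: list of replicate entries (events_csv, replicate_id,
      species, sex, standard_1c, standard_name,
      expected_sample_range_pg) plus optional keys n_channels,
      smooth_window, min_peak_events, cv_max.
    * ``kmer``: list of entries (histogram, k) or (reads, k).
    * ``phylo``: tree (Newick path), traits (CSV path), n_perm, seed.
    * ``study``: ``use_packaged_tables: true`` to summarise the shipped
      flow-cytometry tables.

    Writes estimates/summary/sex-test CSVs, a k-mer report CSV, a
    phylogenetic-signal JSON, a study-stats JSON and a run log; returns
    the bundle as a dict.  A stage failure raises PipelineError naming
    the stage.
    """
    cfg, base, digest = _load_config(config)
    stages = [s for s in ("fcm", "kmer", "phylo", "study") if s in cfg]
    if not stages:
        raise ValidationError(
            "empty config: requires at least one of fcm/kmer/phylo/study")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    log_lines = [f"cvalkit {_version()}", f"config sha256/16 {digest}",
                 f"stages: {', '.join(stages)}"]

    if "fcm" in cfg:
        try:
            section = cfg["fcm"]
            entries = section if isinstance(section, list) else section["inputs"]
            opts = {} if isinstance(section, list) else {
                k_: v for k_, v in section.items() if k_ != "inputs"}
            estimates = []
            for entry in entries:
                table = fcm.read_events_csv(
                    base / entry["events_csv"],
                    replicate_id=entry.get("replicate_id"),
                    species=entry.get("species", ""),
                    sex=entry.get("sex", ""),
                    standard_name=entry.get("standard_name", ""),
                    standard_1c=float(entry["standard_1c"]))
                estimates.append(fcm.estimate_from_events(
                    table,
                    expected_sample_range=tuple(entry["expected_sample_range_pg"]),
                    n_channels=int(opts.get("n_channels", fcm.DEFAULT_N_CHANNELS)),
                    smooth_window=int(opts.get("smooth_window",
                                               fcm.DEFAULT_SMOOTH_WINDOW)),
                    min_peak_events=opts.get("min_peak_events"),
                    cv_max=float(opts.get("cv_max", fcm.DEFAULT_CV_MAX))))
            est_df = fcm.estimates_to_frame(estimates)
            est_df.to_csv(outdir / "estimates.csv", index=False)
            summaries = []
            for (_, _), group in _group_estimates(estimates):
                summaries.append(fcm.aggregate_replicates(group))
            fcm.summaries_to_frame(summaries).to_csv(
                outdir / "summary.csv", index=False)
            both_sexes = est_df[est_df["qc_pass"]]
            sex_df = sex_difference_tests(both_sexes)
            if len(sex_df):
                sex_df.to_csv(outdir / "sex_differences.csv", index=False)
            bundle["fcm"] = est_df
            log_lines.append(f"fcm: {len(estimates)} replicates, "
                             f"{len(summaries)} summaries")
        except Exception as exc:
            raise PipelineError(f"stage fcm failed: {exc}") from exc

    if "kmer" in cfg:
        try:
            rows = []
            for entry in cfg["kmer"]:
                k_val = int(entry.get("k", kmer.DEFAULT_K))
                if "histogram" in entry:
                    spec = kmer.Spectrum.read(base / entry["histogram"], k=k_val)
                else:
                    spec = kmer.count_kmers_in_file(base / entry["reads"], k=k_val)
                est = kmer.kmer_report(spec)
                rows.append({"input": entry.get("histogram", entry.get("reads")),
                             "k": est.k, "error_cutoff": est.error_cutoff,
                             "d_hom": est.d_hom,
                             "genome_bp": est.genome_size_bp,
                             "genome_pg": est.genome_size_pg,
                             "repeat_fraction": est.repeat_fraction,
                             "heterozygosity": est.heterozygosity})
            kdf = pd.DataFrame(rows)
            kdf.to_csv(outdir / "kmer_report.csv", index=False)
            bundle["kmer"] = kdf
            log_lines.append(f"kmer: {len(rows)} spectra")
        except Exception as exc:
            raise PipelineError(f"stage kmer failed: {exc}") from exc

    if "phylo" in cfg:
        try:
            section = cfg["phylo"]
            tree = comparative.load_tree(base / section["tree"])
            traits = comparative.read_trait_csv(base / section["traits"])
            seed = int(section.get("seed", 0))
            report = comparative.phylo_signal_report(
                tree, traits, n_perm=int(section.get("n_perm", 999)), seed=seed)
            (outdir / "phylo_signal.json").write_text(
                json.dumps(report, indent=2))
            bundle["phylo"] = report
            log_lines.append(f"phylo: lambda_hat={report['lambda_hat']:.3f} "
                             f"K={report['K']:.3f} seed={seed}")
        except Exception as exc:
            raise PipelineError(f"stage phylo failed: {exc}") from exc

    if "study" in cfg:
        try:
            stats = study_stats()
            payload = stats.to_dict()
            (outdir / "study_stats.json").write_text(
                json.dumps(payload, indent=2))
            bundle["study"] = payload
            log_lines.append(
                f"study: mean={stats.overall_mean_1c} fold={stats.fold_range}")
        except Exception as exc:
            raise PipelineError(f"stage study failed: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle


def _group_estimates(estimates):
    groups: dict = {}
    for e in estimates:
        groups.setdefault((e.species, e.sex), []).append(e)
    return groups.items()


def _version() -> str:
    from . import __version__
    return __version__
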