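"""End-to-end workflow: simulate → preprocess → spectra → DTF → statistics.

``run_analysis`` consumes a cohort (in memory or on disk) and produces a
:class:`ResultsBundle`: the per-subject band-power table, DTF aggregates,
behavioral phenotypes, and the group-statistics battery. Group membership
for the statistics follows the study's logic: simulated patients are
split into normal-performing and impaired analogs by the phenotyping rule
itself (generator truth is reserved for recovery scoring), giving the
three analysis groups ``Con``, ``patient-normal`` and ``patient-impaired``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import DTFResult, dtf_analysis, fit_mvar
from .io import Recording, load_recording, read_behavior, read_events
from .montage import RegionMap, default_region_map
from .preprocess import extract_epochs, preprocess_recording
from .simulate import Cohort, GroundTruth, SimulationConfig, generate_cohort, write_cohort
from .spectral import (
    DEFAULT_BANDS,
    BandScheme,
    SpectralConfig,
    band_power,
    band_power_table,
    prominent_band,
    region_power,
    stft_psd,
    wm_efficiency,
)
from .stats import (
    StatTestResult,
    assumption_checks,
    one_way_anova_lsd,
    pearson_corr,
    phenotype,
    summarize_behavior,
    t_test,
)

__all__ = [
    "PipelineConfig",
    "ResultsBundle",
    "run_simulate",
    "load_cohort",
    "run_analysis",
    "render_report",
]

logger = logging.getLogger(__name__)

ANALYSIS_GROUPS = ("Con", "patient-normal", "patient-impaired")


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable settings for one analysis run."""

    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    bands: BandScheme = DEFAULT_BANDS
    mvar_order: int | str = "auto"
    mvar_criterion: str = "bic"
    mvar_max_order: int = 8
    connectivity_band: str = "theta"
    hub_region: str = "F"
    phenotype_threshold: float = 1.5
    lowpass_cutoff: float | None = 100.0
    notch_band: tuple[float, float] | None = (49.0, 51.0)
    drift_method: str = "linear_detrend"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spectral"] = dataclasses.asdict(self.spectral)
        d["bands"] = [list(b) for b in self.bands.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "spectral" in d and isinstance(d["spectral"], dict):
            d["spectral"] = SpectralConfig(**d["spectral"])
        if "bands" in d and not isinstance(d["bands"], BandScheme):
            d["bands"] = BandScheme(tuple(tuple(b) for b in d["bands"]))
        if "notch_band" in d and d["notch_band"] is not None:
            d["notch_band"] = tuple(d["notch_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class ResultsBundle:
    """Everything one analysis run produced, ready to persist."""

    subject_table: pd.DataFrame          # one row per subject
    band_powers: pd.DataFrame            # tidy subject/channel/band table
    dtf_results: dict[str, DTFResult]
    statistics: list[StatTestResult]
    assumptions: dict
    config: PipelineConfig
    manifest: dict

    def statistics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.statistics:
            rows.append(
                {
                    "measure": r.extra.get("measure", ""),
                    "test": r.test,
                    "groups": " vs ".join(r.groups),
                    "statistic": r.statistic,
                    "df": str(r.df),
                    "p_value": r.p_value,
                    "direction": r.direction,
                }
            )
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.subject_table.to_csv(out / "subjects.tsv", sep="\t", index=False,
                                  float_format=fmt)
        self.band_powers.to_csv(out / "band_powers.tsv", sep="\t", index=False,
                                float_format=fmt)
        self.statistics_frame().to_csv(out / "statistics.tsv", sep="\t",
                                       index=False, float_format=fmt)
        (out / "statistics.json").write_text(json.dumps({
            "tests": [
                {
                    "measure": r.extra.get("measure", ""),
                    "test": r.test,
                    "groups": list(r.groups),
                    "statistic": r.statistic,
                    "df": r.df if not isinstance(r.df, tuple) else list(r.df),
                    "p_value": r.p_value,
                    "direction": r.direction,
                }
                for r in self.statistics
            ],
            "assumption_checks": self.assumptions,
        }, indent=2, sort_keys=True))
        for subject, res in self.dtf_results.items():
            sdir = out / "dtf" / subject
            sdir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                res.band_gamma, index=list(res.channel_labels),
                columns=list(res.channel_labels),
            ).to_csv(sdir / "band_gamma.tsv", sep="\t", float_format=fmt)
            res.dtf_kl.to_csv(sdir / "dtf_regions.tsv", sep="\t", float_format=fmt)
            (sdir / "summary.json").write_text(json.dumps({
                "dtf_g": res.dtf_g,
                "dtf_out": res.dtf_out,
                "dtf_in": res.dtf_in,
                "hub_region": res.hub_region,
                "band": list(res.band),
                "mvar_order": res.mvar_order,
            }, indent=2, sort_keys=True))
        manifest = dict(self.manifest)
        manifest["config"] = self.config.to_dict()
        manifest["software_version"] = __version__
        path = out / "results_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


def run_simulate(
    sim_config: SimulationConfig,
    out_dir: str | Path,
    eeg_format: str = "csv",
    overwrite: bool = False,
) -> Path:
    """Generate a synthetic cohort and write it to disk."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite to replace it"
        )
    cohort = generate_cohort(sim_config)
    return write_cohort(cohort, out_dir, eeg_format=eeg_format, overwrite=overwrite)


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a written cohort back into memory via its manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "cohort_manifest.json").read_text())
    config = SimulationConfig(**{
        k: (tuple(v) if k == "channels" and v is not None else v)
        for k, v in manifest["config"].items()
    })
    gt = GroundTruth(
        config=config,
        subjects=tuple(manifest["subjects"]),
        group_labels=manifest["group_labels"],
        impaired_flags=manifest["impaired_flags"],
        latent_theta=manifest["latent_theta"],
        coupling={},
        noise_scales={},
        hub_gains={},
        hub_channel=manifest["hub_channel"],
        subject_seeds=manifest["subject_seeds"],
    )
    recordings, events, behavior = {}, {}, {}
    missing = []
    ext = "edf" if manifest.get("eeg_format") == "edf" else "csv"
    for subject in gt.subjects:
        sdir = cohort_dir / subject
        eeg = sdir / f"eeg.{ext}"
        if not eeg.exists():
            missing.append(subject)
            continue
        recordings[subject] = load_recording(
            eeg, fs=manifest["fs"], subject_id=subject
        )
        events[subject] = read_events(sdir / "events.tsv")
        behavior[subject] = read_behavior(sdir / "behavior.tsv")
    if missing:
        raise FileNotFoundError(
            f"cohort at {cohort_dir} is missing EEG for subjects {missing}"
        )
    return Cohort(ground_truth=gt, recordings=recordings, events=events,
                  behavior=behavior)


# --------------------------------------------------------------------------
# Per-subject analysis
# --------------------------------------------------------------------------

def analyze_subject(
    rec: Recording,
    events: pd.DataFrame,
    config: PipelineConfig,
    regions: RegionMap,
) -> dict:
    """Spectral and connectivity measures for one subject.

    The resting baseline is taken to be everything before the first task
    event; the task signal is the encoding epochs.
    """
    rec = preprocess_recording(
        rec,
        lowpass_cutoff=config.lowpass_cutoff if config.lowpass_cutoff else np.inf,
        notch_band=config.notch_band or (np.inf, np.inf),
        drift_method=config.drift_method,
    )
    first_onset = int(events["onset_sample"].min())
    rest = Recording(
        data=rec.data[:, :first_onset],
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        subject_id=rec.subject_id,
    )
    epochs = extract_epochs(rec, events, "encoding")
    p_raw = band_power(stft_psd(epochs, config.spectral), config.bands)
    p_rs = band_power(stft_psd(rest, config.spectral), config.bands)
    p_wm = wm_efficiency(p_raw, p_rs)
    prominent = prominent_band(p_raw)

    model = fit_mvar(
        epochs,
        order=config.mvar_order,
        criterion=config.mvar_criterion,
        max_order=config.mvar_max_order,
    )
    band_edges = config.bands.edges(config.connectivity_band)
    dtf_res = dtf_analysis(
        model,
        regions,
        band=band_edges,
        hub_region=config.hub_region,
        freq_resolution=config.spectral.freq_resolution,
    )
    wm_region = region_power(p_wm[config.connectivity_band], regions)
    return {
        "p_raw": p_raw,
        "p_rs": p_rs,
        "p_wm": p_wm,
        "prominent_band": prominent,
        "dtf": dtf_res,
        "wm_region_power": wm_region,
    }


def run_analysis(
    cohort: Cohort | str | Path,
    config: PipelineConfig,
    on_error: str = "raise",
) -> ResultsBundle:
    """Full cohort analysis; see the module docstring for the group logic.

    ``on_error="skip"`` enables the partial-failure mode: a subject whose
    analysis raises is excluded with a logged warning instead of aborting
    the whole run.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    if not isinstance(cohort, Cohort):
        cohort = load_cohort(cohort)
    gt = cohort.ground_truth
    regions = default_region_map().restricted(gt.config.channels)

    per_subject: dict[str, dict] = {}
    rows = []
    band_tables = []
    dtf_results: dict[str, DTFResult] = {}
    excluded: list[str] = []
    for subject in gt.subjects:
        try:
            res = analyze_subject(
                cohort.recordings[subject], cohort.events[subject], config, regions
            )
        except Exception as err:
            if on_error == "raise":
                raise
            logger.warning("excluding subject %s: %s", subject, err)
            excluded.append(subject)
            continue
        per_subject[subject] = res
        dtf_results[subject] = res["dtf"]
        band_tables.append(band_power_table(subject, res["p_raw"], res["p_rs"]))
    subjects = [s for s in gt.subjects if s not in excluded]

    summaries = [
        summarize_behavior(s, cohort.behavior[s]) for s in subjects
    ]
    control_ids = {s for s in subjects if gt.group_labels[s] == "Con"}
    phen = {
        p.subject: p
        for p in phenotype(
            summaries, control_ids, threshold=config.phenotype_threshold
        )
    }

    for s, summary in zip(subjects, summaries):
        res = per_subject[s]
        p = phen[s]
        if p.is_control:
            agroup = "Con"
        else:
            agroup = "patient-impaired" if p.phenotype == "impaired" else "patient-normal"
        row = {
            "subject": s,
            "group": gt.group_labels[s],
            "analysis_group": agroup,
            "mean_rt_ms": summary.mean_rt_correct,
            "acc": summary.acc,
            "z_rt": p.z_rt,
            "z_acc": p.z_acc,
            "phenotype": p.phenotype,
            "prominent_band": res["prominent_band"],
            "dtf_g": res["dtf"].dtf_g,
            "dtf_out": res["dtf"].dtf_out,
            "dtf_in": res["dtf"].dtf_in,
        }
        for region in regions.regions:
            row[f"dtf_{region}"] = res["dtf"].region_strength[region]
            row[f"pwm_{config.connectivity_band}_{region}"] = res["wm_region_power"][region]
        rows.append(row)
    table = pd.DataFrame(rows)

    statistics, assumptions = _statistics_battery(table, config, regions)
    manifest = {
        "subjects": subjects,
        "excluded_subjects": excluded,
        "group_labels": gt.group_labels,
        "analysis_groups": dict(zip(table["subject"], table["analysis_group"])),
        "hub_channel": gt.hub_channel,
        "n_subjects": len(subjects),
    }
    return ResultsBundle(
        subject_table=table,
        band_powers=pd.concat(band_tables, ignore_index=True),
        dtf_results=dtf_results,
        statistics=statistics,
        assumptions=assumptions,
        config=config,
        manifest=manifest,
    )


def _grouped(table: pd.DataFrame, column: str) -> dict[str, np.ndarray]:
    return {
        g: sub[column].to_numpy(dtype=float)
        for g, sub in table.groupby("analysis_group")
        if len(sub) >= 2
    }


def _statistics_battery(
    table: pd.DataFrame, config: PipelineConfig, regions: RegionMap
) -> tuple[list[StatTestResult], dict]:
    """The group-comparison battery over behavior, power and connectivity."""
    stats: list[StatTestResult] = []
    assumptions: dict = {}

    def add_anova(measure: str):
        groups = _grouped(table, measure)
        if len(groups) < 2:
            logger.warning("skipping ANOVA for %s: fewer than 2 groups", measure)
            return
        try:
            omnibus, pairwise = one_way_anova_lsd(groups)
        except ValueError as err:
            logger.warning("ANOVA failed for %s: %s", measure, err)
            return
        omnibus.extra["measure"] = measure
        stats.append(omnibus)
        for p in pairwise:
            p.extra["measure"] = measure
            stats.append(p)
        try:
            assumptions[measure] = assumption_checks(groups)
        except ValueError:
            pass

    # behavior (two-group contrast plus the three-group ANOVA)
    con = table[table["analysis_group"] == "Con"]
    patients = table[table["analysis_group"] != "Con"]
    for measure in ("mean_rt_ms", "acc"):
        if len(con) >= 2 and len(patients) >= 2:
            r = t_test(
                con[measure], patients[measure], labels=("Con", "patients")
            )
            r.extra["measure"] = measure
            stats.append(r)
        add_anova(measure)

    # spectral and connectivity measures
    for measure in (
        [f"pwm_{config.connectivity_band}_{r}" for r in regions.regions]
        + ["dtf_g", "dtf_out", "dtf_in"]
        + [f"dtf_{r}" for r in regions.regions]
    ):
        add_anova(measure)

    # correlations within each analysis group (power/connectivity vs behavior)
    hub = config.hub_region
    for group, sub in table.groupby("analysis_group"):
        if len(sub) < 3:
            continue
        for x_col in (f"pwm_{config.connectivity_band}_{hub}", f"dtf_{hub}"):
            for y_col in ("mean_rt_ms", "acc"):
                try:
                    r = pearson_corr(sub[x_col], sub[y_col])
                except ValueError:
                    continue
                r = dataclasses.replace(r, groups=(str(group),))
                r.extra["measure"] = f"{x_col}~{y_col}"
                stats.append(r)
    return stats, assumptions


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def render_report(bundle: ResultsBundle) -> str:
    """Markdown report of cohort behavior, band power, DTF and statistics."""
    lines = ["# Working-memory EEG analysis report", ""]
    t = bundle.subject_table
    lines.append(f"Subjects: {len(t)}; analysis groups: "
                 + ", ".join(f"{g} (n={n})" for g, n in
                             t["analysis_group"].value_counts().items()))
    lines.append("")
    lines.append("## Cohort table")
    lines.append(t.to_csv(sep="\t", index=False, float_format="%.10g").rstrip())
    lines.append("")
    lines.append("## Group means")
    num = t.select_dtypes("number")
    means = t[["analysis_group"]].join(num).groupby("analysis_group").mean()
    lines.append(means.to_csv(sep="\t", float_format="%.10g").rstrip())
    lines.append("")
    lines.append("## Statistics")
    sf = bundle.statistics_frame()
    if sf.empty:
        lines.append("No tests run.")
    else:
        lines.append(sf.to_csv(sep="\t", index=False, float_format="%.10g").rstrip())
    lines.append("")
    return "\n".join(lines)
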