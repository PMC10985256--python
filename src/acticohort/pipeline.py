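"""End-to-end orchestration: simulate/load -> wear -> measures -> statistics.

`run_pipeline` is deterministic given a config (seed included): two runs with
the same config produce byte-identical reports.  Outputs are a per-subject
summary TSV (one row per subject x placement x visit), a cohort statistics
JSON, and a run log containing the fully resolved configuration.
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

from . import stats as cstats
from .epochs import (
    EpochSeries,
    read_clinical_table,
    read_diary_csv,
    read_epoch_csv,
)
from .metrics import CutPoints, MEASURES, summarize_subject
from .simulate import Cohort, CohortConfig, simulate_cohort
from .wear import ChoiParams, flag_wear

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort", "cohort_statistics"]

logger = logging.getLogger(__name__)

CLINICAL_CORRELATES = ["sara", "mfars", "adl", "ccfs", "disease_duration"]


@dataclass
class PipelineConfig:
    """Fully serializable run configuration with embedded defaults."""

    out_dir: str = "pipeline_out"
    input_dir: str | None = None  # None -> simulate a cohort
    write_data: bool = True  # write simulated CSVs under out_dir/data
    seed: int = 0
    n_frda: int = 26
    n_ctr: int = 13
    days: int = 7
    annual_decline: float = 1.0

    choi_window: int = 90
    choi_spike: int = 2
    choi_flank: int = 30
    choi_axis: str = "axis1"
    min_wear_hours: float = 8.0
    use_diary: bool = True

    cut_sedentary: float = 99.0
    cut_light: float = 1951.0
    cut_moderate: float = 5724.0
    bout_min_duration: int = 10
    bout_drop_tolerance: int = 0

    alpha: float = 0.05
    n_families: int = 7
    srm_delta: float = 1.0
    srm_solver: str = "normal"

    def choi_params(self) -> ChoiParams:
        return ChoiParams(self.choi_window, self.choi_spike, self.choi_flank, self.choi_axis)

    def cutpoints(self) -> CutPoints:
        return CutPoints(self.cut_sedentary, self.cut_light, self.cut_moderate)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_frda=self.n_frda,
            n_ctr=self.n_ctr,
            days=self.days,
            seed=self.seed,
            annual_decline=self.annual_decline,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Summarization
# ---------------------------------------------------------------------------

def _summary_rows(
    flagged: list[tuple[EpochSeries, str]],
    config: PipelineConfig,
) -> pd.DataFrame:
    rows = []
    for series, group in flagged:
        try:
            summ = summarize_subject(
                series,
                config.cutpoints(),
                config.min_wear_hours,
                config.bout_min_duration,
                config.bout_drop_tolerance,
            )
        except ValueError:
            logger.warning(
                "excluding %s %s %s: no valid wear days",
                series.subject_id, series.placement, series.visit,
            )
            continue
        row = summ.to_dict()
        row["group"] = group
        rows.append(row)
    cols = ["subject_id", "group", "placement", "visit", *MEASURES, "wear_days", "wear_minutes"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["group", "subject_id", "placement", "visit"], ignore_index=True
    )


def summarize_cohort(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    use_diary: bool = False,
) -> tuple[pd.DataFrame, list[EpochSeries]]:
    """Run wear detection and the seven measures over every series of a
    simulated cohort; returns the summary table and the wear-flagged series."""
    config = config or PipelineConfig()
    diaries = cohort.diaries() if use_diary else {}
    group_of = {s.baseline.subject_id: s.baseline.group for s in cohort.subjects}
    flagged: list[tuple[EpochSeries, str]] = []
    for (sid, placement, visit), sim in sorted(cohort.series.items()):
        series = flag_wear(sim.series, config.choi_params(), diaries.get(sid))
        flagged.append((series, group_of[sid]))
    df = _summary_rows(flagged, config)
    return df, [s for s, _ in flagged]


def _load_input(config: PipelineConfig):
    base = Path(config.input_dir)
    epoch_dir = base / "epochs"
    if not epoch_dir.is_dir():
        raise FileNotFoundError(f"missing epoch directory: {epoch_dir}")
    clinical_path = base / "clinical.csv"
    if not clinical_path.is_file():
        raise FileNotFoundError(f"missing clinical table: {clinical_path}")
    records = read_clinical_table(clinical_path)
    diary_path = base / "diary.csv"
    diaries = read_diary_csv(diary_path) if diary_path.is_file() else {}
    group_of = {r.subject_id: r.group for r in records}
    flagged = []
    for path in sorted(epoch_dir.glob("*.csv")):
        series = read_epoch_csv(path)
        if series.subject_id not in group_of:
            raise ValueError(f"{path}: subject {series.subject_id} absent from clinical table")
        series = flag_wear(
            series,
            config.choi_params(),
            diaries.get(series.subject_id) if config.use_diary else None,
        )
        flagged.append((series, group_of[series.subject_id]))
    return records, flagged


# ---------------------------------------------------------------------------
# Cohort statistics report
# ---------------------------------------------------------------------------

def _wide(summary: pd.DataFrame, placement: str, visit: str) -> pd.DataFrame:
    sel = summary[(summary.placement == placement) & (summary.visit == visit)]
    return sel.set_index("subject_id")


def cohort_statistics(
    summary: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    baseline_series: list[EpochSeries] | None = None,
) -> dict:
    """Assemble the full statistics report from a measure summary table and a
    clinical table.

    Sections: baseline FRDA-vs-control comparison (Bonferroni over the
    measure family), Spearman correlations of baseline FRDA measures with
    clinical scores, longitudinal paired changes per group, responsiveness
    (SRM and trial sample size) of the FRDA changes, and - when the epoch
    series are provided - odd/even weekday split-half reliability
    (ICC -> SEM -> MDC95).
    """
    config = config or PipelineConfig()
    m = config.n_families
    report: dict = {
        "group_comparison": {},
        "correlations": {},
        "longitudinal": {},
        "responsiveness": {},
        "reliability": {},
    }
    clin_base = clinical[clinical.visit == "baseline"].set_index("subject_id")

    for placement in ("waist", "wrist"):
        base = _wide(summary, placement, "baseline")
        frda = base[base.group == "FRDA"]
        ctr = base[base.group == "CTR"]
        comp: dict = {}
        pvals = []
        for measure in MEASURES:
            res = cstats.compare_groups(frda[measure], ctr[measure])
            comp[measure] = {
                "test": res.test,
                "statistic": res.statistic,
                "p": res.pvalue,
                "frda_mean": float(frda[measure].mean()),
                "frda_sd": float(frda[measure].std(ddof=1)),
                "ctr_mean": float(ctr[measure].mean()),
                "ctr_sd": float(ctr[measure].std(ddof=1)),
            }
            pvals.append(res.pvalue)
        adj = cstats.bonferroni(pvals, m)
        for measure, p_adj in zip(MEASURES, adj):
            comp[measure]["p_bonferroni"] = float(p_adj)
            comp[measure]["significant"] = bool(p_adj < config.alpha)
        report["group_comparison"][placement] = comp

        # Spearman: FRDA baseline measures vs clinical severity scores
        clin_cols = [c for c in CLINICAL_CORRELATES if c in clin_base.columns]
        frda_clin = clin_base.loc[clin_base.group == "FRDA", clin_cols]
        rho, pval = cstats.spearman_matrix(frda_clin, frda[list(MEASURES)])
        report["correlations"][placement] = {
            c: {
                d: {"rho": _nn(rho.loc[c, d]), "p": _nn(pval.loc[c, d])}
                for d in MEASURES
            }
            for c in rho.index
        }

        # Longitudinal change per group + responsiveness in FRDA
        for group in ("FRDA", "CTR"):
            fu = _wide(summary, placement, "followup")
            gb = base[base.group == group]
            gf = fu[fu.group == group]
            common = gb.index.intersection(gf.index)
            section: dict = {}
            pvals_l = []
            for measure in MEASURES:
                res = cstats.paired_change_test(
                    gb.loc[common, measure], gf.loc[common, measure]
                )
                section[measure] = {
                    "test": res.test,
                    "p": res.pvalue,
                    "mean_change": res.mean_change,
                    "sd_change": res.sd_change,
                    "n": res.n,
                }
                pvals_l.append(res.pvalue)
                if group == "FRDA":
                    try:
                        resp = cstats.responsiveness(
                            (gf.loc[common, measure] - gb.loc[common, measure]).to_numpy(),
                            config.alpha,
                            0.80,
                            config.srm_delta,
                            config.srm_solver,
                        )
                        report["responsiveness"].setdefault(placement, {})[measure] = {
                            "srm": resp.srm,
                            "n_per_arm": resp.n_per_arm,
                            "category": resp.category,
                        }
                    except ValueError:
                        pass
            adj_l = cstats.bonferroni(pvals_l, m)
            for measure, p_adj in zip(MEASURES, adj_l):
                section[measure]["p_bonferroni"] = float(p_adj)
            report["longitudinal"].setdefault(placement, {})[group] = section

    if baseline_series:
        report["reliability"] = _reliability_section(baseline_series, config)
    return report


def _reliability_section(series_list: list[EpochSeries], config: PipelineConfig) -> dict:
    out: dict = {}
    for placement in ("waist", "wrist"):
        pairs_by_measure: dict[str, list] = {measure: [] for measure in MEASURES}
        for series in series_list:
            if series.placement != placement or series.visit != "baseline":
                continue
            try:
                odd, even = cstats.odd_even_split(
                    series, config.cutpoints(), config.min_wear_hours
                )
            except ValueError:
                continue
            for measure in MEASURES:
                pairs_by_measure[measure].append((odd[measure], even[measure]))
        section = {}
        for measure, pairs in pairs_by_measure.items():
            if len(pairs) < 5:
                continue
            try:
                rel = cstats.icc(np.asarray(pairs), split_label="odd_even_weekdays")
            except ValueError:
                continue
            section[measure] = {
                "icc": rel.icc,
                "sem": rel.sem,
                "mdc95": rel.mdc95,
                "n_subjects": rel.n_subjects,
            }
        out[placement] = section
    return out


def _nn(x) -> float | None:
    """NaN -> None for strict JSON."""
    x = float(x)
    return None if np.isnan(x) else x


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _nn(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns ``{"summary": DataFrame, "stats": dict, "paths": {...}}`` and
    writes ``summary.tsv``, ``stats.json`` and ``run_log.txt`` under
    ``config.out_dir``.  Any validation failure raises before partial
    outputs are written.
    """
    out = Path(config.out_dir)

    if config.input_dir is None:
        cohort = simulate_cohort(config.cohort_config())
        summary, flagged_series = summarize_cohort(cohort, config, use_diary=config.use_diary)
        records = cohort.clinical_records
    else:
        records, flagged = _load_input(config)
        summary = _summary_rows(flagged, config)
        flagged_series = [s for s, _ in flagged]
        cohort = None

    if summary.empty:
        raise ValueError("no analyzable series: every recording failed the wear-day rule")

    clinical = pd.DataFrame([dataclasses.asdict(r) for r in records])
    baseline_series = [s for s in flagged_series if s.visit == "baseline"]
    stats_report = cohort_statistics(summary, clinical, config, baseline_series)

    out.mkdir(parents=True, exist_ok=True)
    if cohort is not None and config.write_data:
        cohort.write(out / "data")
    summary_path = out / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6f")
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(_sanitize(stats_report), indent=1, sort_keys=True))
    log_path = out / "run_log.txt"
    log_path.write_text(
        "acticohort pipeline run\nresolved configuration:\n" + config.to_yaml()
    )
    return {
        "summary": summary,
        "stats": stats_report,
        "paths": {"summary": summary_path, "stats": stats_path, "log": log_path},
    }
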