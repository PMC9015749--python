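"""End-to-end pipeline: streams -> indicators -> stratified inference.

Stages: eligibility filtering, daily-vector and cycle construction,
per-household-per-stratum clustering and indicator extraction, then
group comparison (Levene, one-way ANOVA and Tukey-Kramer for the
weekday and season schemes; additive two-way ANOVA plus Tukey over the
season x weekday cells).  Every household inclusion or exclusion
decision is logged with its reason, and the whole run is deterministic
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import occupancy, preprocess, sleep, stats, strata
from .errors import DataError
from .preprocess import DailyMatrix
from .synth import SyntheticHousehold

INDICATOR_NAMES = ("sleep_time", "wake_time", "duration", "minutes_at_home")


@dataclass
class HouseholdRecord:
    """One household's daily matrix plus eligibility metadata."""

    household_id: str
    daily: DailyMatrix
    n_sensors: int | None = None
    n_occupants: int | None = None


@dataclass
class RunConfig:
    scheme: str = "weekday"
    threshold: int = preprocess.DEFAULT_THRESHOLD
    k_max: int = sleep.DEFAULT_K_MAX
    min_cycles: int = sleep.DEFAULT_MIN_CYCLES
    seed: int = 0
    alpha: float = 0.05
    min_days: int = preprocess.MIN_DAYS
    min_sensors: int = preprocess.MIN_SENSORS
    max_occupants: int = preprocess.MAX_OCCUPANTS
    compute_p: bool = True

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.scheme not in strata.SCHEMES:
            raise DataError(f"unknown scheme {self.scheme!r}; one of {strata.SCHEMES}")


@dataclass
class ResultBundle:
    indicators: pd.DataFrame  # long: household_id, scheme, stratum, indicator, value
    summaries: pd.DataFrame
    anova: pd.DataFrame
    tukey: pd.DataFrame
    levene: pd.DataFrame
    log: list[str] = field(default_factory=list)


def records_from_synthetic(
    households: list[SyntheticHousehold], threshold: int = preprocess.DEFAULT_THRESHOLD
) -> list[HouseholdRecord]:
    """Wrap generated households without materializing long-format streams."""
    out = []
    for hh in households:
        daily = preprocess.daily_from_activation(hh.household_id, hh.dates, hh.activation, threshold)
        out.append(
            HouseholdRecord(
                household_id=hh.household_id,
                daily=daily,
                n_sensors=hh.config.n_sensors,
                n_occupants=hh.config.n_occupants,
            )
        )
    return out


def records_from_stream(
    df: pd.DataFrame,
    occupants: dict[str, int] | None = None,
    threshold: int = preprocess.DEFAULT_THRESHOLD,
) -> list[HouseholdRecord]:
    """Build records from a long-format stream; sensor counts come from
    the stream, occupant counts from the optional metadata mapping."""
    matrices = preprocess.daily_from_stream(df, threshold)
    sensors = df.groupby("household_id")["sensor_id"].nunique()
    occupants = occupants or {}
    return [
        HouseholdRecord(
            household_id=hid,
            daily=dm,
            n_sensors=int(sensors.get(hid, 0)) or None,
            n_occupants=occupants.get(hid),
        )
        for hid, dm in matrices.items()
    ]


def records_from_daily(
    matrices: dict[str, DailyMatrix], meta: pd.DataFrame | None = None
) -> list[HouseholdRecord]:
    meta_map = {}
    if meta is not None:
        for _, row in meta.iterrows():
            meta_map[str(row["household_id"])] = (
                int(row["n_sensors"]) if "n_sensors" in row else None,
                int(row["n_occupants"]) if "n_occupants" in row else None,
            )
    out = []
    for hid, dm in matrices.items():
        ns, no = meta_map.get(hid, (None, None))
        out.append(HouseholdRecord(hid, dm, ns, no))
    return out


def compute_indicators(
    records: list[HouseholdRecord], config: RunConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Eligibility-filter households and compute per-stratum indicators."""
    rows: list[dict] = []
    log: list[str] = []
    for rec in records:
        days = rec.daily.n_days
        if not preprocess.check_eligibility(
            days,
            rec.n_sensors,
            rec.n_occupants,
            min_days=config.min_days,
            min_sensors=config.min_sensors,
            max_occupants=config.max_occupants,
        ):
            log.append(
                f"household={rec.household_id} status=excluded reason=ineligible"
                f"(days={days},sensors={rec.n_sensors},occupants={rec.n_occupants})"
            )
            continue
        cycle_dates, cycles, n_gaps = preprocess.build_sleep_cycles(rec.daily)
        if n_gaps:
            log.append(f"household={rec.household_id} status=note gaps_skipped={n_gaps}")
        s_rows, s_log = sleep.household_sleep_rows(
            rec.household_id,
            cycle_dates,
            cycles,
            config.scheme,
            k_max=config.k_max,
            seed=config.seed,
            min_cycles=config.min_cycles,
        )
        h_rows, h_log = occupancy.household_home_rows(
            rec.household_id,
            rec.daily.dates,
            rec.daily.slots,
            config.scheme,
            k_max=config.k_max,
            seed=config.seed,
            min_days=config.min_cycles,
        )
        log.extend(s_log)
        log.extend(h_log)
        log.append(f"household={rec.household_id} status=included days={days}")
        rows.extend(s_rows)
        rows.extend(h_rows)
    if not rows:
        raise DataError("empty cohort: no household produced any indicator")
    df = pd.DataFrame(rows)
    df.insert(1, "scheme", config.scheme)
    return df, log


def indicator_groups(indicators: pd.DataFrame, indicator: str) -> dict[str, np.ndarray]:
    """Per-stratum arrays of household values, canonically ordered."""
    sub = indicators[indicators["indicator"] == indicator]
    groups = {
        stratum: grp["value"].to_numpy(dtype=float)
        for stratum, grp in sub.groupby("stratum", sort=False)
    }
    return {lab: groups[lab] for lab in strata.sorted_labels(groups)}


def run_stats(indicators: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, ...]:
    """Group comparison tables over the indicator data frame.

    Returns ``(summaries, anova, tukey, levene)`` data frames.  The
    season x weekday scheme uses the additive two-way model with Type II
    sums of squares and its residual mean square for the Tukey pairs.
    """
    sum_rows, anova_rows, tukey_rows, levene_rows = [], [], [], []
    for indicator in INDICATOR_NAMES:
        groups = indicator_groups(indicators, indicator)
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        summaries = [stats.summarize(lab, vals) for lab, vals in groups.items()]
        for s in summaries:
            sum_rows.append(
                {"indicator": indicator, "stratum": s.label, "n": s.n, "mean": s.mean, "sd": s.sd}
            )
        try:
            lev = stats.levene(list(groups.values()))
            levene_rows.append({"indicator": indicator, "W": lev.W, "p": lev.p})
        except DataError:
            pass
        if config.scheme == "season_weekday":
            values, f_season, f_wday = [], [], []
            for lab, vals in groups.items():
                season, wday = lab.split(":", 1)
                values.extend(vals)
                f_season.extend([season] * vals.size)
                f_wday.extend([wday] * vals.size)
            results = stats.anova_twoway_additive(values, f_wday, f_season, names=("weekday", "season"))
            resid = next(iter(results.values()))
            for term, res in results.items():
                anova_rows.append(_anova_row(indicator, term, res))
            ms_within, df_within = resid.ms_within, resid.df_within
        else:
            res = stats.anova_oneway(list(groups.values()))
            anova_rows.append(_anova_row(indicator, config.scheme, res))
            ms_within, df_within = res.ms_within, res.df_within
        pairs = stats.tukey_kramer(
            summaries, ms_within, df_within, alpha=config.alpha, with_p=config.compute_p
        )
        for pr in pairs:
            tukey_rows.append(
                {
                    "indicator": indicator,
                    "group1": pr.group1,
                    "group2": pr.group2,
                    "diff": pr.diff,
                    "se": pr.se,
                    "q": pr.q,
                    "ci_low": pr.ci_low,
                    "ci_high": pr.ci_high,
                    "p_adj": pr.p_adj,
                }
            )
    return (
        pd.DataFrame(sum_rows),
        pd.DataFrame(anova_rows),
        pd.DataFrame(tukey_rows),
        pd.DataFrame(levene_rows),
    )


def _anova_row(indicator: str, term: str, res: stats.AnovaResult) -> dict:
    return {
        "indicator": indicator,
        "term": term,
        "ss_between": res.ss_between,
        "df_between": res.df_between,
        "ss_within": res.ss_within,
        "df_within": res.df_within,
        "F": res.F,
        "p": res.p,
    }


def run_pipeline(records: list[HouseholdRecord], config: RunConfig) -> ResultBundle:
    """Full analysis over prepared household records."""
    indicators, log = compute_indicators(records, config)
    summaries, anova, tukey, levene = run_stats(indicators, config)
    return ResultBundle(indicators, summaries, anova, tukey, levene, log)


# ---------------------------------------------------------------------------
# Output writers


def _clock(anchored_min: float) -> str:
    total = int(round(anchored_min + 20 * 60)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


def indicators_wide(indicators: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(household, stratum) table with hh:mm display columns."""
    wide = indicators.pivot_table(
        index=["household_id", "scheme", "stratum"],
        columns="indicator",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    rename = {
        "sleep_time": "sleep_time_min",
        "wake_time": "wake_time_min",
        "duration": "duration_min",
    }
    wide = wide.rename(columns=rename)
    for col in ("sleep_time_min", "wake_time_min", "duration_min", "minutes_at_home"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide["sleep_time_hhmm"] = [
        _clock(v) if np.isfinite(v) else "" for v in wide["sleep_time_min"]
    ]
    wide["wake_time_hhmm"] = [
        _clock(v) if np.isfinite(v) else "" for v in wide["wake_time_min"]
    ]
    order = [
        "household_id",
        "scheme",
        "stratum",
        "sleep_time_min",
        "wake_time_min",
        "duration_min",
        "minutes_at_home",
        "sleep_time_hhmm",
        "wake_time_hhmm",
    ]
    key = wide["stratum"].map(strata.stratum_sort_key)
    wide = wide.assign(_key=key).sort_values(["household_id", "_key"]).drop(columns="_key")
    return wide[order].reset_index(drop=True)


def write_bundle(bundle: ResultBundle, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    writers = {
        "indicators.csv": indicators_wide(bundle.indicators),
        "indicators_long.csv": bundle.indicators,
        "summary.csv": bundle.summaries,
        "anova.csv": bundle.anova,
        "tukey.csv": bundle.tukey,
        "levene.csv": bundle.levene,
    }
    for name, frame in writers.items():
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = path
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(bundle.log) + "\n")
    paths["run_log.txt"] = log_path
    return paths


def summary_report(summaries: list[stats.GroupSummary], alpha: float = 0.05, with_p: bool = True):
    """ANOVA + Tukey tables straight from published (n, mean, sd) rows."""
    anova = stats.anova_oneway_from_summary(summaries)
    pairs = stats.tukey_kramer(summaries, anova.ms_within, anova.df_within, alpha=alpha, with_p=with_p)
    return anova, pairs
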