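"""Synthetic household motion-sensor streams with a known truth ledger.

Generates 5-minute per-sensor activation streams shaped like a
smart-thermostat motion export: every sensor reports 0/1 at every grid
point.  Each simulated day has a ground-truth schedule — nightly sleep
block, optional daytime away blocks, weekday-specific means and seasonal
offsets — so downstream inference can be checked against a recoverable
truth.

Model
-----
Occupants act as a single household unit.  While the household is home
and awake each sensor fires independently per 5-minute interval with
probability ``1 - (1 - p_active)^n_occupants`` (``p_active`` is the
per-occupant rate); during sleep and away blocks it fires with the false
-activation rate ``p_noise``.  Daily schedules are drawn independently
across days around weekday-specific means, shifted additively by the
season of the calendar date.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .strata import assign_season

GRID_MIN = 5
INTERVALS_PER_DAY = 24 * 60 // GRID_MIN  # 288

STATE_AWAKE = 0
STATE_SLEEP = 1
STATE_AWAY = 2

# clamp bounds for drawn schedules (minutes after midnight of the
# anchoring day); sleep may start no earlier than 20:00 and waking must
# happen before noon for the cycle window to capture it
_ONSET_MIN, _ONSET_MAX = 20 * 60, 24 * 60 + 11 * 60
_WAKE_MIN, _WAKE_MAX = 5, 12 * 60 - 5

STREAM_COLUMNS = ("household_id", "timestamp", "sensor_id", "motion")
TRUTH_COLUMNS = ("household_id", "date", "sleep_onset_min", "wake_min", "away_min")


@dataclass(frozen=True)
class AwayBlock:
    """Recurring absence: on the given weekdays (0=Mon..6=Sun), with the
    given probability, the household is away from ``start_min`` for
    ``duration_min`` minutes."""

    weekdays: frozenset
    start_min: int
    duration_min: int
    probability: float = 1.0


@dataclass(frozen=True)
class HouseholdConfig:
    household_id: str = "hh"
    n_sensors: int = 6
    n_occupants: int = 2
    n_days: int = 305
    start_date: dt.date = dt.date(2018, 1, 1)
    #: per-weekday (Mon..Sun) mean sleep onset, minutes after midnight of
    #: the onset day; values past 1440 mean falling asleep after midnight
    sleep_onset_mean: tuple = (1380,) * 7
    #: per-weekday mean wake-up, minutes after midnight of the waking day
    wake_mean: tuple = (420,) * 7
    schedule_sd: float = 0.0
    #: additive minutes by season, applied to onset/wake and away length
    season_offsets: dict = field(default_factory=dict)
    away_blocks: tuple = ()
    p_active: float = 0.8
    p_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.household_id:
            raise ConfigError("household_id", "must be non-empty")
        if self.n_sensors < 1:
            raise ConfigError("n_sensors", f"must be >= 1, got {self.n_sensors}")
        if self.n_occupants < 1:
            raise ConfigError("n_occupants", f"must be >= 1, got {self.n_occupants}")
        if self.n_days < 1:
            raise ConfigError("n_days", f"must be >= 1, got {self.n_days}")
        if not (0.0 < self.p_active <= 1.0):
            raise ConfigError("p_active", f"must be in (0, 1], got {self.p_active}")
        if not (0.0 <= self.p_noise < self.p_active):
            raise ConfigError("p_noise", f"must satisfy 0 <= p_noise < p_active, got {self.p_noise}")
        for name, arr in (("sleep_onset_mean", self.sleep_onset_mean), ("wake_mean", self.wake_mean)):
            if len(arr) != 7:
                raise ConfigError(name, "needs exactly 7 per-weekday values")
        for i in range(7):
            if not (self.wake_mean[i] < self.sleep_onset_mean[i]):
                raise ConfigError("wake_mean", f"weekday {i}: wake must precede the next sleep onset")
        if self.schedule_sd < 0:
            raise ConfigError("schedule_sd", "must be >= 0")
        for b in self.away_blocks:
            if not (0.0 <= b.probability <= 1.0):
                raise ConfigError("away_blocks", f"probability {b.probability} outside [0, 1]")
            if b.duration_min < 0 or not (0 <= b.start_min < 1440):
                raise ConfigError("away_blocks", "start must be a clock minute, duration >= 0")
        for season in self.season_offsets:
            if season not in ("winter", "spring", "summer", "fall"):
                raise ConfigError("season_offsets", f"unknown season {season!r}")

    @property
    def p_household(self) -> float:
        """Effective per-sensor firing rate with all occupants home and awake."""
        return 1.0 - (1.0 - self.p_active) ** self.n_occupants


@dataclass
class SyntheticHousehold:
    """One generated stream plus its ground truth.

    ``activation`` is an (n_sensors, n_days * 288) 0/1 matrix over the
    5-minute grid; ``states`` holds the per-interval occupant state
    (awake-home / sleep / away); ``truth`` has one row per complete
    sleep cycle: the onset of the night starting on ``date`` (minutes
    after midnight of that day), the wake-up the next morning (minutes
    after midnight of the next day), and the away minutes of ``date``.
    """

    config: HouseholdConfig
    dates: list
    activation: np.ndarray
    states: np.ndarray
    truth: pd.DataFrame

    @property
    def household_id(self) -> str:
        return self.config.household_id

    def to_readings(self) -> pd.DataFrame:
        """Full-grid long-format stream (one row per sensor per grid point)."""
        cfg = self.config
        t = self.activation.shape[1]
        base = pd.Timestamp(cfg.start_date)
        times = base + pd.to_timedelta(np.arange(t) * GRID_MIN, unit="m")
        frames = []
        for s in range(cfg.n_sensors):
            frames.append(
                pd.DataFrame(
                    {
                        "household_id": cfg.household_id,
                        "timestamp": times,
                        "sensor_id": f"s{s:02d}",
                        "motion": self.activation[s],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True).sort_values(
            ["timestamp", "sensor_id"], kind="stable", ignore_index=True
        )

    def daily_true_away_minutes(self) -> np.ndarray:
        st = self.states.reshape(self.config.n_days, INTERVALS_PER_DAY)
        return (st == STATE_AWAY).sum(axis=1) * GRID_MIN


def _season_offset(cfg: HouseholdConfig, date: dt.date) -> float:
    season = assign_season(date)
    return float(cfg.season_offsets.get(season, 0.0)) if season else 0.0


def generate_household(config: HouseholdConfig) -> SyntheticHousehold:
    """Simulate one household; identical config (incl. seed) => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_days = config.n_days
    total = n_days * INTERVALS_PER_DAY
    dates = [config.start_date + dt.timedelta(days=i) for i in range(n_days)]
    weekdays = np.array([d.weekday() for d in dates])
    offsets = np.array([_season_offset(config, d) for d in dates])

    wake_noise = rng.normal(0.0, config.schedule_sd, size=n_days) if config.schedule_sd else np.zeros(n_days)
    onset_noise = rng.normal(0.0, config.schedule_sd, size=n_days) if config.schedule_sd else np.zeros(n_days)
    wake = np.clip(
        np.array([config.wake_mean[w] for w in weekdays]) + offsets + wake_noise,
        _WAKE_MIN,
        _WAKE_MAX,
    )
    onset = np.clip(
        np.array([config.sleep_onset_mean[w] for w in weekdays]) + offsets + onset_noise,
        _ONSET_MIN,
        _ONSET_MAX,
    )
    # a night must end after it starts: cap onset below the next wake
    onset[:-1] = np.minimum(onset[:-1], 1440.0 + wake[1:] - 2 * GRID_MIN)

    states = np.zeros(total, dtype=np.uint8)
    # morning of day 0 sleeps until its drawn wake-up
    states[: int(wake[0] // GRID_MIN)] = STATE_SLEEP
    for i in range(n_days):
        a = i * INTERVALS_PER_DAY + int(onset[i] // GRID_MIN)
        if i + 1 < n_days:
            b = (i + 1) * INTERVALS_PER_DAY + int(wake[i + 1] // GRID_MIN)
        else:
            b = total
        states[a:b] = STATE_SLEEP

    for i in range(n_days):
        for block in config.away_blocks:
            if weekdays[i] not in block.weekdays:
                continue
            if rng.random() >= block.probability:
                continue
            dur = max(0.0, block.duration_min + _season_offset(config, dates[i]))
            lo = i * INTERVALS_PER_DAY + block.start_min // GRID_MIN
            hi = min(total, lo + int(dur // GRID_MIN))
            seg = states[lo:hi]
            seg[seg == STATE_AWAKE] = STATE_AWAY

    p_interval = np.where(states == STATE_AWAKE, config.p_household, config.p_noise)
    activation = (rng.random((config.n_sensors, total)) < p_interval).astype(np.uint8)

    away = (states.reshape(n_days, INTERVALS_PER_DAY) == STATE_AWAY).sum(axis=1) * GRID_MIN
    truth = pd.DataFrame(
        {
            "household_id": config.household_id,
            "date": dates[: n_days - 1],
            "sleep_onset_min": onset[: n_days - 1],
            "wake_min": wake[1:],
            "away_min": away[: n_days - 1],
        }
    )
    return SyntheticHousehold(config=config, dates=dates, activation=activation, states=states, truth=truth)


#: heterogeneity keys supported by generate_cohort; each is an SD of an
#: additive household-level deviation from the template value
COHORT_FIELDS = ("sleep_onset_mean", "wake_mean", "schedule_sd", "p_active", "p_noise")


def generate_cohort(
    n_households: int,
    template: HouseholdConfig,
    heterogeneity: dict | None = None,
    seed: int = 0,
) -> list[SyntheticHousehold]:
    """Simulate a cohort with household-level parameter heterogeneity.

    Household parameters are the template's, plus Normal(0, sd) shifts
    for each field named in ``heterogeneity``; per-household seeds are
    spawned deterministically from the master ``seed``.
    """
    if n_households < 1:
        raise ConfigError("n_households", f"must be >= 1, got {n_households}")
    heterogeneity = dict(heterogeneity or {})
    for key in heterogeneity:
        if key not in COHORT_FIELDS:
            raise ConfigError("heterogeneity", f"unsupported field {key!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_households + 1)
    prng = np.random.default_rng(children[0])
    out = []
    for h in range(n_households):
        changes: dict = {
            "household_id": f"{template.household_id}{h:04d}",
            "seed": int(children[h + 1].generate_state(1)[0]),
        }
        if heterogeneity.get("sleep_onset_mean"):
            shift = prng.normal(0.0, heterogeneity["sleep_onset_mean"])
            changes["sleep_onset_mean"] = tuple(v + shift for v in template.sleep_onset_mean)
        if heterogeneity.get("wake_mean"):
            shift = prng.normal(0.0, heterogeneity["wake_mean"])
            changes["wake_mean"] = tuple(v + shift for v in template.wake_mean)
        if heterogeneity.get("schedule_sd"):
            changes["schedule_sd"] = max(0.0, template.schedule_sd + prng.normal(0.0, heterogeneity["schedule_sd"]))
        if heterogeneity.get("p_active"):
            changes["p_active"] = float(
                np.clip(template.p_active + prng.normal(0.0, heterogeneity["p_active"]), template.p_noise + 1e-6, 1.0)
            )
        if heterogeneity.get("p_noise"):
            changes["p_noise"] = float(
                np.clip(template.p_noise + prng.normal(0.0, heterogeneity["p_noise"]), 0.0, template.p_active - 1e-6)
            )
        out.append(generate_household(dataclasses.replace(template, **changes)))
    return out


# ---------------------------------------------------------------------------
# I/O


def write_stream_csv(households, path) -> None:
    """Write one or many households as the long-format stream CSV."""
    if isinstance(households, SyntheticHousehold):
        households = [households]
    frames = [hh.to_readings() for hh in households]
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, columns=list(STREAM_COLUMNS))


def write_truth_csv(households, path) -> None:
    if isinstance(households, SyntheticHousehold):
        households = [households]
    df = pd.concat([hh.truth for hh in households], ignore_index=True)
    df.to_csv(path, index=False, columns=list(TRUTH_COLUMNS))


def write_households_csv(households, path) -> None:
    """Metadata sidecar: sensor and occupant counts per household."""
    rows = [
        {
            "household_id": hh.household_id,
            "n_sensors": hh.config.n_sensors,
            "n_occupants": hh.config.n_occupants,
        }
        for hh in households
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_config_from_yaml(path) -> tuple[int, HouseholdConfig, dict]:
    """Load ``(n_households, template, heterogeneity)`` from a YAML file.

    The file has keys ``n_households``, ``heterogeneity`` (optional) and
    ``template`` whose entries mirror :class:`HouseholdConfig`;
    ``away_blocks`` entries are mappings with ``weekdays``, ``start_min``,
    ``duration_min`` and ``probability``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or raw.get("template") is None:
        raise ConfigError("config", "expected a mapping with a 'template' section")
    tpl = dict(raw.get("template") or {})
    if "start_date" in tpl and not isinstance(tpl["start_date"], dt.date):
        tpl["start_date"] = dt.date.fromisoformat(str(tpl["start_date"]))
    for key in ("sleep_onset_mean", "wake_mean"):
        if key in tpl:
            tpl[key] = tuple(tpl[key])
    if "away_blocks" in tpl:
        tpl["away_blocks"] = tuple(
            AwayBlock(
                weekdays=frozenset(b["weekdays"]),
                start_min=int(b["start_min"]),
                duration_min=int(b["duration_min"]),
                probability=float(b.get("probability", 1.0)),
            )
            for b in tpl["away_blocks"]
        )
    unknown = set(tpl) - {f.name for f in dataclasses.fields(HouseholdConfig)}
    if unknown:
        raise ConfigError("template", f"unknown fields: {sorted(unknown)}")
    template = HouseholdConfig(**tpl)
    n_households = int(raw.get("n_households", 1))
    heterogeneity = dict(raw.get("heterogeneity") or {})
    return n_households, template, heterogeneity
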