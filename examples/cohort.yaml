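# Example synthetic cohort: 20 households over a full year with a
# weekday/weekend schedule split, seasonal shifts and workday absences.
n_households: 20
heterogeneity:
  sleep_onset_mean: 20 # SD (minutes) of household-level onset shifts
  wake_mean: 15
template:
  household_id: hh
  n_sensors: 6
  n_occupants: 2
  n_days: 365
  start_date: 2018-01-01
  # Mon..Sun means, minutes after midnight (Fri/Sat onset 30 min later)
  sleep_onset_mean: [1380, 1380, 1380, 1380, 1410, 1410, 1380]
  wake_mean: [420, 420, 420, 420, 420, 465, 465]
  schedule_sd: 15
  season_offsets: { winter: 10, spring: 0, summer: -10, fall: 0 }
  away_blocks:
    - { weekdays: [0, 1, 2, 3, 4], start_min: 540, duration_min: 480, probability: 0.85 }
  p_active: 0.7
  p_noise: 0.02
  seed: 1
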