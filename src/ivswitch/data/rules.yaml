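# Default trigger-rule configuration.
# Windows are half-open [lo, hi) hours elapsed since the order start,
# evaluated at the daily run time.  Lab thresholds in 10^9 cells per litre.
first_window_hours: [48, 72]
second_window_hours: [96, 120]
neutrophil_threshold: 0.5
leukocyte_threshold: 1.0
severe_infection_agents: [meropenem, imipenem, ertapenem]
high_dose_is_severe: true
max_reminders: 2
run_time_of_day: "07:00:00"
weekend_days: [5, 6]          # Mon=0 .. Sun=6
crp_mode: previous            # comparator for "CRP increasing": previous | minimum | first
switch_detection_window_hours: 24
protocol_map:
  ceftriaxone: ["amoxicillin/clavulanic acid"]
  cefotaxim: ["amoxicillin/clavulanic acid"]
  ciprofloxacin: [ciprofloxacin]
  clindamycin: [clindamycin]
  metronidazole: [metronidazole]
  fluconazole: [fluconazole]
  amoxicillin: [amoxicillin]
  flucloxacillin: [flucloxacillin]
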