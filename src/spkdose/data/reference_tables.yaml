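# Reference defaults for the bottom tier of the missing-data cascade.
# These are editable placeholders: age-graded 24-h urine outputs in the
# 500-700 mL range and body weights bracketing 14-23 kg for ages 3-6.
# Override per run with --reference-tables when better data are available.
default_void_volume_ml_per_24h:
  "3": {m: 500.0, f: 500.0}
  "4": {m: 550.0, f: 540.0}
  "5": {m: 600.0, f: 590.0}
  "6": {m: 650.0, f: 640.0}
default_body_weight_kg:
  "3": {m: 15.5, f: 15.0}
  "4": {m: 17.5, f: 17.0}
  "5": {m: 19.5, f: 19.0}
  "6": {m: 22.0, f: 21.5}
# Scheduled void times on the study clock (hours since midnight of day 1).
default_event_times_hr:
  bedtime: 21.0        # 21:00 day 1
  first_morning: 31.0  # 07:00 day 2
  lunch: 36.0          # 12:00 day 2
  dinner: 43.0         # 19:00 day 2
exposure_time_hr: 19.0 # dinner bolus, 19:00 day 1
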