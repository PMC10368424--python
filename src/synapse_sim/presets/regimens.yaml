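# Dosing-regimen presets (continuous infusion, ug/day, one entry per week
# of a 22-week course).  SYNTHETIC presets: the high dose in scheme 1
# follows the approved blinatumomab pattern for B-ALL (9 ug/day in week 1 of
# cycle 1, then 28 ug/day; 4-week-on / 2-week-off cycles); medium and low
# scale the post-ramp rate down, and scheme 2 is an alternating-week variant
# that delivers a lower cumulative dose at the same rate.  Edit freely.

scheme1_high:
  scheme: 1
  dose_level: high
  weekly_ug_per_day: [9, 28, 28, 28, 0, 0,
                      28, 28, 28, 28, 0, 0,
                      28, 28, 28, 28, 0, 0,
                      28, 28, 28, 28]

scheme1_medium:
  scheme: 1
  dose_level: medium
  weekly_ug_per_day: [3, 9, 9, 9, 0, 0,
                      9, 9, 9, 9, 0, 0,
                      9, 9, 9, 9, 0, 0,
                      9, 9, 9, 9]

scheme1_low:
  scheme: 1
  dose_level: low
  weekly_ug_per_day: [1, 3, 3, 3, 0, 0,
                      3, 3, 3, 3, 0, 0,
                      3, 3, 3, 3, 0, 0,
                      3, 3, 3, 3]

scheme2_high:
  scheme: 2
  dose_level: high
  weekly_ug_per_day: [9, 28, 0, 28, 0, 28,
                      0, 28, 0, 28, 0, 28,
                      0, 28, 0, 28, 0, 28,
                      0, 28, 0, 28]

scheme2_medium:
  scheme: 2
  dose_level: medium
  weekly_ug_per_day: [3, 9, 0, 9, 0, 9,
                      0, 9, 0, 9, 0, 9,
                      0, 9, 0, 9, 0, 9,
                      0, 9, 0, 9]

scheme2_low:
  scheme: 2
  dose_level: low
  weekly_ug_per_day: [1, 3, 0, 3, 0, 3,
                      0, 3, 0, 3, 0, 3,
                      0, 3, 0, 3, 0, 3,
                      0, 3, 0, 3]
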