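# Default lap/segment schedule for the 21-min varying-terrain treadmill session.
#
# Seven identical 3-min laps, four segments per lap: moderate uphill (5%),
# flat (2%), steep uphill (12%) and a simulated downhill where the skier
# holds a rope in a tuck.  Per-segment durations and speeds are an
# approximate reconstruction calibrated so that the time-weighted mean
# speed (with the downhill display-speed substitution of 30/35 km/h) is
# exactly 16.7 km/h at LI and 21.3 km/h at HI, giving session totals of
# 5.8 / 7.5 km over 1260 s.  The treadmill itself runs the downhill at
# 20 km/h at both intensities.
laps: 7
lap_duration_s: 180
downhill_display_speed_li_kmh: 30.0
downhill_display_speed_hi_kmh: 35.0
segments:
  - incline_pct: 5.0
    speed_li_kmh: 15.0
    speed_hi_kmh: 20.0
    duration_s: 60
  - incline_pct: 2.0
    speed_li_kmh: 16.0
    speed_hi_kmh: 21.0
    duration_s: 45
  - incline_pct: 12.0
    speed_li_kmh: 10.8
    speed_hi_kmh: 14.2
    duration_s: 45
  - incline_pct: -10.0
    speed_li_kmh: 20.0
    speed_hi_kmh: 20.0
    duration_s: 30
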