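"""Session schedule: lap/segment structure and whole-session totals.

Builds the packaged 7 x 3-min varying-terrain protocol and reports the
distance and mean speed of the low- and high-intensity sessions, using the
downhill display-speed substitution (the treadmill runs the simulated
downhill at a safe 20 km/h while the skier rests in a tuck holding a rope,
so a realistic downhill speed is substituted when totalling distance).
"""

import skifuse as sf

protocol = sf.default_protocol()
print(f"{protocol.laps} laps x {protocol.lap_duration:.0f} s "
      f"= {protocol.total_duration:.0f} s total")
for seg in protocol.segments:
    print(f"  segment {seg.index}: incline {seg.incline:+.0%}, "
          f"{seg.duration:.0f} s, LI {seg.speed_li} km/h / HI {seg.speed_hi} km/h")

for intensity in ("LI", "HI"):
    distance, speed = sf.session_distance_and_speed(protocol, intensity)
    print(f"{intensity}: {distance} km at a mean {speed} km/h")

w = sf.segment_at(protocol, 400.0)
print(f"t = 400 s falls in lap {w.lap}, segment {w.segment} "
      f"(window [{w.start:.0f}, {w.end:.0f}) s)")
# Expected output: LI totals 5.8 km / 16.7 km/h and HI 7.5 km / 21.3 km/h —
# the whole-session workload difference between the two training intensities.
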