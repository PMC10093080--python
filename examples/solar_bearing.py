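"""Turn a dance angle into a compass bearing via the solar azimuth.

A dancer waggling 40 degrees clockwise of vertical at midday points 40
degrees clockwise of the sun's azimuth; the bearing drifts with the sun
through the session, which is why the azimuth is evaluated per phase.
"""

from datetime import datetime, timedelta, timezone

from dancemap import bearing_from_dance, solar_position

lat, lon = 46.15, -0.64
angle_from_vertical = 40.0

t = datetime(2022, 6, 21, 10, 49, tzinfo=timezone.utc)  # 12:49 local (CEST)
for k in range(3):
    sp = solar_position(t, lat, lon)
    bearing = bearing_from_dance(angle_from_vertical, sp.azimuth_deg)
    print(f"{t.isoformat()}  solar azimuth {sp.azimuth_deg:6.2f} deg, "
          f"elevation {sp.elevation_deg:5.2f} deg -> bearing {bearing:6.2f} deg")
    t += timedelta(minutes=5)
# Over the 10-minute session the azimuth (and hence every decoded bearing)
# advances about 2-3 degrees.
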