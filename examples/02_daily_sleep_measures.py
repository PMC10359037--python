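"""Derive sleep measures for hand-constructed activity days.

Shows the three primitives on a single constructed example: the inferred
sleep period (longest daily inactivity run), the expected sleep period
(longest circular inactivity run of a binarized 30-day profile), and the
overlap/disruption measures that compare the two.
"""

import numpy as np

from sleeptap import compute_esp, compute_isp, count_disruptions, overlap_percentage
from sleeptap.sleep import binarize_window

# a 30-day activity-fraction profile: quiet from 23:00 to 07:00, busy daytime
rng = np.random.default_rng(0)
profile = np.where((np.arange(96) < 28) | (np.arange(96) >= 92), 0.08, 0.75)
profile += rng.normal(0, 0.02, 96).clip(-0.05, 0.05)
profile = profile.clip(0, 1)

binarized = binarize_window(profile)
esp = compute_esp(binarized)
print(f"ESP: starts at bin {esp.start_bin} ({esp.start_bin * 15 // 60:02d}:"
      f"{esp.start_bin * 15 % 60:02d}), {esp.duration_h:.2f} h, "
      f"crosses midnight: {esp.circular}")

# one day: slept 00:30-07:30 with two nocturnal phone checks
day = np.ones(96, dtype=int)
day[2:30] = 0
day[[9, 17]] = 1
isp = compute_isp(day)
print(f"ISP: bin {isp.start_bin}, {isp.length} bins ({isp.duration_h:.2f} h)")
print(f"overlap: {overlap_percentage(isp, esp):.0%} of the ISP inside the ESP")
print(f"disruptions: {count_disruptions(day, esp)} active bins inside the ESP")
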