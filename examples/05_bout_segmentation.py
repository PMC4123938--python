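"""Bout segmentation with the >5-second rule.

Builds a small hand-written stream of 1-s behavior samples and shows how
the segmentation rule handles interruptions: a gap of 5 s or less (or a
different behavior not sustained for more than 5 s) does not end a bout,
while anything longer splits or switches it.  Durations are in seconds.
"""

from coopgis.ethogram import segment_bouts
from coopgis.io import BehaviorAnnotation


def stream(*chunks):
    out = []
    for label, start, end in chunks:
        if label is not None:
            out += [BehaviorAnnotation("H01", float(t), "behavior", label)
                    for t in range(start, end)]
    return out


cases = {
    "4-s gap inside feeding (merges)": stream(("feed", 0, 30), ("feed", 34, 60)),
    "6-s gap inside feeding (splits)": stream(("feed", 0, 30), ("feed", 36, 60)),
    "3-s preen inside feeding (absorbed)": stream(
        ("feed", 0, 10), ("preen", 10, 13), ("feed", 13, 40)
    ),
    "7-s preen inside feeding (new bout)": stream(
        ("feed", 0, 10), ("preen", 10, 17), ("feed", 17, 30)
    ),
}

for name, anns in cases.items():
    bouts = segment_bouts(anns)
    desc = ", ".join(f"{b.label} [{b.start:.0f}, {b.end:.0f}) = {b.duration:.0f} s"
                     for b in bouts)
    print(f"{name}:\n  {desc}")
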