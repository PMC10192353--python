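"""Apply the semiquantitative fundus-spot scale to per-quadrant counts.

Each eye grades 0-4 (no spots; 1-10 spots; one quadrant involved; two to
three quadrants; all four quadrants) and the two eyes sum to 0-8 per mouse.
"""

from fundusmap import FundusExam, score_eye, score_mouse

examples = [
    ("clear fundus", (0, 0, 0, 0)),
    ("7 scattered spots", (7, 0, 0, 0)),
    ("one heavy quadrant", (15, 1, 0, 0)),
    ("two involved quadrants", (8, 7, 1, 0)),
    ("spots everywhere", (20, 20, 20, 20)),
]

scores = []
for label, counts in examples:
    s = score_eye(FundusExam("demo", "OD", counts))
    scores.append(s)
    print(f"{label:26s} quadrant counts {counts} -> eye score {s}")

mouse = score_mouse(scores[1], scores[4])
print(f"\nmouse with eyes scoring {scores[1]} and {scores[4]} -> per-mouse score {mouse} (scale 0-8)")
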