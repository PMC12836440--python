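"""Estimate the box-counting dimension of three known-dimension fixtures.

A 1-pixel curve should come out near 1, a filled region near 2, and the
depth-5 Sierpinski carpet near its exact dimension log 8 / log 3 ~ 1.8928.
Agreement on these fixtures is what justifies trusting the estimator on
trabecular skeletons, whose true dimension is unknown.
"""

import math

from condylefd import fractal_dimension, make_filled_rect, make_line, make_sierpinski_carpet

carpet = fractal_dimension(make_sierpinski_carpet(5), box_sizes=[1, 3, 9, 27, 81])
line = fractal_dimension(make_line(243))
square = fractal_dimension(make_filled_rect(243, 243))

print(f"Sierpinski carpet: fd = {carpet.fd:.4f}  (exact {math.log(8) / math.log(3):.4f}, "
      f"r^2 = {carpet.r_squared:.4f})")
print(f"straight line:     fd = {line.fd:.4f}  (expected ~1)")
print(f"filled square:     fd = {square.fd:.4f}  (expected ~2)")
print()
print("carpet box sizes:", carpet.box_sizes)
print("carpet counts:   ", carpet.counts, "(each step of 3x in size divides counts by 8)")
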