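"""Exercise the sO2 display palette and locate its color boundaries.

The clinical display renders oxygen saturation below 85% in red (grading
to magenta at extreme hypoxia), leaves the normal band [85, 90]% fully
transparent so the grayscale anatomy shows through, and renders values
above 90% in green (grading to cyan at the arterial extreme).
"""

from oabreast.render import PaletteSpec, classify_so2

palette = PaletteSpec()
for value in (30.0, 80.0, 85.0, 88.0, 90.0, 95.0, 99.5):
    print(f"sO2 {value:5.1f}%  ->  {classify_so2(value, palette)}")


def bisect(lo, hi, tol=0.005):
    c_lo = classify_so2(lo, palette)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if classify_so2(mid, palette) == c_lo else (lo, mid)
    return 0.5 * (lo + hi)


print(f"\nred/transparent boundary:   {bisect(70.0, 88.0):.3f}%")
print(f"transparent/green boundary: {bisect(88.0, 95.0):.3f}%")
print("These anchors (85 and 90) delimit the no-color band of normally "
      "oxygenated tissue.")
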