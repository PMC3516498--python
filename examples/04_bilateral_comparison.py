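"""Compare an operated orbit against its healthy contralateral side.

The left orbit is shrunk 10% in every dimension (emulating post-surgical
volume loss); both sides are measured, a 3-rater x 3-repeat area table is
simulated around the measurements, and each slice is tested with a paired
t-test (n = 9 same-rater same-repeat pairs, alpha = 0.05, flagged only
when the operated side is significantly SMALLER).  The flag pattern
classifies the case: A = slices 1-4 (or all 5) significant, B = 1-3,
C = none.
"""

import numpy as np

from orbitovol import (
    PhantomSpec,
    classify_case,
    generate_phantom,
    make_asymmetric_pair,
    measure_orbit,
    simulate_repeated_measures,
    slice_significance,
)

spec = make_asymmetric_pair(PhantomSpec(), shrink_fraction=0.1, side="left")
vol, _ = generate_phantom(spec)
operated = measure_orbit(vol, "left", (-25.0, 0.0, 0.0))
healthy = measure_orbit(vol, "right", (25.0, 0.0, 0.0))

rng = np.random.default_rng(0)
rm = simulate_repeated_measures(
    {"left": operated.areas_mm2, "right": healthy.areas_mm2},
    noise_sd=10.0,  # mm^2 of human re-tracing variability
    rng=rng,
)
pattern = slice_significance(rm, operated_side="left")
category = classify_case(pattern)

print("slice  operated_mm2  healthy_mm2        p  significant")
for k, (a, b, p, f) in enumerate(
    zip(operated.areas_mm2, healthy.areas_mm2, pattern.p_values, pattern.flags), 1
):
    print(f"{k:>5} {a:13.1f} {b:12.1f} {p:9.2g}  {'yes' if f else 'no'}")
print(f"\noperated volume: {operated.volume_mm3:8.1f} mm^3")
print(f"healthy volume : {healthy.volume_mm3:8.1f} mm^3")
print(f"category: {category.category} ({category.n_significant} significant slices)")
print("A 10% unilateral shrinkage is flagged on every slice: category A,")
print("the pattern of clear post-operative volume deficit.")
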