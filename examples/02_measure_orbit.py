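"""Measure one orbit: five coronal slices, areas in mm^2, Cavalieri volume.

Slices are taken at 4.8 mm intervals dorsally from the orbital frame
plane.  On each slice the bony contour is closed (bridging wall openings
with chords), flood-filled, and its area measured as pixel count times
pixel area; the orbit volume is interval x sum of areas.
"""

from orbitovol import PhantomSpec, generate_phantom, measure_orbit

spec = PhantomSpec()
vol, gt = generate_phantom(spec)
m = measure_orbit(vol, "right", seed_point=(25.0, 0.0, 0.0))

print("slice  depth_mm   area_mm2   analytic   err%   bridged")
for s in m.slices:
    depth = -s.plane_position
    ref = gt.area("right", depth)
    print(
        f"{s.slice_index:>5}  {depth:8.2f} {s.area_mm2:10.2f} {ref:10.2f}"
        f" {100 * (s.area_mm2 / ref - 1):+6.2f}   {len(s.bridged_segments)}"
    )

d1, dn = -m.slices[0].plane_position, -m.slices[-1].plane_position
ref_vol = gt.slab_reference_volume("right", d1 - 2.4, dn + 2.4)
print(f"\nCavalieri volume: {m.volume_mm3:9.1f} mm^3")
print(f"analytic slab   : {ref_vol:9.1f} mm^3 ({100*(m.volume_mm3/ref_vol-1):+.2f}%)")
print("Measured areas track the analytic cone cross-sections to a fraction")
print("of a percent; slices 4-5 cross the fissure openings, hence bridges.")
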