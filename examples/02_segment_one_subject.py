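"""Segment one subject: changepoints, intervention times, TOI/transition windows.

Shows the two-stage segmentation: exact penalized changepoint detection with
a piecewise-linear cost, then the marker-guided windowing that turns the
changepoints into optimal TOIs separated by artifact-absorbing transition
windows of half-width k.
"""

from toiseg import SimulationDesign, algorithm1, default_penalty, pelt_segment, simulate_subject

design = SimulationDesign(seed=7)
rec = simulate_subject(design, "control", "male", subject_seed=7)

penalty = default_penalty(rec.values)
print(f"auto penalty: beta={penalty.beta:.0f} (noise scale {penalty.sigma_hat:.1f})")

cpts = pelt_segment(rec.values, penalty)
print(f"changepoints (with 0/{rec.n} sentinels): {cpts.positions.tolist()}")

seg = algorithm1(cpts, rec)
print(f"k = {seg.k} (post-basal changepoint count -> window half-width)")
print(f"intervention times: {seg.it_times[1:].astype(int).tolist()}  (true boundaries 301, 601)")
print(f"optimal TOIs: {seg.otoi}")
print(f"transition windows: {seg.ott}")
# Every sample in a transition window [IT-k, IT+k] is excluded from all
# downstream statistics: that is where the intervention artifacts live.
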