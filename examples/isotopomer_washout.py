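"""Isotopomer washout: predicted [18O]Pi species distributions over time.

Starting from the measured label distribution on the gamma-phosphoryl of
substrate ATP (57/17/2/24 % with 3/2/1/0 labels), the constant-rate event
chain predicts how the four Pi species evolve as exchange proceeds.
"""

from oxex import LabelDistribution, isotopomer_distribution, mean_label_count

initial = LabelDistribution(57.0, 17.0, 2.0, 24.0)
print(f"initial distribution, mean labels/Pi = {mean_label_count(initial):.2f}")
print()
print("   kt     %3-label  %2-label  %1-label  %0-label   mean")
for kt in (0.0, 0.25, 0.5, 1.0, 2.0, 5.0):
    d = isotopomer_distribution(initial, kt)
    print(
        f"{kt:5.2f} {d.p3:10.2f} {d.p2:9.2f} {d.p1:9.2f} {d.p0:9.2f}"
        f" {mean_label_count(d):6.3f}"
    )
print()
print("Each exchange event replaces one 18O with a water 16O, so the")
print("triple-labeled pool decays as e^-kt and everything drains into the")
print("unlabeled pool; kt = k * n / v couples the curve to ATP concentration.")
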