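"""Exact progeny sex ratios under an active-Y system.

Enumerates every gamete and offspring genotype with rational
arithmetic; any offspring carrying at least one Y chromosome is male.
"""

import sdrmap as sm

for cross, label in [
    ("XXxXY", "standard diploid outcross"),
    ("XY_selfed", "fruiting inconstant male, selfed"),
    ("XXXXxXXYY", "tetraploid female x colchicine-doubled male"),
]:
    ratio = sm.expected_sex_ratio(cross)
    print(f"{cross:10s} ({label}): male:female = {ratio:g}:1")

print()
print("The 3:1 selfed ratio arises because XX:XY:YY segregate 1:2:1 and")
print("both Y-bearing classes are male; the tetraploid 5:1 because only")
print("1 of the 6 balanced XXYY gametes is X-only (XX:XY:YY = 1:4:1).")
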