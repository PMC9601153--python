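"""Closed-form detectability limits: how small can a shared module be?

No graphs are needed here — the ideal case (the walker captures every module
node with no stray visits in both graphs) has a closed-form p-value bound
4*(4/|V|)^(|S|-2), and inverting it gives the minimal module size that can
reach a wanted significance level.
"""

import ctdpair as cp

print("ideal-case p-value bound, |V| = 1000:")
for s in range(2, 8):
    print(f"  |S| = {s}: p <= {cp.ideal_bound(1000, s):.3e}")

print()
print("minimal detectable module size:")
for n in (100, 1000, 10000):
    for p in (0.05, 5e-10):
        print(f"  |V| = {n:>6}, p_wanted = {p:<8g} -> |S| >= {cp.min_module_size(n, p)}")

print()
print("Tightening the wanted level by eight orders of magnitude (0.05 to")
print("5e-10 at |V|=1000) only raises the floor from 3 to 7 nodes: module")
print("size is not the binding constraint of the method.")
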