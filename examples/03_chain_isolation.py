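"""Progressive isolation of a chain versus global weakening.

Starting from a dense 50-node random graph, one experiment decays every
edge between a 10-node chain and the rest by 0.05 per iteration (sculpting
a lollipop stick); the control decays all edges uniformly. Lost edge weight
is added back as self loops, so weakening slows the walk. Mean hitting time
rises in both cases — only skewness tells the two scenarios apart.
"""

import lollinet as ln

res = ln.run_isolation_study(seeds=range(5))
ends = res.table[res.table["iteration"].isin([0, 19])]
print(ends.groupby(["mode", "iteration"])[["mean_hitting", "kelley"]].mean().round(1))
print()
for name, check in res.checks.items():
    print(f"check {name}: passed={check['passed']} (proportion {check['value']:.2f})")
print("\nBoth modes inflate the mean, but the Kelley skewness explodes only when")
print("the chain is isolated -- the signature used to detect linear subnetworks.")
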