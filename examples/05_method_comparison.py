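"""Head-to-head: windowed DMD vs windowed ICA at mode reconstruction.

Both methods extract modes from identical sliding windows; the
supervised top-k reconstruction (order modes by |correlation| with a
reference, average the best k) then upper-bounds what any unsupervised
clustering of each mode set could return.  On the noisy benchmark the
DMD mode set reconstructs both reference images more faithfully.
"""

import dmdnet as dn
from dmdnet import baselines

sim = dn.simulate_benchmark(seed=0)
references = {"cat": sim.cat_image.ravel(), "chicken": sim.chicken_image.ravel()}

table = baselines.compare_methods(sim.data, dn.WindowSpec(), references, seed=0)
print(table.to_string(index=False))

piv = table.pivot(index="reference", columns="method", values="correlation")
for ref in piv.index:
    gap = piv.loc[ref, "dmd"] - piv.loc[ref, "ica"]
    print(
        f"{ref}: best DMD reconstruction beats ICA by {gap:+.3f} correlation"
    )
# Correlations near 1 mean the averaged top-k modes reproduce the true
# image almost exactly; k is the number of modes averaged to get there.
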