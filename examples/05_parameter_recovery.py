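"""Parameter recovery at the region level: error shrinks as runs lengthen.

Simulates the generative model directly (no channel layer) and fits it at
several per-condition lengths, printing coefficient RMSE.
"""

import numpy as np

import nirsconn as nc
from nirsconn.projection import ClusterAssignment
from nirsconn import ProjectedSeries

truth = nc.make_ground_truth(M=6, K=4, p=1, sparsity=0.2, effect_size=0.4, seed=0)
target = np.concatenate([truth.phi0[None], truth.deltas])
names = tuple(f"c{k}" for k in range(5))
asg = ClusterAssignment(np.arange(6), 6, np.zeros((6, 3)))

for T in (200, 1000, 5000):
    data = {
        n: ProjectedSeries(
            g=nc.simulate_condition_run(truth, k, T, seed=10 * T + k),
            fs=10.2, assignment=asg, run_condition=n,
        )
        for k, n in enumerate(names)
    }
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = nc.fit_ols(nc.build_design(data, nc.ConditionCoding(names), p=1))
    rmse = np.sqrt(np.mean((fit.phi - target) ** 2))
    print(f"T = {T:5d} samples/condition -> coefficient RMSE {rmse:.4f}")

print("\nOLS is root-n consistent here: ten times the data, about a third")
print("of the error. At T = 5000 every coefficient is within a few 0.01.")
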