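"""Virtual resection: predicting the effect of surgery in the fitted model.

A synthetic seizure is driven by one highly excitable region that recruits
everything downstream.  Removing the driver from the network and re-running
the dynamics with the same excitabilities suppresses the cascade; removing
random regions does not.  Precision-recall compares the predicted
epileptogenic zone, {i : p(c_i > 2) > p_t}, with the resected set.
"""

import numpy as np

import seizprop as sp

n = 8
W = np.zeros((n, n))
W[1:, 0] = 1.0  # region r0 drives everyone
con = sp.Connectome(W, [f"r{i}" for i in range(n)])
q = sp.ExcitationParams(-6.0, 0.0, 3.2, 2.0)
c = np.full(n, -1.0)
c[0] = 3.0

for resected in ([], ["r0"], ["r3", "r4"]):
    res = sp.virtual_resection(con, resected, c[None, :], q)
    print(f"resect {resected or 'nothing'!s:>14}: "
          f"n_preop={res.n_preop}, n_postop={res.n_postop}, "
          f"relative reduction={res.relative_reduction:.2f}")
print("\nOnly removing the driver stops the simulated seizure (reduction 1); "
      "removing followers merely removes them.")

# agreement between predicted epileptogenicity and the resected set
p_ez = sp.high_excitability_probability(c[None, :] + 0.3 *
                                        np.random.default_rng(0).standard_normal((500, n)))
pr = sp.precision_recall_curve(p_ez, con.region_ids, {"r0"}, thresholds=[0.5])
print(f"\nprecision {pr.precision[0]:.2f}, recall {pr.recall[0]:.2f} at "
      "p_t = 0.5: the predicted epileptogenic zone is exactly the resected "
      "driver.")
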