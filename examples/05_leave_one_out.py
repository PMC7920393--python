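"""Leave-one-out validation: can the model predict a withheld observation?

Every observed region is hidden in turn, the single-seizure model is
refitted, and the posterior prediction for the withheld region is scored
against the truth — alongside two baselines that replace the posterior with
the other observed onsets (unweighted, or weighted by connection strength).
"""

import seizprop as sp

W = sp.generate_network(15, seed=19)
obs, truth = sp.generate_seizure(W, sp.DEFAULT_TRUE_Q, hidden_fraction=0.2,
                                 noise_sd=5.0, seed=20)

df = sp.run_loo(obs, W, sp.DEFAULT_TRUE_Q, seed=21, chains=2,
                warmup=400, draws=400)

summary = df.groupby("method")[["state_pa", "onset_pa"]].median()
print("median prediction accuracy over", obs.n_obs, "left-out regions:")
print(summary.round(3))
print("\nstate_pa: posterior probability of the true seizing/non-seizing "
      "state;\nonset_pa: probability of predicting the onset within 5 s "
      "(seizing regions only).\nValues near 1 mean the network plus the "
      "other observations pin down the withheld region.")
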