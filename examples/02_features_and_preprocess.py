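"""From episodes to a modelling table: nine front-desk features and a
leakage-safe preprocessing pipeline.

Every feature is computable the moment the patient registers: the
assigned physician's queue length and composition, appointment status,
the clock-time zone, and the physician's consultation record over the
previous hour.  Preprocessing fits every threshold (outlier fences,
min-max bounds) on the training split only.
"""

import waitcast as wc
from waitcast import preprocess as pp

records = wc.simulate(wc.ClinicConfig(n_physicians=2, n_days=5, seed=11))
episodes, _ = wc.reconstruct_episodes(records)

features = wc.build_features(episodes, wc.FeatureConfig(tau=60.0))
print("feature table:", features.shape[0], "rows")
print(features[["Q_L", "Q_R", "A_S", "T_S", "P_ACT", "P_NP", "waiting_minutes"]]
      .head(3).round(3).to_string(index=False))

train, test, state, drops = pp.preprocess_pipeline(features, ratio=0.8, seed=0)
print(f"\ntrain {len(train)} / test {len(test)} rows; "
      f"outliers dropped: {drops}")
print("training min-max bounds:",
      {k: (round(state.feature_min[k], 2), round(state.feature_max[k], 2))
       for k in ("Q_L", "P_ACT", "P_NP")})

# The model is trained on sqrt(waiting minutes); a normalized queue
# length of e.g. 0.5 de-normalizes back to patients via these bounds,
# which is how narratives cite concrete numbers later.
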