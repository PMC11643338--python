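"""Train a small AC-aware GNN on synthetic scaffold families.

Generates a dataset with planted, substituent-determined activity
cliffs, trains a GCN with the ACA loss (alpha = 1), and prints the
training trajectory: watch the number of mined high-value triplets M'
fall as the latent space absorbs the cliff structure.
Runs in well under a minute.
"""

import numpy as np

from cliffaware import (
    ACALossConfig,
    DataSplit,
    EncoderConfig,
    SyntheticConfig,
    TrainingConfig,
    build_encoder,
    generate_dataset,
    train,
)

records, cliff_pairs = generate_dataset(
    SyntheticConfig(n_scaffolds=4, analogs_per_scaffold=25, seed=0)
)
print(f"{len(records)} molecules in 4 scaffold families, "
      f"{len(cliff_pairs)} planted cliff pairs")

rng = np.random.default_rng(0)
perm = rng.permutation(len(records))
split = DataSplit(
    train=[records[i] for i in perm[:60]],
    validation=[records[i] for i in perm[60:80]],
    test=[records[i] for i in perm[80:]],
)

model = build_encoder(
    EncoderConfig(backbone="gcn", conv_channels=(16, 32), head_widths=(16, 8)),
    seed=0,
)
model, history = train(
    model,
    split,
    ACALossConfig(alpha=1.0, cl=1.0, cu=1.0),
    TrainingConfig(batch_size=32, learning_rate=2e-3, max_epochs=40,
                   early_stopping_patience=40, seed=0, monitor="rmse"),
)

df = history.to_dataframe()
print(f"\n{'epoch':>5} {'MAE':>7} {'M_train':>8} {'Mp_train':>9} {'val RMSE':>9}")
for _, row in df.iloc[::8].iterrows():
    print(f"{int(row.epoch):>5} {row.train_regression:>7.3f} {int(row.train_m):>8} "
          f"{int(row.train_m_prime):>9} {row.val_rmse:>9.3f}")
print(f"\nbest epoch {history.best_epoch}: validation RMSE "
      f"{df.val_rmse.min():.3f}, test RMSE {df.test_rmse[history.best_epoch]:.3f}")
print("M' (violated triplets) shrinking while M stays fixed is the "
      "signature of the latent space becoming activity-coherent.")
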