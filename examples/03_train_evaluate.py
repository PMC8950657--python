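"""The full predictive pipeline: split, oversample, encode, train, evaluate.

Reproduces the design of the best-performing configuration — a random forest
on nucleotide-chemical-property features, a 10% independent test partition,
and two-pass probabilistic oversampling of the positive training windows —
on synthetic benchmark-shaped data.
"""

import dhupred as dp

data = dp.generate_dataset(dp.SyntheticConfig(seed=7))
model = dp.ModelSpec("RF", seed=0)
encoder = dp.EncoderSpec("NCP")

# repeated 5-fold cross-validation on the full data
X = dp.encode_dataset(data, encoder)
cv = dp.cross_validate(X, data.labels, model, k=5, repeats=5, seed=1)
print(f"5-fold CV x5 (550 windows): AUC = {cv.mean('AUC'):.4f} "
      f"+/- {cv.std('AUC'):.4f}, Acc = {cv.mean('Acc'):.4f}")

# independent test after a 10% split with oversampled positives
split = dp.partition(data, dp.SplitSpec(0.10, seed=2))
train = dp.oversample_positives(
    data.subset(split.train_ids), dp.OversampleSpec(passes=2, p=0.5, seed=3)
)
test = data.subset(split.test_ids)
trained = dp.fit(model, dp.encode_dataset(train, encoder), train.labels)
m = dp.independent_test(trained, dp.encode_dataset(test, encoder), test.labels)
print(f"independent test ({len(test)} windows): Sn = {m.Sn:.4f}, "
      f"Sp = {m.Sp:.4f}, Acc = {m.Acc:.4f}, MCC = {m.MCC:.4f}, "
      f"AUC = {m.AUC:.4f}")
print("\nSn/Sp are the positive/negative recall, MCC the correlation between")
print("predicted and true labels, AUC the threshold-free ranking quality.")
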