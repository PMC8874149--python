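"""Train the forest on a synthetic cohort and evaluate a held-out split.

Generates an annotation bundle plus labeled DEL/DUP sets with planted signal
(pathogenic SVs target constrained genes and start codons), trains the
random forest with the production hyperparameters, and reports held-out AUC
with a Hanley-McNeil 95% CI and the 90%-sensitivity score threshold.
"""

from sklearn.model_selection import train_test_split

from svforest.classifier import ForestConfig, gini_importances, predict, train
from svforest.evaluation import roc_auc, sensitivity_threshold
from svforest.fixtures import FixtureSpec, planted_training_frame

spec = FixtureSpec(n_pathogenic=600, n_benign_per_tier=(600,), seed=42)
df = planted_training_frame(spec)
tr, te = train_test_split(df, test_size=300, random_state=0, stratify=df["label"])

model = train(tr, tr["label"].tolist(), ForestConfig(seed=0), sizes=tr["size"].tolist())
scores = predict(model, te, sizes=te["size"].tolist())
y = (te["label"] == "pathogenic").to_numpy()

res = roc_auc(scores, y)
thr, sens, fpr = sensitivity_threshold(scores, y, 0.9)
print(f"held-out AUC {res.auc:.3f} (95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}, n={len(te)})")
print(f"90% sensitivity at score >= {thr:.2f} (FPR {fpr:.2f})")
print("\ntop feature importances (Gini):")
print(gini_importances(model).sort_values(ascending=False).head(5).round(3).to_string())
print(
    "\nAUC near 0.9 means the forest recovers the planted signal: scores of"
    "\npathogenic SVs rank above benign ones for ~90% of random pairs."
)
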