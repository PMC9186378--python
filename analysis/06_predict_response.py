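#!/usr/bin/env python
"""Train and evaluate the ICB-response network on the bulk cohort.

The 7 predictor features are the per-gene ssGSEA grades of CXCL9,
CXCL10, CXCL11, CCL5 and the deconvolved fractions of M1 macrophages,
CD8 T cells, and activated-memory CD4 T cells. A [7, 20, 5, 1] sigmoid
network with hidden-layer dropout is fit to the first 140 samples by
full-batch gradient descent on binary cross-entropy and evaluated on the
held-out 60.
"""

from pathlib import Path

import pandas as pd

from tammune import predict
from tammune import io as tio

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"
SEED = 60


def main() -> None:
    bulk = tio.read_expression_tsv(DATA / "bulk_expression.tsv")
    fractions = pd.read_csv(BASE / "bulk_fractions.tsv", sep="\t", index_col=0)
    response = pd.read_csv(DATA / "bulk_response.tsv", sep="\t", index_col=0).iloc[:, 0]

    ft = predict.build_features(bulk, fractions, response)
    ft.to_csv(BASE / "icb_features.tsv", sep="\t", index_label="sample")
    train_ft, test_ft = ft.iloc[:140], ft.iloc[140:]
    print(f"features: {len(ft)} samples, responder rate "
          f"{ft['response'].mean():.2f}; train 140 / test {len(test_ft)}")

    model = predict.train_mlp(train_ft, lr=0.1, epochs=2000, dropout_rate=0.2,
                              seed=SEED)
    model.save(BASE / "icb_model.json")
    print(f"training loss {model.loss_trace[0]:.3f} -> {model.loss_trace[-1]:.3f} "
          f"over {len(model.loss_trace)} epochs")

    for name, part in (("train", train_ft), ("test", test_ft)):
        res = predict.evaluate(predict.predict_proba(model, part), part["response"])
        pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
            BASE / f"roc_{name}.tsv", sep="\t", index=False
        )
        print(f"{name} AUC = {res.auc:.3f}; confusion at 0.5:\n{res.confusion}")


if __name__ == "__main__":
    main()
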