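"""Train the elastic-net epigenetic clocks and evaluate them by
leave-one-sample-out cross-validation.

A blood clock and a combined-tissue clock are trained on sqrt-transformed
age; every LOO prediction re-runs lambda selection without the held-out
sample. Writes results/clocks/{clock_blood.csv, clock_combined.csv,
loo_predictions.csv, clock_evaluation.csv}.
"""

from pathlib import Path

import pandas as pd

from equusage import io
from equusage.clock import ClockConfig, evaluate_predictions, loo_predict, train_clock

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "clocks"
OUT.mkdir(parents=True, exist_ok=True)

beta = io.read_beta_matrix(ROOT / "data" / "betas.csv")
sheet = io.read_sample_sheet(ROOT / "data" / "sample_sheet.csv")

rows, preds_frames = [], []
for label, tissue in (("blood", "blood"), ("combined", None)):
    cfg = ClockConfig(tissue=tissue, cv_folds=10)
    model = train_clock(beta, sheet, cfg)
    io.write_clock(model, OUT / f"clock_{label}.csv")
    preds = loo_predict(beta, sheet, cfg)
    ages = (
        sheet.frame.set_index("sample_id").loc[preds.sample_ids, "age"].to_numpy()
    )
    ev = evaluate_predictions(preds.ages, ages)
    rows.append(
        {
            "clock": label,
            "n": len(preds.sample_ids),
            "nonzero_sites": model.n_sites,
            "lambda": model.lam,
            "loo_pearson_r": round(ev.pearson_r, 4),
            "loo_mae_years": round(ev.mae, 4),
        }
    )
    preds_frames.append(
        pd.DataFrame(
            {
                "clock": label,
                "sample_id": preds.sample_ids,
                "age": ages,
                "loo_predicted_age": preds.ages,
            }
        )
    )
    print(
        f"{label} clock: {model.n_sites} CpGs, LOO r={ev.pearson_r:.3f}, "
        f"MAE={ev.mae:.2f} years"
    )

pd.concat(preds_frames).to_csv(OUT / "loo_predictions.csv", index=False)
pd.DataFrame(rows).to_csv(OUT / "clock_evaluation.csv", index=False)
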