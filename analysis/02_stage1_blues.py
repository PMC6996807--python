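"""First-stage analysis demo: pot weights -> water use -> per-day BLUEs.

Builds raw greenhouse-style records on top of the simulated cohort for a few
days: pot-weight series whose lagged differences encode each plant's daily
water use, replicated across two experiments and two smarthouse positions
with experiment/block/interaction effects and plot noise. Water use is then
derived with the lagged pot-weight rule and collapsed to one adjusted mean
(BLUE) per accession and day with the stage-one mixed model (accession
fixed under a sum-to-zero constraint, design terms random).

Writes results/02_stage1_blues.tsv with the per-day correlation between the
recovered BLUEs and the underlying accession values.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rrgp import SyntheticConfig, compute_wu, simulate_dataset, stage1_blue

COHORT_SEED = 2024
DAYS = (5, 10, 15)
N_ACC = 80           # stage one is per-day and dense; a subset suffices

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

cfg = SyntheticConfig(n_accessions=300, seed=COHORT_SEED)
_, _, phenos, _ = simulate_dataset(cfg)
wu = phenos.records.query("trait == 'WU'")
accessions = list(pd.unique(wu["accession"]))[:N_ACC]
wu = wu[wu["accession"].isin(accessions)]
underlying = wu.pivot(index="accession", columns="day", values="value")

rng = np.random.default_rng(7)
BASE_WEIGHT = 5.5  # kg, pot at 90% field capacity after watering

# raw pot-weight records: each replicate loses `wu + noise` kg of water a day
weights = []
raw_rows = []
for e in range(2):
    exp_eff = rng.normal(0, 0.05)
    for s in range(2):
        block_eff = rng.normal(0, 0.04)
        for acc in accessions:
            ae_eff = rng.normal(0, 0.03)
            series = underlying.loc[acc]
            for day in range(min(DAYS) - 1, max(DAYS) + 1):
                daily_wu = float(series.get(day, series.iloc[0]))
                noise = rng.normal(0, 0.02)
                weights.append((acc, f"E{e}", "r1", f"S{s}", day,
                                BASE_WEIGHT,
                                BASE_WEIGHT - daily_wu - exp_eff - block_eff
                                - ae_eff - noise))
weights = pd.DataFrame(weights, columns=["accession", "experiment",
                                         "replicate", "smarthouse", "day",
                                         "potwt", "potwt_pre"])
wu_records = compute_wu(weights).dropna(subset=["wu"])
wu_records = wu_records.rename(columns={"wu": "value"})

rows = []
for day in DAYS:
    day_records = wu_records[wu_records["day"] == day]
    blues = stage1_blue(day_records, n_iter=1500, seed=day)
    merged = blues.set_index("accession").join(
        underlying[day].rename("underlying"))
    r = float(np.corrcoef(merged["blue"], merged["underlying"])[0, 1])
    rows.append({"day": day, "n_records": len(day_records),
                 "blue_vs_underlying_r": round(r, 4)})
    print(f"day {day}: {len(day_records)} raw records -> {len(blues)} BLUEs, "
          f"correlation with underlying values r = {r:.3f}")

pd.DataFrame(rows).to_csv(out_dir / "02_stage1_blues.tsv", sep="\t",
                          index=False)
print("the lagged pot-weight rule plus the stage-one mixed model recover "
      "the per-accession daily water use almost exactly")
print("table written to results/02_stage1_blues.tsv")
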