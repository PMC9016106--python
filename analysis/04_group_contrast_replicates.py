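"""Replicate study of the diffuse-vs-circumscribed DICE contrast.

Re-runs the full in-memory pipeline on freshly simulated cohorts under
many master seeds and records the rank-sum p-value for the group DICE
difference, estimating how reliably the design detects the contrast.
Uses a scaled-down 64^3 grid with the same physical extent so each
replicate stays cheap.

Writes results/replicates.csv and prints the rejection rate at 0.05.
"""

import argparse
from pathlib import Path

import pandas as pd

from petconcord import phantom, pipeline
from petconcord.cohort import wilcoxon_rank_sum
from petconcord.phantom import PhantomSpec

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--replicates", type=int, default=25)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "replicates.csv")
    args = parser.parse_args()

    base = PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=2.25)
    rows = []
    for r in range(args.replicates):
        master = (args.seed + 7919 * r) % 2**31
        cases = phantom.generate_cohort(base_spec=base, seed=master)
        records = pipeline.cases_to_records(cases)
        d = [rec.metrics.dice for rec in records if rec.group == "diffuse"]
        c = [rec.metrics.dice for rec in records if rec.group == "circumscribed"]
        p = wilcoxon_rank_sum(d, c).p_value
        rows.append(
            {
                "master_seed": master,
                "dice_mean_diffuse": sum(d) / len(d),
                "dice_mean_circumscribed": sum(c) / len(c),
                "ranksum_p": p,
                "reject_at_0.05": p < 0.05,
            }
        )
    frame = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False, float_format="%.6g")
    rate = frame["reject_at_0.05"].mean()
    print(frame[["dice_mean_diffuse", "dice_mean_circumscribed", "ranksum_p"]].describe().round(4))
    print(f"rejection rate at alpha=0.05: {rate:.2%} over {len(frame)} replicates -> {args.out}")


if __name__ == "__main__":
    main()
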