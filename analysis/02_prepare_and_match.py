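#!/usr/bin/env python
"""Classify, include, and match the cohort.

Applies the inclusion criteria (new visit and adoption strictly after the
window start; consistent- and temporary-users dropped), derives each
patient's baseline quarter and discretized baseline profile, estimates
adoption propensity scores, and matches each user 1:1 to the nearest
non-user within the same new-visit quarter.  Writes the exclusion report,
baseline table, matched pairs and the Table-1-style balance diagnostics
under results/cohort/.
"""

from pathlib import Path

from portaldid.matching import balance_table, estimate_propensity, match_nearest
from portaldid.prep import (
    DEMOGRAPHIC_COLUMNS,
    apply_inclusion_criteria,
    baseline_table,
)
from portaldid.simulate import read_cohort

OUTDIR = Path("results/cohort")


def main() -> None:
    patients, quarters = read_cohort(OUTDIR)
    included, exclusions = apply_inclusion_criteria(patients)
    print("exclusions:")
    print(exclusions.to_string(index=False))

    baseline = baseline_table(included, quarters)
    covs = included.set_index("patient_id")[list(DEMOGRAPHIC_COLUMNS)].join(
        baseline.set_index("patient_id")[
            ["apn_cat", "arrived_cat", "noshow_cat", "cancel_cat"]
        ]
    )
    user_flag = included.set_index("patient_id")["status"].eq("user")
    model = estimate_propensity(covs, user_flag)
    ids = included["patient_id"].to_numpy()
    matched = match_nearest(
        model.scores,
        ids[user_flag.loc[ids].to_numpy()],
        ids[~user_flag.loc[ids].to_numpy()],
        strata=included.set_index("patient_id")["new_index"],
    )
    balance = balance_table(covs, user_flag, matched)

    baseline.to_csv(OUTDIR / "baseline.csv", index=False)
    exclusions.to_csv(OUTDIR / "exclusions.csv", index=False)
    matched.pairs.to_csv(OUTDIR / "pairs.csv", index=False)
    balance.to_csv(OUTDIR / "balance.csv", index=False)

    post = balance[balance["cohort"] == "matched"].groupby("variable")["p_value"].first()
    pre = balance[balance["cohort"] == "unmatched"].groupby("variable")["p_value"].first()
    print(f"\nmatched {len(matched.pairs)} pairs "
          f"({len(matched.unmatched_users)} users unmatched)")
    print("balance p-values (pre -> post):")
    for var in post.index:
        print(f"  {var:16s} {pre[var]:8.4f} -> {post[var]:8.4f}")
    print(f"covariates balanced after matching: {(post > 0.05).sum()}/{len(post)}")


if __name__ == "__main__":
    main()
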