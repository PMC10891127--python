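"""Score the held-out validation cohort with the discovered signature
(S = sum_i c_i x_i), stratify into score tertiles, and test prognostic
value: Kaplan-Meier curves with a log-rank test across tertiles, a
univariable Cox model on the continuous score, and a multivariable model
adjusting for age, sex, stage and histology.

Run after 03_discover_signature.py:
    python analysis/04_evaluate_signature.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

import clonalsig as cs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    t = pd.read_csv(OUT / "signature.tsv", sep="\t", index_col=0)
    sig = cs.Signature(
        genes=t.index.tolist(),
        coefficients=t["coefficient"],
        penalized_coefficients=t["penalized"],
        provenance={"input": len(t), "lasso": len(t)},
        lam=0.06,
    )
    cohort = cs.align_cohort(
        cs.read_expression(OUT / "validation.expression.tsv", "log2"),
        cs.read_clinical(OUT / "validation.clinical.tsv"),
    )

    rs = cs.evaluate(sig, cohort, covariates=["age", "sex", "stage", "histology"])

    rs.scores.to_frame().join(rs.groups).to_csv(
        OUT / "validation.scores.tsv", sep="\t", index_label="sample_id"
    )
    pd.concat(
        [c.assign(group=g) for g, c in rs.km.curves.items()], ignore_index=True
    ).to_csv(OUT / "validation.km_curves.tsv", sep="\t", index=False)
    rs.cox_multivariable.summary.to_csv(
        OUT / "validation.multivariable.tsv", sep="\t", index_label="covariate"
    )

    uni = rs.cox_univariable.summary.loc["score"]
    multi = rs.cox_multivariable.summary.loc["score"]
    sizes = rs.groups.value_counts()
    print(f"validation cohort: {cohort.n_samples} samples; tertile sizes "
          f"{sizes.get('low', 0)}/{sizes.get('intermediate', 0)}/{sizes.get('high', 0)}")
    print(f"log-rank across tertiles: chi2={rs.km.statistic:.2f} "
          f"(df={rs.km.df}), p={rs.logrank_p:.3g}")
    print(f"univariable score HR: {uni.hr:.3f} "
          f"({uni.hr_lower:.3f}-{uni.hr_upper:.3f}), p={uni.p:.3g}")
    print(f"multivariable score HR (age/sex/stage/histology adjusted): "
          f"{multi.hr:.3f} ({multi.hr_lower:.3f}-{multi.hr_upper:.3f}), p={multi.p:.3g}")
    comp = cs.compare_score_by_group(
        rs.scores, cohort.clinical.table["histology"], test="t"
    )
    comp.to_csv(OUT / "validation.score_by_histology.tsv", sep="\t", index=False)
    print(f"tables -> {OUT}/validation.*.tsv")


if __name__ == "__main__":
    main()
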