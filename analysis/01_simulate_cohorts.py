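"""Generate the synthetic study: a 26-patient x 3-region tumor cohort with
planted clonal/subclonal/null genes, a 300-sample discovery survival cohort,
and an independent 211-sample validation cohort, all written as TSVs under
results/. Ground truth (gene classes and planted hazards) is saved so later
steps can report recovery.

Run: python analysis/01_simulate_cohorts.py [--seed 1]
"""

import argparse
from pathlib import Path

import clonalsig as cs
from clonalsig.expression import write_clinical, write_expression, write_sample_map

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    cfg = cs.SimulationConfig(n_genes=2000, seed=args.seed)
    mr, truth = cs.simulate_multiregion(cfg)
    discovery = cs.simulate_survival_cohort(cfg, truth, n_samples=300, seed=args.seed + 10)
    validation = cs.simulate_survival_cohort(cfg, truth, n_samples=211, seed=args.seed + 20)

    write_expression(mr.expression, OUT / "multiregion.expression.tsv")
    write_sample_map(mr.sample_map, OUT / "multiregion.sample_map.tsv")
    write_expression(discovery.expression, OUT / "discovery.expression.tsv")
    write_clinical(discovery.clinical, OUT / "discovery.clinical.tsv")
    write_expression(validation.expression, OUT / "validation.expression.tsv")
    write_clinical(validation.clinical, OUT / "validation.clinical.tsv")
    truth.gene_class.to_frame().join(truth.beta).to_csv(OUT / "truth.tsv", sep="\t")

    n_cl = (truth.gene_class == "clonal").sum()
    print(f"multi-region cohort: {cfg.n_patients} patients x {cfg.regions_per_patient} "
          f"regions, {cfg.n_genes} genes ({n_cl} clonal, "
          f"{len(truth.prognostic_genes)} planted prognostic)")
    print(f"discovery cohort: 300 samples, {discovery.event.sum()} events")
    print(f"validation cohort: 211 samples, {validation.event.sum()} events")
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
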