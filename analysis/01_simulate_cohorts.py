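#!/usr/bin/env python
"""Generate the synthetic study cohorts used by the downstream analyses.

Writes, under results/simulated/:
  * a paired NC/CRC cassette-exon cohort (18 patients, ~200 informative
    reads per event, two planted effects PSI 0.5->0.85 and 0.1->0.45 among
    100 null events) as a junction count table with its planted truth,
  * an NC/CRC/MC trio cohort plus a 10-patient NC/CRC replication cohort,
  * a CD44-like donor-sharing site-group cohort,
  * a 382-tumor / 51-normal junction-usage matrix with 3-block correlation
    structure, and exponential survival records tied to the first
    predictor's median split.
"""

from pathlib import Path

from splicemark import simulate as sim

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    counts, _, truth = sim.simulate_cassette_counts(seed=SEED)
    counts.to_tsv(OUT / "cassette_counts.tsv", index_label="junction")
    truth.to_csv(OUT / "cassette_truth.tsv", sep="\t")
    print(f"cassette cohort: {len(counts.counts)} junction rows, "
          f"{len(counts.samples)} samples, "
          f"{(truth.kind == 'planted').sum()} planted events")

    trio, pair, _, trio_truth = sim.simulate_trio_cohort(seed=SEED + 1)
    trio.to_tsv(OUT / "trio_counts.tsv", index_label="junction")
    pair.to_tsv(OUT / "pair_counts.tsv", index_label="junction")
    trio_truth.to_csv(OUT / "trio_truth.tsv", sep="\t")
    print(f"trio cohort: {len(trio.samples)} samples "
          f"(+{len(pair.samples)} replication samples)")

    sg_counts, _, sg_truth = sim.simulate_site_group_counts(seed=SEED + 2)
    sg_counts.to_tsv(OUT / "site_group_counts.tsv", index_label="junction")
    sg_truth.to_csv(OUT / "site_group_truth.tsv", sep="\t")
    print(f"site-group cohort: {len(sg_counts.counts)} junctions")

    matrix, labels, usage_truth = sim.simulate_usage_matrix(seed=SEED + 3)
    matrix.to_csv(OUT / "usage_matrix.tsv", sep="\t", index_label="sample")
    labels.to_frame().to_csv(OUT / "labels.tsv", sep="\t", index_label="sample")
    usage_truth.to_csv(OUT / "usage_truth.tsv", sep="\t")
    survival = sim.simulate_survival(matrix.iloc[:, 0], seed=SEED + 4)
    survival.to_csv(OUT / "survival_records.tsv", sep="\t", index_label="person")
    print(f"usage matrix: {matrix.shape[0]} samples x {matrix.shape[1]} "
          f"junction predictors; survival records for {len(survival)} persons")


if __name__ == "__main__":
    main()
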