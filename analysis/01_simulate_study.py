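#!/usr/bin/env python
"""Generate the synthetic nested case-control study.

Draws a source cohort of 60,000 participants, samples 927 incident CHD
cases, 1114 ischemic-stroke cases, 1127 intracerebral-hemorrhage cases and
1513 frequency-matched controls (age bin x sex x study area), and a
disjoint 13,060-participant selection cohort for the genetic scores.
Writes all study tables plus the generative ground truth under
results/study/.
"""

import sys
from pathlib import Path

from lipidmed import simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    params = simulate.default_params(n_source=60_000, seed=SEED)
    study = simulate.simulate_study(params)
    OUT.mkdir(parents=True, exist_ok=True)
    study.analysis.to_csv(OUT / "cohort.tsv", sep="\t")
    study.metabolites_raw.to_csv(OUT / "metabolites.tsv", sep="\t")
    study.selection.to_csv(OUT / "selection_cohort.tsv", sep="\t")
    study.dosages_analysis.to_csv(OUT / "dosages_analysis.tsv", sep="\t")
    study.dosages_selection.to_csv(OUT / "dosages_selection.tsv", sep="\t")
    study.variant_meta.to_csv(OUT / "variants.tsv", sep="\t", index=False)
    (OUT / "simulation_truth.json").write_text(study.truth.to_json())
    counts = study.analysis["status"].value_counts()
    print(f"analysis set: {len(study.analysis)} participants "
          f"({counts.get('chd_case', 0)} CHD cases, {counts.get('control', 0)} controls)")
    print(f"selection cohort: {len(study.selection)} participants, "
          f"{study.variant_meta.shape[0]} variants in "
          f"{study.variant_meta['gene_window'].nunique()} gene windows")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
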