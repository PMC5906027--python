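"""Build the synthetic lesion cohort with planted representational structure.

Generates the demonstration world — a voxel template of 12 white-matter-like
connections (4 carrying semantic structure, 8 null), 80 multifocal lesion
patients, and their binary picture-naming responses — and writes everything
under results/demo/ in the standard on-disk formats (NIfTI volumes + TSV/CSV
tables) so later stages can run from disk alone.
"""

import json
from pathlib import Path

import numpy as np

from lesion_rsa.io import save_cohort, save_naming, save_template
from lesion_rsa.pipeline import demo_config, simulate_stage

OUT = Path("results/demo")


def main() -> None:
    cfg = demo_config(str(OUT), seed=1)
    template, truth, cohort, naming = simulate_stage(cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    save_template(template, OUT / "template")
    save_cohort(cohort, OUT / "cohort")
    save_naming(naming, OUT / "naming.csv")
    (OUT / "ground_truth.json").write_text(json.dumps(truth.sidecar(), indent=1))
    cfg.to_yaml(OUT / "config.yaml")

    acc = naming.values.mean(axis=0)
    sizes = [len(cohort.masks[p]) for p in cohort.patient_ids]
    informative = [n for n, f in truth.informative_flags.items() if f]
    print(f"template: {len(template.names)} connections x "
          f"{template[template.names[0]].n_voxels} voxels on {template.grid.shape}")
    print(f"informative connections: {', '.join(informative)}")
    print(f"cohort: {cohort.n_patients} patients, lesion sizes "
          f"{min(sizes)}-{max(sizes)} voxels, "
          f"{(cohort.patients['etiology'] == 'stroke').sum()} stroke / "
          f"{(cohort.patients['etiology'] == 'tbi').sum()} TBI")
    print(f"naming: {naming.n_items} items, grand mean accuracy "
          f"{naming.values.mean():.2f}, item accuracy span "
          f"{acc.min():.2f}-{acc.max():.2f}")
    print(f"calibrated logistic intercept: {truth.logistic_params[0]:.2f} "
          f"(slope {truth.logistic_params[1]})")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
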