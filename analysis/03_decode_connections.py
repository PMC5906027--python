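"""Decode naming from lesion features, connection by connection.

Loads the template, cohort, and naming table written by 01 from disk,
extracts the per-connection voxel x patient feature matrices, applies the
lesion-coverage filter, and runs the item-wise balanced-bootstrap SVM
decoding with the within-item permutation test. Writes the per-connection
neural RDMs and the decoding summary (mean within-item correspondence,
permutation p, FDR decision).
"""

from pathlib import Path

import pandas as pd

from lesion_rsa._rng import child_seed
from lesion_rsa.decoding import decode_connection, fdr_select
from lesion_rsa.features import coverage_filter, extract_features
from lesion_rsa.io import load_cohort, load_naming, load_template
from lesion_rsa.pipeline import RunConfig

OUT = Path("results/demo")


def main() -> None:
    cfg = RunConfig.from_yaml(OUT / "config.yaml")
    template = load_template(OUT / "template")
    cohort = load_cohort(OUT / "cohort")
    naming = load_naming(OUT / "naming.csv")

    feats = [extract_features(template, cohort, n) for n in template.names]
    coverage = coverage_filter(feats, cfg.min_patients, cfg.min_voxels)
    coverage.report().to_csv(OUT / "coverage.tsv", sep="\t", index=False)
    print(f"coverage filter: {len(coverage.kept)}/{len(feats)} connections kept")

    neural = {}
    for f in feats:
        if f.region not in coverage.kept:
            continue
        neural[f.region] = decode_connection(
            f, naming, reps=cfg.reps, min_minority=cfg.min_minority,
            seed=child_seed(cfg.seed, "decode", f.region),
            n_perm=cfg.n_perm, perm_reps=cfg.perm_reps, C=cfg.svm_C)
        v = neural[f.region]
        print(f"  {f.region}: within-item {v.mean_within_item:.3f}, "
              f"permutation p = {v.permutation_p:.4f}")

    kept = fdr_select([v.permutation_p for v in neural.values()], cfg.decoding_q)
    for flag, v in zip(kept, neural.values()):
        v.fdr_kept = bool(flag)

    rdm_dir = OUT / "neural_rdms"
    rdm_dir.mkdir(parents=True, exist_ok=True)
    for name, v in neural.items():
        v.rdm.to_csv(rdm_dir / f"{name}.csv")
    pd.DataFrame([
        {"connection": n, "mean_accuracy": v.mean_within_item,
         "p": v.permutation_p, "fdr_kept": v.fdr_kept}
        for n, v in neural.items()
    ]).to_csv(OUT / "decoding.tsv", sep="\t", index=False)
    n_dec = sum(v.fdr_kept for v in neural.values())
    print(f"decodable connections (within-item FDR q < {cfg.decoding_q}): "
          f"{n_dec}/{len(neural)}")
    print(f"wrote {OUT}/decoding.tsv and {rdm_dir}/")


if __name__ == "__main__":
    main()
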