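"""Render the human-readable run report (summary tables + RDM heatmaps)."""

from pathlib import Path

from lesion_rsa.pipeline import report

OUT = Path("results/demo")


def main() -> None:
    # the report needs a manifest; synthesize a minimal one if 01-04 were run
    # stage-by-stage rather than through run_all
    import json

    import pandas as pd

    manifest_path = OUT / "manifest.json"
    if not manifest_path.exists():
        dec = pd.read_csv(OUT / "decoding.tsv", sep="\t")
        rsa = pd.read_csv(OUT / "rsa.tsv", sep="\t")
        cov = pd.read_csv(OUT / "coverage.tsv", sep="\t")
        manifest_path.write_text(json.dumps({
            "config": {}, "config_hash": "staged-run",
            "n_regions_kept_coverage": int(cov["kept"].sum()),
            "n_regions_decodable": int(dec["fdr_kept"].sum()),
            "n_rsa_kept": int(rsa["fdr_kept"].sum()),
        }, indent=1))
    path = report(OUT)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
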