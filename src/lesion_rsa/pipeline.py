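"""End-to-end orchestration: one config, seeded streams, staged outputs.

Stages run in order: synthetic-world generation (or loading of real inputs),
behavioral RDM construction, lesion-feature extraction + coverage filter,
per-region decoding with the within-item permutation gate, and the RSA screen.
Every stage writes plain-text tables under the run directory, and the run
manifest records the config hash so a rerun with the same config is
reproducible stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, synth
from ._rng import child_seed
from .core import LesionCohort, NamingMatrix, VoxelTemplate
from .decoding import NeuralRDM, decode_connection, fdr_select
from .features import coverage_filter, extract_features
from .rdm import RDM
from .rsa import results_table, rsa_screen

__all__ = ["RunConfig", "demo_config", "run_all", "report"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0

    # --- synthetic world (ignored when synthetic=False) -------------------
    synthetic: bool = True
    grid_shape: tuple[int, int, int] = (13, 13, 13)
    n_connections: int = 12
    voxels_per_connection: int = 150
    n_informative: int = 4
    gain: float = 2.0
    damage_scale: float = 24.0
    n_patients: int = 80
    lesion_size_range: tuple[int, int] = (30, 34)
    n_foci: tuple[int, int] = (3, 3)
    confine_lesions: bool = True
    n_items: int = 30
    n_categories: int = 5
    dim: int = 3
    attr_corr_targets: dict = field(
        default_factory=lambda: dict(synth.DEFAULT_ATTR_TARGETS))
    coupling_override: dict = field(default_factory=dict)
    beta0: float = -2.0
    beta1: float = 1.5
    target_accuracy: float | None = 0.70
    item_difficulty_sd: float = 0.0
    n_raters: int = 20
    arrangement_noise_sd: float = 0.1
    trials_per_rater: int = 8

    # --- real-data inputs (when synthetic=False) ---------------------------
    template_dir: str | None = None
    cohort_dir: str | None = None
    naming_csv: str | None = None
    behavioral_dir: str | None = None  # CSV RDMs named <kind>.csv

    # --- coverage filter ----------------------------------------------------
    min_patients: int = 5
    min_voxels: int = 20

    # --- decoding -----------------------------------------------------------
    reps: int = 100
    n_perm: int = 10000
    perm_reps: int = 10
    min_minority: int = 2
    svm_C: float = 1.0
    pval_add_one: bool = False
    decoding_q: float = 0.05
    gate_on_decoding: bool = True

    # --- RSA -----------------------------------------------------------------
    model_kind: str = "semantic"
    nuisance_kinds: tuple = ()
    missing_mode: str = "one"
    q: float = 0.05
    n_boot: int = 1000
    alternative: str = "greater"

    def validate(self) -> None:
        counts = dict(reps=self.reps, n_perm=self.n_perm, perm_reps=self.perm_reps,
                      min_minority=self.min_minority, min_patients=self.min_patients)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 < self.q < 1:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if not self.synthetic:
            for attr in ("template_dir", "cohort_dir", "naming_csv"):
                p = getattr(self, attr)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{attr} missing or not found: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["lesion_size_range"] = list(self.lesion_size_range)
        d["n_foci"] = list(self.n_foci)
        d["nuisance_kinds"] = list(self.nuisance_kinds)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "lesion_size_range", "n_foci"):
            if key in data:
                data[key] = tuple(data[key])
        if "nuisance_kinds" in data:
            data["nuisance_kinds"] = tuple(data["nuisance_kinds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def demo_config(out_dir: str, seed: int = 0, **overrides) -> RunConfig:
    """The desk-scale synthetic demonstration: 80 patients, 30 items, 12
    connections (4 informative at gain 2), 20 decoding reps, 1,000
    permutations at 1 internal rep."""
    cfg = RunConfig(out_dir=out_dir, seed=seed, reps=20, n_perm=1000,
                    perm_reps=1, n_boot=200)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(cfg: RunConfig):
    """Build the synthetic world: template, ground truth, cohort, naming."""
    grid = synth.GridSpec(shape=cfg.grid_shape)
    template = synth.make_template(grid, cfg.n_connections,
                                   cfg.voxels_per_connection,
                                   seed=child_seed(cfg.seed, "template"))
    truth = synth.make_item_space(
        cfg.n_items, cfg.n_categories, cfg.dim, dict(cfg.attr_corr_targets),
        seed=child_seed(cfg.seed, "items"),
        coupling_override=dict(cfg.coupling_override) or None)
    informative = template.names[: cfg.n_informative]
    truth.logistic_params = (cfg.beta0, cfg.beta1)
    synth.make_loadings(template, truth, informative, cfg.gain,
                        seed=child_seed(cfg.seed, "loadings"),
                        damage_scale=cfg.damage_scale)
    cohort = synth.simulate_lesions(template, cfg.n_patients,
                                    cfg.lesion_size_range,
                                    seed=child_seed(cfg.seed, "lesions"),
                                    n_foci=cfg.n_foci,
                                    confine_to_regions=cfg.confine_lesions)
    naming = synth.simulate_naming(cohort, template, truth,
                                   seed=child_seed(cfg.seed, "naming"),
                                   target_accuracy=cfg.target_accuracy,
                                   item_difficulty_sd=cfg.item_difficulty_sd)
    return template, truth, cohort, naming


def behavioral_stage(cfg: RunConfig, truth: synth.GroundTruth) -> dict[str, RDM]:
    """Measure the planted item spaces: arrangement-based semantic and
    attribute RDMs plus the three control RDMs."""
    seed = child_seed(cfg.seed, "behavior")
    rdms: dict[str, RDM] = {}
    trials = synth.simulate_arrangements(
        truth, cfg.n_raters, cfg.arrangement_noise_sd, cfg.trials_per_rater,
        seed=seed)
    rdms["semantic"] = behavior.aggregate_arrangement(trials, truth.item_ids,
                                                      kind="semantic")
    for attr in truth.attribute_embeddings:
        trials = synth.simulate_arrangements(
            truth, cfg.n_raters, cfg.arrangement_noise_sd, cfg.trials_per_rater,
            seed=seed, attribute=attr)
        raw = behavior.aggregate_arrangement(trials, truth.item_ids, kind=attr)
        rdms[attr] = behavior.fill_missing_attribute(raw, cfg.missing_mode)
    sils = synth.simulate_silhouettes(truth, seed=child_seed(cfg.seed, "silhouettes"))
    rdms["visual"] = behavior.visual_rdm(sils)
    trans = synth.simulate_transcriptions(truth.item_ids,
                                          seed=child_seed(cfg.seed, "names"))
    rdms["phonological"] = behavior.phonological_rdm(trans)
    rdms["categorical"] = behavior.categorical_rdm(
        dict(zip(truth.item_ids, truth.categories)))
    return rdms


def features_stage(cfg: RunConfig, template: VoxelTemplate, cohort: LesionCohort):
    feats = [extract_features(template, cohort, name) for name in template.names]
    coverage = coverage_filter(feats, cfg.min_patients, cfg.min_voxels)
    kept = [f for f in feats if f.region in coverage.kept]
    return kept, coverage


def decoding_stage(cfg: RunConfig, kept_features, naming: NamingMatrix
                   ) -> dict[str, NeuralRDM]:
    neural: dict[str, NeuralRDM] = {}
    for f in kept_features:
        neural[f.region] = decode_connection(
            f, naming, reps=cfg.reps, min_minority=cfg.min_minority,
            seed=child_seed(cfg.seed, "decode", f.region),
            n_perm=cfg.n_perm, perm_reps=cfg.perm_reps,
            add_one=cfg.pval_add_one, C=cfg.svm_C)
    pvals = [neural[n].permutation_p for n in neural]
    if cfg.n_perm > 0 and pvals and all(p is not None for p in pvals):
        kept = fdr_select(np.array(pvals), q=cfg.decoding_q)
        for flag, name in zip(kept, neural):
            neural[name].fdr_kept = bool(flag)
    return neural


def rsa_stage(cfg: RunConfig, neural: dict[str, NeuralRDM],
              behavioral: dict[str, RDM]):
    if cfg.gate_on_decoding and any(v.fdr_kept is not None for v in neural.values()):
        gated = {n: v.rdm for n, v in neural.items() if v.fdr_kept}
    else:
        gated = {n: v.rdm for n, v in neural.items()}
    if not gated:
        return []
    model = behavioral[cfg.model_kind]
    nuisance = [behavioral[k] for k in cfg.nuisance_kinds]
    return rsa_screen(gated, model, nuisance, q=cfg.q,
                      alternative=cfg.alternative, n_boot=cfg.n_boot,
                      seed=child_seed(cfg.seed, "rsa_boot"))


# ---------------------------------------------------------------------------
# run-all + report
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and write all artifacts under cfg.out_dir."""
    from .io import load_cohort, load_naming, load_template, save_naming

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic:
        template, truth, cohort, naming = simulate_stage(cfg)
        behavioral = behavioral_stage(cfg, truth)
        (out / "ground_truth.json").write_text(json.dumps(truth.sidecar(), indent=1))
    else:
        template = load_template(cfg.template_dir)
        cohort = load_cohort(cfg.cohort_dir)
        naming = load_naming(cfg.naming_csv)
        truth = None
        behavioral = {}
        for f in sorted(Path(cfg.behavioral_dir).glob("*.csv")):
            behavioral[f.stem] = RDM.from_csv(f, kind=f.stem)
    save_naming(naming, out / "naming.csv")
    for kind, rdm in behavioral.items():
        rdm.to_csv(out / f"rdm_{kind}.csv")

    kept_features, coverage = features_stage(cfg, template, cohort)
    coverage.report().to_csv(out / "coverage.tsv", sep="\t", index=False)

    neural = decoding_stage(cfg, kept_features, naming)
    dec = pd.DataFrame([
        {"connection": n, "mean_accuracy": v.mean_within_item,
         "p": v.permutation_p, "fdr_kept": v.fdr_kept}
        for n, v in neural.items()
    ])
    dec.to_csv(out / "decoding.tsv", sep="\t", index=False)
    neural_dir = out / "neural_rdms"
    neural_dir.mkdir(exist_ok=True)
    for n, v in neural.items():
        v.rdm.to_csv(neural_dir / f"{n}.csv")

    results = rsa_stage(cfg, neural, behavioral)
    results_table(results).to_csv(out / "rsa.tsv", sep="\t", index=False)

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_regions_kept_coverage": len(kept_features),
        "n_regions_decodable": int(sum(bool(v.fdr_kept) for v in neural.values())),
        "n_rsa_kept": int(sum(r.fdr_kept for r in results)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"template": template, "truth": truth, "cohort": cohort,
            "naming": naming, "behavioral": behavioral, "coverage": coverage,
            "neural": neural, "rsa": results, "manifest": manifest}


def report(run_dir: str | Path, heatmaps: int = 4) -> Path:
    """Human-readable summary of a completed run (tables + RDM heatmaps).

    Heatmaps use the display percentile transform; it preserves ranks, so
    nothing the report shows differs in order from what the statistics used.
    """
    run_dir = Path(run_dir)
    needed = ["manifest.json", "decoding.tsv", "rsa.tsv"]
    missing = [f for f in needed if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run at {run_dir}: missing {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    dec = pd.read_csv(run_dir / "decoding.tsv", sep="\t")
    rsa = pd.read_csv(run_dir / "rsa.tsv", sep="\t")

    lines = [f"# Run report ({manifest['config_hash']})", ""]
    lines += [f"- regions passing coverage: {manifest['n_regions_kept_coverage']}",
              f"- regions with decodable within-item accuracy (FDR): "
              f"{manifest['n_regions_decodable']}",
              f"- regions kept by the RSA screen: {manifest['n_rsa_kept']}", ""]
    if len(rsa) == 0 or manifest["n_rsa_kept"] == 0:
        lines.append("No connections passed the RSA screen.")
    else:
        lines.append("## RSA screen (kept connections)")
        lines.append(rsa[rsa["fdr_kept"]].to_string(index=False))
    lines += ["", "## Within-item decoding", dec.to_string(index=False), ""]

    from .rdm import percentile_transform
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    neural_dir = run_dir / "neural_rdms"
    if neural_dir.exists():
        for f in sorted(neural_dir.glob("*.csv"))[:heatmaps]:
            rdm = percentile_transform(RDM.from_csv(f, kind="neural"))
            fig, ax = plt.subplots(figsize=(4, 4))
            im = ax.imshow(rdm.values, cmap="RdBu", vmin=0, vmax=1)
            ax.set_title(f"{f.stem} (percentile)")
            fig.colorbar(im, ax=ax, shrink=0.8)
            fig.savefig(run_dir / f"heatmap_{f.stem}.png", dpi=100,
                        bbox_inches="tight")
            plt.close(fig)
            lines.append(f"![{f.stem}](heatmap_{f.stem}.png)")

    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
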