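"""End-to-end orchestration: simulate -> behavior -> decode -> RSA -> report.

A single seeded :class:`RunConfig` drives every stage; each stage writes its
artifacts under the output directory and the manifest records files, child
seeds and content hashes so a run can be reproduced byte-for-byte. Child
seeds fan out from the global seed through ``numpy.random.SeedSequence``
spawn keys, one per stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, design, figures, rsa, synth

STAGES = ("simulate", "behavior", "decode", "rsa", "report")


class ConfigError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, JSON round-trippable."""

    seed: int | None = None
    out_dir: str = "bundleval_run"
    n_subjects: int = 14
    generative: dict = field(default_factory=dict)  # GenerativeBundleSpec kwargs
    coding: dict = field(default_factory=dict)  # CodingScheme kwargs
    rois: list[str] = field(default_factory=lambda: ["vmPFC", "dmPFC", "OFCmed"])
    decoding_alpha: float = 1e3
    fdr_q: float = 0.05
    rsa_families: list[str] = field(default_factory=lambda: list(rsa.RSA_FAMILIES))
    behavior_families: list[str] = field(default_factory=lambda: list(synth.FAMILIES))
    rsa_trials_per_subject: int = 120  # subsample for tractable DSM fits
    run_decoding: bool = True
    run_rsa: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("config is missing the seed")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    ss = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# dataset I/O

_WTP_COLUMNS = [
    "subject_id", "day", "trial_type", "item_id", "left_item", "right_item",
    "category", "bundle_type", "bid", "latent_value",
]


def save_dataset(obj, path: str | Path, kind: str) -> list[Path]:
    """Write a dataset as plain text (CSV; patterns as NPZ + metadata CSV)."""
    path = Path(path)
    if kind in ("wtp", "schedule", "choices"):
        obj.to_csv(path, index=False)
        return [path]
    if kind == "patterns":
        np.savez(path.with_suffix(".npz"), patterns=obj.patterns,
                 roi_label=obj.roi_label)
        meta_path = path.with_suffix(".meta.csv")
        obj.meta.to_csv(meta_path, index=False)
        return [path.with_suffix(".npz"), meta_path]
    raise ConfigError(f"unknown dataset kind {kind!r}")


def load_dataset(path: str | Path, kind: str):
    """Load and validate a dataset written by :func:`save_dataset`.

    Schema violations are reported with the offending row number.
    """
    path = Path(path)
    if kind in ("wtp", "choices"):
        df = pd.read_csv(path)
        missing = set(_WTP_COLUMNS[:9]) - set(df.columns) if kind == "wtp" else set()
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        bad = df.index[(df.bid < synth.BID_MIN) | (df.bid > synth.BID_MAX)]
        if len(bad):
            raise ValidationError(
                f"bid outside [0, 20] at row {int(bad[0])} (value {df.bid[bad[0]]})"
            )
        bad_tt = df.index[~df.trial_type.isin(["item", "bundle"])]
        if len(bad_tt):
            raise ValidationError(f"unknown trial type at row {int(bad_tt[0])}")
        return df
    if kind == "schedule":
        df = pd.read_csv(path)
        bad_tt = df.index[~df.trial_type.isin(["item", "bundle"])]
        if len(bad_tt):
            raise ValidationError(f"unknown trial type at row {int(bad_tt[0])}")
        return df
    if kind == "patterns":
        arr = np.load(path.with_suffix(".npz"), allow_pickle=False)
        meta = pd.read_csv(path.with_suffix(".meta.csv"))
        if len(arr["patterns"]) != len(meta):
            raise ValidationError(
                f"pattern rows ({len(arr['patterns'])}) do not match metadata "
                f"rows ({len(meta)})"
            )
        return synth.VoxelPatternDataset(
            patterns=arr["patterns"], meta=meta, roi_label=str(arr["roi_label"])
        )
    raise ConfigError(f"unknown dataset kind {kind!r}")


def load_nifti_patterns(
    image_path: str | Path, meta_path: str | Path, roi_label: str = "roi"
):
    """Optional import path: trial-wise beta maps from a 4D NIfTI image.

    The 4th axis must index trials and align row-for-row with the sidecar
    metadata CSV (value, trial_type, day, run, button_side, ...). Voxels
    are flattened; all-NaN voxels are dropped.
    """
    import nibabel as nib  # optional dependency, imported lazily

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"expected a 4D image, got {data.ndim}D")
    patterns = data.reshape(-1, data.shape[-1]).T  # trials x voxels
    keep = ~np.all(np.isnan(patterns), axis=0)
    patterns = np.nan_to_num(patterns[:, keep])
    meta = pd.read_csv(meta_path)
    if len(patterns) != len(meta):
        raise ValidationError(
            f"image volumes ({len(patterns)}) do not match metadata rows "
            f"({len(meta)})"
        )
    return synth.VoxelPatternDataset(patterns=patterns, meta=meta,
                                     roi_label=roi_label)


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    config.to_json(out / "config.json")

    try:
        datasets = _stage_simulate(config, out, manifest)
        _stage_behavior(config, out, manifest, datasets)
        if config.run_decoding:
            _stage_decode(config, out, manifest, datasets)
        else:
            manifest["stages"]["decode"] = {"status": "skipped"}
        if config.run_rsa:
            _stage_rsa(config, out, manifest, datasets)
        else:
            manifest["stages"]["rsa"] = {"status": "skipped"}
        # hash result tables first so the report can list them and a rerun of
        # the same config (into any directory) compares byte-identical
        skip = {"manifest.json", "report.md", "config.json"}
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name not in skip:
                manifest["files"][str(f.relative_to(out))] = _sha256(f)
        _stage_report(config, out, manifest)
    except Exception as exc:  # persist partial outputs, then re-raise with stage
        stage = next((s for s in STAGES if s not in manifest["stages"]), "?")
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _timed(manifest, stage):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, *a):
            if not a[0]:
                manifest["stages"].setdefault(stage, {})["seconds"] = round(
                    time.time() - self.t0, 2
                )
                manifest["stages"][stage]["status"] = "ok"
    return _T()


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> dict:
    with _timed(manifest, "simulate"):
        seed = child_seed(config.seed, "simulate")
        catalog = design.build_item_roster(seed=seed)
        spec = synth.GenerativeBundleSpec(**config.generative)
        wtp = synth.simulate_wtp_dataset(spec, catalog, config.n_subjects, seed)
        schedule = design.build_trial_schedule(catalog, wtp, seed=seed)
        choices = synth.simulate_choices(schedule, wtp, seed=seed)
        save_dataset(wtp, out / "wtp_bids.csv", "wtp")
        save_dataset(schedule, out / "trial_schedule.csv", "schedule")
        save_dataset(choices, out / "choices.csv", "choices")
        manifest["stages"]["simulate"] = {
            "seed": seed,
            "n_subjects": config.n_subjects,
            "n_trials": int(len(schedule)),
        }
    return {"catalog": catalog, "wtp": wtp, "schedule": schedule,
            "choices": choices, "spec": spec, "seed": seed}


def _stage_behavior(config, out, manifest, datasets) -> None:
    with _timed(manifest, "behavior"):
        table = behavior.compare_bundle_models(
            datasets["wtp"], config.behavior_families
        )
        table.to_csv(out / "behavior_model_comparison.csv", index=False)
        by_type = behavior.fit_by_bundle_type(datasets["wtp"])
        pd.DataFrame(
            [{"bundle_type": k, **f.params, "r2": f.r2} for k, f in by_type.items()]
        ).to_csv(out / "behavior_by_bundle_type.csv", index=False)
        best_family = table.family.iloc[0]
        fit = behavior.fit_bundle_model(
            datasets["wtp"], behavior.BundleModelSpec(family=best_family)
        )
        curve = behavior.evaluate_fit_curve(fit)
        curve.to_csv(out / "fit_curve.csv", index=False)
        figures.bundle_vs_sum_figure(datasets["wtp"], curve,
                                     out / "fig_bundle_vs_sum.png")
        manifest["stages"]["behavior"] = {
            "best_family": best_family,
            "table": table.to_dict("records"),
        }


def _patterns_for_subject(config, datasets, roi, subject_id, seed):
    roi_key = int(hashlib.sha256(roi.encode()).hexdigest()[:6], 16) % 1000
    scheme = synth.CodingScheme(**{**config.coding,
                                   "encoding_seed": seed + roi_key})
    return synth.simulate_voxel_patterns(
        datasets["schedule"], datasets["wtp"], scheme,
        seed=seed + subject_id, roi_label=roi, subject_id=subject_id,
    )


def _stage_decode(config, out, manifest, datasets) -> None:
    with _timed(manifest, "decode"):
        seed = child_seed(config.seed, "decode")
        cfg = decoding.DecodingConfig(alpha=config.decoding_alpha, q_fdr=config.fdr_q)
        frames = []
        for roi in config.rois:
            for s in sorted(datasets["wtp"].subject_id.unique()):
                data = _patterns_for_subject(config, datasets, roi, s, seed)
                frames.append(cross_decode_drop_folds(data, cfg))
        results = pd.concat(frames, ignore_index=True)
        results.drop(columns=["fold_r"]).to_csv(
            out / "decoding_accuracies.csv", index=False
        )
        group = decoding.group_decoding_tests(results, q_fdr=config.fdr_q)
        group.to_csv(out / "decoding_group_stats.csv", index=False)
        figures.decoding_split_figure(group, out / "fig_decoding_splits.png")
        manifest["stages"]["decode"] = {
            "seed": seed,
            "n_significant": int(group.significant.sum()),
        }


def cross_decode_drop_folds(data, cfg):
    return decoding.cross_decode(data, cfg)


def _stage_rsa(config, out, manifest, datasets) -> None:
    with _timed(manifest, "rsa"):
        seed = child_seed(config.seed, "rsa")
        rng = np.random.default_rng(seed)
        rows, fullnorm_fits = [], []
        roi = config.rois[0]
        for s in sorted(datasets["wtp"].subject_id.unique()):
            data = _patterns_for_subject(config, datasets, roi, s, seed)
            # subsample trials to keep the pairwise problem tractable
            keep = np.sort(
                rng.choice(data.n_trials,
                           min(config.rsa_trials_per_subject, data.n_trials),
                           replace=False)
            )
            sub = synth.VoxelPatternDataset(
                data.patterns[keep], data.meta.iloc[keep].reset_index(drop=True),
                data.roi_label,
            )
            neural = rsa.compute_neural_dsm(sub)
            trials = sub.meta
            table = rsa.compare_rsa_models(
                neural, trials, tuple(config.rsa_families), seed=seed + s
            )
            table["subject_id"] = s
            rows.append(table)
            fn = table[table.family == "full_normalization"]
            if len(fn):
                fullnorm_fits.append(fn.iloc[0])
        all_rows = pd.concat(rows, ignore_index=True)
        all_rows.to_csv(out / "rsa_model_comparison.csv", index=False)
        figures.rsa_delta_bic_figure(all_rows, out / "fig_rsa_delta_bic.png")
        stats = {}
        if len(fullnorm_fits) >= 5:
            fn = pd.DataFrame(fullnorm_fits)
            stats = rsa.test_coefficient_attenuation(fn)
            Path(out / "rsa_attenuation.json").write_text(json.dumps(stats, indent=2))
            figures.attenuation_figure(fn, out / "fig_rsa_attenuation.png")
        manifest["stages"]["rsa"] = {"seed": seed, "attenuation": stats}


def _stage_report(config, out, manifest) -> None:
    with _timed(manifest, "report"):
        manifest["stages"]["report"] = {"file": "report.md"}
        write_report(manifest, out)


def write_report(manifest: dict, out: Path) -> Path:
    """Summary document with one section per analysis stage."""
    out = Path(out)
    lines = ["# Bundle valuation synthetic-run report", ""]
    lines += [f"Global seed: {manifest['seed']}", ""]
    lines += ["## Design", ""]
    sim = manifest["stages"].get("simulate", {})
    lines += [f"- subjects: {sim.get('n_subjects')}",
              f"- scheduled trials: {sim.get('n_trials')}", ""]
    lines += ["## Behavioral model comparison", ""]
    beh = manifest["stages"].get("behavior", {})
    if beh:
        lines += [f"Best family by summed BIC: **{beh.get('best_family')}**", ""]
        for rec in beh.get("table", []):
            lines += [f"- {rec['family']}: delta BIC {rec['delta_bic']:.1f}, "
                      f"R2 {rec['r2']:.3f}"]
        lines += [""]
    lines += ["## Cross-condition decoding", ""]
    dec = manifest["stages"].get("decode", {})
    if dec.get("status") == "skipped":
        lines += ["(skipped)", ""]
    else:
        lines += [f"Significant ROI/split tests: {dec.get('n_significant')}",
                  "(see decoding_group_stats.csv)", ""]
    lines += ["## RSA model comparison", ""]
    rsa_st = manifest["stages"].get("rsa", {})
    if rsa_st.get("status") == "skipped":
        lines += ["(skipped)", ""]
    else:
        att = rsa_st.get("attenuation") or {}
        if att:
            lines += [
                "Value-coefficient attenuation (bundle - item): "
                f"mean {att['mean_difference']:.3f} +/- {att['se']:.3f}, "
                f"t = {att['t']:.2f}, p = {att['p']:.2g}", ""]
    lines += ["## Files", ""]
    for name in sorted(manifest.get("files", {})):
        lines += [f"- {name}"]
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
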