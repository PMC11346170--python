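"""End-to-end orchestration: cohort -> imaging/morphometry -> scoring ->
cytometry -> statistics, with a reproducibility manifest.

One root seed drives every stage (split deterministically per stage); the
manifest records the config hash, seed, per-stage inputs/outputs and a
content hash over all outputs, so a rerun with the same config and seed is
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort_frame, write_cohort_tsv
from .config import CohortConfig, default_config, load_config
from .cytometry import BeadSet, auf_to_mfi, fit_bead_calibration, mfi_to_auf
from .imaging import ImageSpec, render_eye, write_frames
from .morphometry import compute_frame_metrics, summarize_eye
from .scoring import score_summary
from .stats import (
    compare_hla_by_icsc,
    spearman_matrix,
    stratify_extreme_tivcm,
    within_group_correlations,
)

log = logging.getLogger(__name__)

#: synthetic bead lot used by the demo cytometry stage (log-linear, ABC = 10*MFI)
DEMO_BEADS = BeadSet(
    mfi=(100.0, 500.0, 2500.0, 12500.0, 62500.0),
    abc=(1e3, 5e3, 2.5e4, 1.25e5, 6.25e5),
    lot_id="synthetic-demo-lot",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class StageRecord:
    name: str
    inputs: list[str]
    outputs: list[str]
    n_in: int
    n_out: int


@dataclass
class RunManifest:
    config_name: str
    config_hash: str
    seed: int
    version: str
    stages: list[StageRecord] = field(default_factory=list)
    output_hash: str = ""
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_files(paths: list[Path]) -> str:
    digest = hashlib.sha256()
    for path in sorted(paths):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()


def _spec_for_eye(row: pd.Series, seed: int) -> ImageSpec:
    """Translate one eye's latent morphometry into a rendering spec."""
    background = 40.0
    tort = max(float(row["mean_tortuosity"]) - 1.0, 0.0)
    return ImageSpec(
        n_cells=int(round(row["mean_ic_density"] * 0.16)),
        n_nerves=max(int(round(row["mean_nfd"] * 0.16)), 1),
        tortuosity_amplitude=16.0 * np.sqrt(tort),
        nerve_contrast=background * max(float(row["mean_reflectivity"]) - 1.0, 0.1),
        background_level=background,
        noise_sd=3.0,
        seed=seed,
    )


def run_full(
    config: CohortConfig | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path = "results/run",
    n_morpho_eyes: int = 4,
) -> RunManifest:
    """Run every stage on a synthetic cohort and write all stage outputs."""
    if config is None:
        config = default_config()
    elif not isinstance(config, CohortConfig):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_name=config.name,
        config_hash=config.cache_key(),
        seed=seed,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    all_outputs: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                record = fn()
            except Exception as exc:  # annotate failures with the stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            manifest.stages.append(record)
            all_outputs.extend(Path(p) for p in record.outputs)
            log.info("stage %s: %d in -> %d out", name, record.n_in, record.n_out)
            return record

        return wrap

    # --- cohort -----------------------------------------------------------
    cohort_path = out_dir / "cohort.tsv"

    @stage("cohort")
    def _cohort():
        frame = generate_cohort_frame(config, seed)
        write_cohort_tsv(frame, cohort_path)
        return StageRecord("cohort", [], [str(cohort_path)], config.n_total, len(frame))

    cohort = pd.read_csv(cohort_path, sep="\t")

    # --- imaging + morphometry (demo subset, measured against ground truth)
    morpho_path = out_dir / "morphometry.tsv"

    @stage("morphometry")
    def _morpho():
        rows = []
        subset = cohort.head(n_morpho_eyes)
        for i, (_, row) in enumerate(subset.iterrows()):
            spec = _spec_for_eye(row, seed=seed * 10_000 + i + 1)
            frames = render_eye(spec, eye_id=row["patient_id"])
            metrics = [
                compute_frame_metrics(img, ann.image_id, ann.cells, ann.nerves)
                for img, ann in frames
            ]
            summary = summarize_eye(metrics, eye_id=row["patient_id"])
            rows.append(
                {
                    "eye_id": summary.eye_id,
                    "n_images_used": summary.n_images_used,
                    "measured_ic_density": summary.mean_ic_density,
                    "measured_nfd": summary.mean_nfd,
                    "measured_nfl": summary.mean_nfl,
                    "measured_tortuosity": summary.mean_tortuosity,
                    "measured_reflectivity": summary.mean_reflectivity,
                    "generated_ic_density": row["mean_ic_density"],
                    "generated_nfd": row["mean_nfd"],
                    "generated_tortuosity": row["mean_tortuosity"],
                    "generated_reflectivity": row["mean_reflectivity"],
                }
            )
        pd.DataFrame(rows).to_csv(morpho_path, sep="\t", index=False)
        return StageRecord(
            "morphometry", [str(cohort_path)], [str(morpho_path)],
            len(subset), len(rows),
        )

    # --- scoring (recompute from the cohort's morphometry, verify) --------
    scores_path = out_dir / "scores.tsv"

    @stage("scoring")
    def _scoring():
        from .morphometry import MorphometrySummary

        rows = []
        mismatches = 0
        for _, row in cohort.iterrows():
            summary = MorphometrySummary(
                eye_id=row["patient_id"],
                n_images_used=5,
                mean_ic_density=row["mean_ic_density"],
                mean_nfd=row["mean_nfd"],
                mean_nfl=row["mean_nfl"],
                mean_tortuosity=row["mean_tortuosity"],
                mean_reflectivity=row["mean_reflectivity"],
            )
            score = score_summary(summary, config.thresholds)
            mismatches += int(score.total != row["tivcm"])
            rows.append(
                {
                    "eye_id": row["patient_id"],
                    "ic_sub": score.ic_sub,
                    "ic_code": score.ic_code,
                    "nd_sub": score.nd_sub,
                    "nd_code": score.nd_code,
                    "nm_sub": score.nm_sub,
                    "nm_code": score.nm_code,
                    "tivcm": score.total,
                }
            )
        if mismatches:
            raise PipelineError(f"{mismatches} rescored totals disagree with the cohort")
        pd.DataFrame(rows).to_csv(scores_path, sep="\t", index=False)
        return StageRecord(
            "scoring", [str(cohort_path)], [str(scores_path)], len(cohort), len(rows)
        )

    # --- cytometry (bead calibration round trip over the cohort AUFs) -----
    cyto_path = out_dir / "hla_dr_auf.tsv"

    @stage("cytometry")
    def _cyto():
        cal = fit_bead_calibration(DEMO_BEADS)
        rows = []
        for _, row in cohort.iterrows():
            mfi = auf_to_mfi(cal, row["hla_dr_auf"])
            auf, flagged = mfi_to_auf(cal, mfi)
            rows.append(
                {
                    "eye_id": row["patient_id"],
                    "sample_mfi": mfi,
                    "hla_dr_auf": auf,
                    "below_background": flagged,
                }
            )
        frame = pd.DataFrame(rows)
        frame.to_csv(cyto_path, sep="\t", index=False)
        max_err = float(
            np.max(np.abs(frame["hla_dr_auf"].to_numpy() - cohort["hla_dr_auf"].to_numpy()))
        )
        if max_err > 1e-6 * cohort["hla_dr_auf"].max():
            raise PipelineError(f"AUF round trip error {max_err}")
        return StageRecord(
            "cytometry", [str(cohort_path)], [str(cyto_path)], len(cohort), len(frame)
        )

    # --- statistics -------------------------------------------------------
    stats_dir = out_dir / "stats"

    @stage("stats")
    def _stats():
        outputs = []
        result = spearman_matrix(cohort)
        outputs.extend(result.write_tsv(stats_dir))

        comparison = compare_hla_by_icsc(cohort)
        comp_path = stats_dir / "icsc_hla_comparison.tsv"
        if comparison is not None:
            pd.DataFrame([dataclasses.asdict(comparison)]).to_csv(
                comp_path, sep="\t", index=False
            )
            outputs.append(comp_path)

        low, high = stratify_extreme_tivcm(cohort)
        for name, group in (("tivcm_low", low), ("tivcm_high", high)):
            if len(group) >= 3:
                _res, edges = within_group_correlations(group)
                path = stats_dir / f"{name}_edges.tsv"
                edges.to_csv(path, sep="\t", index=False)
                outputs.append(path)
        return StageRecord(
            "stats", [str(cohort_path)], [str(p) for p in outputs],
            len(cohort), len(outputs),
        )

    manifest.output_hash = _hash_files(all_outputs)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


def regenerate_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> Path:
    """Write the small cohort/image/bead fixtures; byte-stable per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    config = default_config()
    small_groups = tuple(
        dataclasses.replace(g, n=6 if g.name == "AIDED" else 14) for g in config.groups
    )
    small = dataclasses.replace(
        config,
        name="fixture_small",
        groups=small_groups,
        calibration=dataclasses.replace(config.calibration, n_calib=10_000),
    )
    frame = generate_cohort_frame(small, seed)
    write_cohort_tsv(frame, out_dir / "cohort_small.tsv")

    spec = ImageSpec(n_cells=10, n_nerves=4, noise_sd=3.0, seed=seed)
    frames = render_eye(spec, eye_id="fixture", n_frames=3)
    write_frames(frames, out_dir / "frames")

    beads = pd.DataFrame({"mfi": DEMO_BEADS.mfi, "abc": DEMO_BEADS.abc})
    beads.to_csv(out_dir / "beads.tsv", sep="\t", index=False)
    return out_dir
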