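"""End-to-end pipeline driver.

Runs the full analysis on in-memory objects or files: ComBat harmonization
-> per-seed interaction GLM -> permutation TFCE-FWE -> Meff-adjusted
significance masks -> union mask -> target-ROI selection -> fingerprints
with per-center and sex-stratified validation -> clinical association.
Writes every artifact plus a manifest JSON with content hashes, seeds and
parameters, so a run is fully reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import associate_clinical
from .combat import apply_combat, biological_design, fit_combat
from .demographics import demographics_table
from .fingerprints import (fingerprint_matrix, per_center_effects,
                           sex_stratified_fingerprints)
from .glm import build_interaction_design
from .inference import meff_li_ji, permutation_fwe, significance_mask
from .io import save_json, save_table, save_volume
from .labels import SEED_COLUMNS
from .synth import GMVStack, Parcellation
from .targets import (build_union_mask, extract_mean_gmv, overlap_table,
                      select_target_rois)
from .tfce import TFCEngine, TFCEParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    output_dir: str | Path
    rng_seed: int = 0
    seeds: tuple[str, ...] = SEED_COLUMNS
    covariates: tuple[str, ...] = ("age", "sex", "tiv")
    n_perm: int = 5000
    alpha: float = 0.05
    tfce: TFCEParams = field(default_factory=TFCEParams)
    scheme: str = "freedman_lane"
    min_ratio: float = 0.15
    min_volume_mm3: float = 1.0
    roi_scope: str = "full_region"
    harmonize_voxels: bool = True
    harmonize_seeds: bool = True
    clinical_vars: tuple[str, ...] = ("panss_pos", "panss_neg", "panss_gen",
                                      "panss_total", "duration", "cpz")
    clinical_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stack: GMVStack, cohort: pd.DataFrame,
                 seed_table: pd.DataFrame, parcellation: Parcellation,
                 ) -> dict:
    """Execute the full analysis; returns the manifest dict.

    All artifacts (tables, volumes, statistics) are written under
    ``config.output_dir``; the manifest lists every file with its SHA-256
    hash along with seeds, parameters and the package version.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _write_table(df: pd.DataFrame, name: str) -> None:
        path = out / name
        save_table(df, path)
        artifacts[name] = _sha256(path)

    def _write_json(obj, name: str) -> None:
        path = out / name
        save_json(obj, path)
        artifacts[name] = _sha256(path)

    def _write_volume(vol, name: str) -> None:
        path = out / name
        save_volume(vol, stack.affine, path)
        artifacts[name] = _sha256(path)

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    # ---- demographics -------------------------------------------------
    @_stage("demographics")
    def _demo():
        _write_table(demographics_table(cohort), "demographics.tsv")

    # ---- harmonization ------------------------------------------------
    @_stage("harmonize")
    def harmonized():
        batch = cohort["site_id"].to_numpy()
        design = biological_design(cohort, config.covariates)
        Y = stack.masked_matrix()
        if config.harmonize_voxels and len(np.unique(batch)) > 1:
            model = fit_combat(Y, batch, design)
            Y = apply_combat(Y, batch, design, model)
        seeds_h = seed_table.copy()
        if config.harmonize_seeds and len(np.unique(batch)) > 1:
            vol_cols = [c for c in seed_table.columns if c != "subject_id"]
            m2 = fit_combat(seed_table[vol_cols].to_numpy(float), batch,
                            design)
            seeds_h[vol_cols] = apply_combat(
                seed_table[vol_cols].to_numpy(float), batch, design, m2)
        return stack.with_masked_matrix(Y), seeds_h

    stack_h, seeds_h = harmonized

    # ---- Meff threshold -----------------------------------------------
    @_stage("meff")
    def eff():
        seed_cols = [s for s in config.seeds if s in seeds_h.columns]
        corr = np.corrcoef(seeds_h[seed_cols].to_numpy(float), rowvar=False)
        e = meff_li_ji(corr, config.alpha)
        _write_json({"meff": e.meff, "alpha": e.alpha,
                     "adjusted_alpha": e.adjusted_alpha,
                     "eigenvalues": e.eigenvalues}, "meff.json")
        return e

    # ---- per-seed inference -------------------------------------------
    @_stage("inference")
    def seed_masks():
        engine = TFCEngine(stack_h.mask, config.tfce)
        masks = {}
        Y = stack_h.masked_matrix()
        for i, seed in enumerate(config.seeds):
            design = build_interaction_design(cohort, seed,
                                              config.covariates,
                                              seed_table=seeds_h)
            res = permutation_fwe(Y, design, config.tfce, config.n_perm,
                                  config.scheme,
                                  rng_seed=config.rng_seed + 1000 + i,
                                  engine=engine)
            sig = significance_mask(res.fwe_p, eff.adjusted_alpha)
            vol = np.zeros(stack_h.mask.shape, np.uint8)
            vol[stack_h.mask] = sig
            masks[seed] = vol.astype(bool)
            _write_volume(res.to_volume(stack_h.mask, "t_obs"),
                          f"tmap_{seed}.nii.gz")
            _write_volume(res.to_volume(stack_h.mask, "fwe_p"),
                          f"fwep_{seed}.nii.gz")
            _write_json({"seed": seed, "null_max": res.null_max,
                         "n_perm": res.n_perm, "rng_seed": res.rng_seed,
                         "scheme": res.scheme}, f"null_{seed}.json")
        return masks

    # ---- targets -------------------------------------------------------
    @_stage("targets")
    def targets():
        union = build_union_mask(list(seed_masks.values()))
        _write_volume(union.astype(np.uint8), "union_mask.nii.gz")
        records = select_target_rois(union, parcellation, config.min_ratio,
                                     config.min_volume_mm3)
        _write_table(overlap_table(records), "overlap.tsv")
        roi_table = pd.DataFrame({"subject_id": cohort["subject_id"]})
        selected = [r for r in records if r.selected]
        for rec in selected:
            roi_table[rec.name] = extract_mean_gmv(
                stack_h, parcellation.region_mask(rec.label),
                config.roi_scope, union_mask=union)
        _write_table(roi_table, "roi_mean_gmv.tsv")
        return union, selected, roi_table

    union, selected, roi_table = targets

    significant_seeds = [s for s, m in seed_masks.items() if m.any()]
    roi_names = [r.name for r in selected]

    # ---- fingerprints ---------------------------------------------------
    @_stage("fingerprints")
    def fingerprints():
        if not significant_seeds or not roi_names:
            logger.info("no significant seeds or target ROIs; "
                        "fingerprint stages skipped")
            return None
        fp = fingerprint_matrix(roi_table, seeds_h, cohort,
                                significant_seeds, roi_names,
                                config.covariates)
        _write_table(fp.to_frame(), "fingerprints.tsv")

        center_rows, sex_rows = [], []
        for seed in significant_seeds:
            for roi in roi_names:
                _, effects = per_center_effects(
                    roi_table[roi].to_numpy(float),
                    seeds_h[seed].to_numpy(float), cohort,
                    config.covariates, seed_label=seed, roi_label=roi)
                center_rows += [e.__dict__ for e in effects]
                sx = sex_stratified_fingerprints(
                    roi_table[roi].to_numpy(float),
                    seeds_h[seed].to_numpy(float), cohort, seed, roi)
                sex_rows.append({
                    "seed": seed, "roi": roi,
                    "t_male": sx.male.t, "p_male": sx.male.p,
                    "g_male": sx.male.g,
                    "t_female": sx.female.t, "p_female": sx.female.p,
                    "g_female": sx.female.g,
                    "interaction_t": sx.interaction_t,
                    "interaction_p": sx.interaction_p})
        _write_table(pd.DataFrame(center_rows), "center_effects.tsv")
        _write_table(pd.DataFrame(sex_rows), "sex_stratified.tsv")
        return fp

    # ---- clinical -------------------------------------------------------
    @_stage("clinical")
    def _clinical():
        if not significant_seeds or not roi_names:
            return
        pairs = [(s, r) for s in significant_seeds for r in roi_names]
        assoc = associate_clinical(roi_table, seeds_h, cohort, pairs,
                                   config.clinical_vars)
        _write_table(assoc, "clinical_associations.tsv")

    manifest = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "adjusted_alpha": eff.adjusted_alpha,
        "meff": eff.meff,
        "scheme": config.scheme,
        "tfce": dataclasses.asdict(config.tfce),
        "seeds": list(config.seeds),
        "significant_seeds": significant_seeds,
        "target_rois": roi_names,
        "artifacts": artifacts,
    }
    save_json(manifest, out / "manifest.json")
    return manifest
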