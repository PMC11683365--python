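"""End-to-end pipeline runner: simulate -> analyze-rf -> invert ->
discriminate -> report, with a machine-readable run manifest.

Every exclusion (a frame failing the surface-quality gate, a clipped cohort
draw) is recorded in the manifest, and reruns with the same configuration
and seed produce identical manifests and outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from . import cohort_stats, discrimination, io as cio, pore_morphology as pm
from . import spectral_estimation as se
from . import synthetic_data as sd
from .errors import InputError, QualityError
from .frames import AcquisitionConfig, write_rf_hdf5


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (unknown keys are rejected)."""

    seed: int = 0
    design: str = "headline"  # "default" | "headline"
    n_frames: int = 6
    band: tuple[float, float] = (3.0, 9.0)
    grid: tuple[float, float, float] = (20.0, 200.0, 2.0)
    snr_threshold_db: float = se.SNR_THRESHOLD_DB
    n_templates: int = 12
    n_subregions: int = 2
    outcome: str = "any"
    acquisition: dict = field(default_factory=dict)
    verbosity: int = 1

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = dict(payload)
        for key in ("band", "grid"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256((canon + __version__).encode()).hexdigest()[:16]


_FRAME_PROFILES = ["healthy", "osteoporotic", "trabecularized"]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write outputs plus ``manifest.json`` to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % 2**31)
             for name, s in zip(("cohort", "frames", "discriminate"),
                                rng.spawn(3))}
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seeds": seeds,
        "stages": {},
        "outputs": {},
    }

    def finalize(error: Exception | None = None):
        if error is not None:
            manifest["error"] = f"{type(error).__name__}: {error}"
        cio.write_json(manifest, out / "manifest.json")
        manifest["outputs"]["manifest"] = str(out / "manifest.json")

    try:
        # --- simulate -----------------------------------------------------
        design = (sd.headline_effect_design(seeds["cohort"])
                  if config.design == "headline"
                  else sd.default_cohort_design(seeds["cohort"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = sd.synthesize_cohort(design)
        cio.write_cohort_csv(cohort, out / "cohort.csv")
        manifest["stages"]["simulate"] = {
            "n_subjects": int(len(cohort)),
            "clipped_draws": cohort.attrs.get("clipped", {}),
        }
        manifest["outputs"]["cohort"] = str(out / "cohort.csv")

        acq = AcquisitionConfig(**config.acquisition)
        frame_seeds = np.random.SeedSequence(seeds["frames"]).spawn(config.n_frames)
        frame_info = []
        analyzed = []
        grid = pm.make_grid(*config.grid)
        templates = pm.default_template_family(config.n_templates, grid)
        for i, fseed in enumerate(frame_seeds):
            s_pop, s_rf = (int(x.generate_state(1)[0] % 2**31)
                           for x in fseed.spawn(2))
            profile = sd.MORPHOLOGY_REGIMES[_FRAME_PROFILES[i % 3]]
            pop = sd.sample_pore_population(profile, volume_mm3=40.0,
                                            rng_seed=s_pop)
            frame = sd.simulate_rf_frame(pop, acq, rng_seed=s_rf,
                                         alpha0=profile.alpha0_true,
                                         alphaf=profile.alphaf_true)
            frame_path = out / f"frame_{i:02d}.h5"
            write_rf_hdf5(frame, frame_path)
            # --- analyze-rf + invert -------------------------------------
            entry = {"frame": str(frame_path), "profile": _FRAME_PROFILES[i % 3]}
            try:
                surface = se.detect_periosteal_surface(
                    frame, snr_threshold_db=config.snr_threshold_db)
                ref_spec = se.compute_reference_spectrum(frame, surface)
                spec = se.compute_spectrogram(frame, surface, ref_spec)
                att = se.estimate_attenuation(spec, config.band)
                bsc = se.estimate_bsc(spec, att)
                dist = pm.invert_pore_distribution(bsc, grid,
                                                   smoothing_weight=0.3)
                metrics = pm.derive_pore_metrics(dist)
                regions = se.bsc_subregions(spec, att, config.n_subregions)
                metrics.ct_po_dm_i = pm.compute_pore_diameter_index(
                    regions, templates)
                payload = cio.metrics_to_dict(metrics, att, bsc)
                cio.write_json(payload, out / f"metrics_{i:02d}.json")
                entry.update(status="ok",
                             quality_beams=int(surface.quality_flag.sum()),
                             metrics=str(out / f"metrics_{i:02d}.json"))
            except QualityError as exc:
                entry.update(status="excluded", reason=str(exc))
            frame_info.append(entry)
            if entry["status"] == "ok":
                analyzed.append(i)
        n_excluded = sum(1 for e in frame_info if e["status"] == "excluded")
        manifest["stages"]["analyze_rf"] = {
            "frames": frame_info,
            "n_frames": config.n_frames,
            "n_excluded": n_excluded,
            "exclusion_fraction": n_excluded / config.n_frames,
        }
        if not analyzed:
            raise QualityError(
                "insufficient subjects: every RF measurement was excluded "
                "by the quality gate"
            )

        # --- discriminate ------------------------------------------------
        disc = {}
        for feats in ("cortbs", "dxa"):
            res = discrimination.discriminate(
                cohort, outcome=config.outcome, features=feats,
                rng_seed=seeds["discriminate"])
            disc[feats] = {
                "auc": res.roc.auc, "auc_se": res.roc.auc_se,
                "sensitivity": res.roc.sensitivity,
                "specificity": res.roc.specificity,
                "accuracy": res.roc.accuracy,
                "variables": res.selected_variables,
            }
        z, p = discrimination.hanley_mcneil_compare(
            discrimination.discriminate(cohort, outcome=config.outcome,
                                        features="cortbs",
                                        rng_seed=seeds["discriminate"]).loocv_scores,
            discrimination.discriminate(cohort, outcome=config.outcome,
                                        features="dxa",
                                        rng_seed=seeds["discriminate"]).loocv_scores,
            cohort[f"fracture_{config.outcome}"].astype(bool).to_numpy(),
        )
        disc["auc_comparison"] = {"z": z, "p": p}
        cio.write_json(disc, out / "discrimination.json")
        manifest["stages"]["discriminate"] = disc
        manifest["outputs"]["discrimination"] = str(out / "discrimination.json")

        # --- report -------------------------------------------------------
        anova = {}
        for param in ("Ct.Po", "Ct.Po.Dm.D_peak", "α_6-MHz"):
            res = cohort_stats.nway_anova(
                cohort[param],
                {"fracture": cohort["fracture_any"], "group": cohort["group"],
                 "sex": cohort["sex"]},
            )
            anova[param] = {"F": res.f_values, "p": res.p_values}
        cio.write_json(anova, out / "anova.json")
        manifest["stages"]["report"] = {"parameters": sorted(anova)}
        manifest["outputs"]["anova"] = str(out / "anova.json")
    except Exception as exc:
        finalize(exc)
        raise
    finalize()
    return manifest
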