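"""End-to-end orchestration of the cross-modal mapping analysis.

``run_pipeline`` executes, in order: synthetic data generation (or loading
of user-supplied matrices), the regional / global / band-specific
multilinear models, dominance analysis with band contrasts,
distance-dependent and subject-level cross-validation, spin-null
inference on the headline map associations, and the microarchitectural
context statistics. All stages are seeded from one configuration seed,
and every output is written as plain delimited text or JSON with enough
provenance (config, seed, version) to regenerate it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .context import (
    depth_profile_association,
    expression_map_association,
    principal_gradient,
    structure_function_coupling,
)
from .datatypes import BandFCSet, ConnectivityMatrix, ParcelGeometry
from .dominance import band_contribution_anova, dominance_all_regions
from .io import read_geometry, read_matrix, write_geometry, write_map, write_matrix
from .mapping import fit_all_regions, fit_band_specific_models, fit_global_model
from .nulls import generate_spins, spin_pvalue
from .synthetic import (
    SyntheticConfig,
    make_band_fc_set,
    make_context_maps,
    make_crossmodal_truth,
    make_geometry,
    make_subject_ensemble,
)
from .validation import regional_cv, subject_loo_cv

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ResultsBundle", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Validated configuration of one pipeline run.

    Either ``synthetic`` is set (the generator provides every input) or
    ``haemo_path`` / ``band_paths`` / ``geometry_path`` point to
    tab-delimited inputs on disk.
    """

    synthetic: Optional[SyntheticConfig] = field(default_factory=SyntheticConfig)
    haemo_path: Optional[str] = None
    band_paths: Optional[list[str]] = None
    geometry_path: Optional[str] = None
    n_spin: int = 1000
    alpha: float = 0.05
    train_frac: float = 0.75
    seed: int = 0
    out_dir: Optional[str] = None
    run_subject_cv: bool = True
    run_context: bool = True

    def __post_init__(self) -> None:
        if self.synthetic is None:
            missing = [
                p
                for p in (self.haemo_path, self.geometry_path)
                if p is None or not Path(p).exists()
            ]
            if self.band_paths is None or len(self.band_paths) != 6:
                raise ValueError("band_paths must list six band matrices")
            missing += [p for p in self.band_paths if not Path(p).exists()]
            if missing:
                raise ValueError(f"missing input path(s): {missing}")
        if self.n_spin < 1:
            raise ValueError("n_spin must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded, so
        reruns into different directories stay byte-identical)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """In-memory results of a full pipeline run."""

    geometry: ParcelGeometry
    haemo: ConnectivityMatrix
    bands: BandFCSet
    r2_map: np.ndarray
    global_adj_r2: float
    band_maps: dict[str, np.ndarray]
    contributions: np.ndarray
    dominant_band: np.ndarray
    contrast_table: pd.DataFrame
    anova_f: float
    cv_train: np.ndarray
    cv_test: np.ndarray
    summary: dict


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic child seed per stage, kept below 2^31."""
    return int(
        np.random.SeedSequence([seed & 0x7FFFFFFF, stage]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def _load_inputs(config: AnalysisConfig):
    from .datatypes import CANONICAL_BANDS

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        geometry = make_geometry(syn.n_parcels, seed=syn.seed)
        bands = make_band_fc_set(geometry, syn)
        haemo, truth = make_crossmodal_truth(bands, geometry, syn)
        return geometry, haemo, bands, truth, syn
    geometry = read_geometry(config.geometry_path)
    haemo = read_matrix(config.haemo_path, modality="haemodynamic")
    mats = [read_matrix(p, modality="electromagnetic") for p in config.band_paths]
    for band, m in zip(CANONICAL_BANDS, mats):
        m.band = band
    bands = BandFCSet(bands=CANONICAL_BANDS, matrices=mats)
    return geometry, haemo, bands, None, None


def run_pipeline(config: AnalysisConfig) -> ResultsBundle:
    """Execute every analysis stage and (optionally) write the results."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())

    stage = "input"
    try:
        geometry, haemo, bands, truth, syn = _load_inputs(config)
        labels = list(haemo.labels)

        stage = "mapping"
        _, r2_map = fit_all_regions(haemo, bands)
        global_res = fit_global_model(haemo, bands)
        band_maps, _ = fit_band_specific_models(haemo, bands)

        stage = "dominance"
        _, contributions, dominant = dominance_all_regions(haemo, bands)
        contrast = band_contribution_anova(contributions, bands.band_names)

        stage = "cv"
        cv = regional_cv(haemo, bands, geometry, train_frac=config.train_frac)
        subject_cv = None
        if config.run_subject_cv and syn is not None:
            subj_haemo, subj_bands = make_subject_ensemble(
                haemo,
                bands,
                syn.n_subjects,
                syn.subject_noise_sd,
                seed=_stage_seed(config.seed, 4),
            )
            subject_cv = subject_loo_cv(subj_haemo, subj_bands)

        stage = "nulls"
        spins = generate_spins(geometry, config.n_spin, seed=_stage_seed(config.seed, 5))

        summary: dict = {
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "n_parcels": geometry.n,
            "global_adj_r2": global_res.adj_r2,
            "regional_adj_r2_min": float(r2_map.min()),
            "regional_adj_r2_max": float(r2_map.max()),
            "regional_adj_r2_mean": float(r2_map.mean()),
            "anova_f": contrast.f_statistic,
            "anova_df": [contrast.df_between, contrast.df_within],
            "cv_train_mean": float(np.nanmean(cv.train_map)),
            "cv_test_mean": float(np.nanmean(cv.test_map)),
        }
        r_tt = np.corrcoef(cv.train_map, cv.test_map)[0, 1]
        summary["cv_train_test_consistency_r"] = float(r_tt)
        if subject_cv is not None:
            summary["subject_cv_train_test_consistency_r"] = float(
                np.corrcoef(subject_cv.train_map, subject_cv.test_map)[0, 1]
            )

        stage = "context"
        if config.run_context:
            gradient = principal_gradient(
                haemo, anchor=truth.hierarchy if truth is not None else None
            )
            grad_test = spin_pvalue(r2_map, gradient.scores, spins)
            summary["r2_vs_gradient_rs"] = grad_test.r
            summary["r2_vs_gradient_p_spin"] = grad_test.p_spin
            if truth is not None:
                hier_test = spin_pvalue(r2_map, truth.hierarchy, spins)
                summary["r2_vs_hierarchy_rs"] = hier_test.r
                summary["r2_vs_hierarchy_p_spin"] = hier_test.p_spin
                from scipy.stats import spearmanr

                summary["r2_recovery_vs_target_rs"] = float(
                    spearmanr(r2_map, truth.target_r2).statistic
                )
                depth_set, panel, sc = make_context_maps(
                    geometry,
                    anchor_map=truth.target_r2,
                    config=syn,
                )
                depth = depth_profile_association(
                    r2_map, depth_set, spins, alpha=config.alpha
                )
                summary["depth_peak"] = int(np.argmax(np.abs(depth.correlations)))
                summary["depth_n_significant"] = int(depth.fdr_mask.sum())
                expr = expression_map_association(r2_map, panel, "NPY1R", spins)
                summary["r2_vs_expression_rs"] = expr.r
                summary["r2_vs_expression_p_spin"] = expr.p_spin
                coupling = structure_function_coupling(sc, haemo)
                valid = np.isfinite(coupling)
                sfc_test = spin_pvalue(
                    np.where(valid, coupling, np.nanmean(coupling)), r2_map, spins
                )
                summary["r2_vs_sfc_rs"] = sfc_test.r
                summary["r2_vs_sfc_p_spin"] = sfc_test.p_spin
    except Exception:
        logger.error("pipeline failed in stage %r", stage)
        raise

    if out:
        write_geometry(geometry, out / "geometry.tsv")
        write_matrix(haemo, out / "haemodynamic_fc.tsv")
        for band, m in bands:
            write_matrix(m, out / f"band_fc_{band.name}.tsv")
        write_map(r2_map, out / "r2_map.tsv", name="adj_r2", labels=labels)
        for name, values in band_maps.items():
            write_map(values, out / f"band_r2_{name}.tsv", name="adj_r2", labels=labels)
        pd.DataFrame(
            contributions, columns=bands.band_names
        ).assign(region=labels).to_csv(out / "dominance_contributions.tsv", sep="\t", index=False)
        write_map(dominant, out / "dominant_band.tsv", name="band", labels=labels)
        contrast.table.to_csv(out / "band_contrasts.tsv", sep="\t", index=False)
        write_map(cv.train_map, out / "cv_train.tsv", name="train_r", labels=labels)
        write_map(cv.test_map, out / "cv_test.tsv", name="test_r", labels=labels)
        if truth is not None:
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "weights": truth.weights.tolist(),
                        "noise_sd": truth.noise_sd.tolist(),
                        "hierarchy": truth.hierarchy.tolist(),
                        "target_r2": truth.target_r2.tolist(),
                    }
                )
            )
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    return ResultsBundle(
        geometry=geometry,
        haemo=haemo,
        bands=bands,
        r2_map=r2_map,
        global_adj_r2=global_res.adj_r2,
        band_maps=band_maps,
        contributions=contributions,
        dominant_band=dominant,
        contrast_table=contrast.table,
        anova_f=contrast.f_statistic,
        cv_train=cv.train_map,
        cv_test=cv.test_map,
        summary=summary,
    )
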