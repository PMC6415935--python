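"""End-to-end pipeline: simulate -> preprocess -> decode -> RSA ->
separability -> models -> fusion -> stats, with all artifacts written to a
results directory and a machine-readable summary."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

from .behavior import BehaviorTable, simulate_behavior, select_disambiguated_sets
from .config import RunConfig
from .containers import CONDITIONS
from .decoding import DecoderConfig, decode_timecourse
from .design import build_design
from .fusion import fusion_map, model_rsa_timecourse, roi_rdm
from .io import save_epochs, save_events, save_rdm_series, save_timecourse_table
from .models import MODEL_KINDS, build_model_rdm
from .preprocess import baseline_correct, normalize_across_sensors
from .rdm import (
    average_rdm_series,
    intra_rdm_correlation,
    subject_rdm_series,
    within_condition_dissimilarity_timecourse,
)
from .separability import (
    COND_PAIRS,
    cross_condition_diagonal_timecourse,
    offdiagonal_minus_diagonal_timecourse,
    subject_separability_series,
)
from .simulate import make_ground_truth, simulate_roi_patterns, simulate_sensor_epochs
from .stats import cluster_permutation_timecourse, rdm_order_permutation_null


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis under one master seed; returns the results
    directory.  Re-running with the same config is numerically identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    from . import __version__ as version

    summary: dict = {
        "version": version,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "stage_seeds": seeds,
    }
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        design = build_design(
            config.n_real_sets, config.n_catch_sets, config.n_runs, seed=seeds["design"]
        )
        design.validate()
        summary["design"] = {
            "n_runs": design.n_runs,
            "n_real_sets": design.n_real_sets,
            "n_catch_sets": design.n_catch_sets,
            "n_trials": int(len(design.trials)),
            "sets_per_run": design.sets_per_run,
        }
        gt = make_ground_truth(
            n_sets=design.n_sets,
            n_sensors=config.n_sensors,
            seed=seeds["ground_truth"],
            amp_stim=config.amp_stim,
            amp_rec=config.amp_rec,
            amp_att=config.amp_att,
            amp_evoked=config.amp_evoked,
            noise_scale=config.noise_scale,
        )
        epochs = simulate_sensor_epochs(
            design,
            gt,
            n_subjects=config.n_subjects,
            sampling_rate=config.sampling_rate,
            seed=seeds["epochs"],
            band=config.band,
        )
        brng = np.random.default_rng(seeds["behavior"])
        behavior = BehaviorTable.concat(
            [
                simulate_behavior(
                    design,
                    config.p_spontaneous,
                    config.p_post_recognize,
                    seed=int(brng.integers(0, 2**31 - 1)),
                    lapse=config.lapse,
                    subject=s,
                )
                for s in range(config.n_subjects)
            ]
        )
        save_events(epochs.events, out / "events.tsv")
        save_events(behavior.recognition, out / "behavior_recognition.tsv")
        save_events(behavior.verbal, out / "behavior_verbal.tsv")

        stage = "preprocess"
        epochs = normalize_across_sensors(baseline_correct(epochs))
        save_epochs(epochs, out / "epochs.h5")

        stage = "decode"
        if config.subset in ("subjective", "verbal"):
            subset = select_disambiguated_sets(behavior, config.subset)
        elif config.subset == "catch":
            subset = design.catch_image_ids
        else:
            subset = None
        dec = decode_timecourse(epochs, subset, DecoderConfig(cost=config.decoder_cost))
        save_timecourse_table({"accuracy": dec.accuracy}, epochs.time, out / "decoding.tsv")
        dec_clusters = cluster_permutation_timecourse(
            dec.accuracy, 0.5, config.n_perm_decoding, seeds["decoding_stats"]
        )
        summary["decoding"] = {
            "mean_accuracy": float(dec.accuracy.mean()),
            "significant_clusters": int(np.sum(dec_clusters.pvalues < 0.05)),
        }

        stage = "rsa"
        series = subject_rdm_series(epochs, metric=config.metric)
        group = average_rdm_series(series)
        save_rdm_series(group, out / "rdm_group.h5")
        within = {
            cond: np.stack(
                [within_condition_dissimilarity_timecourse(s, cond) for s in series]
            )
            for cond in CONDITIONS
        }
        save_timecourse_table(within, epochs.time, out / "within_condition_dissimilarity.tsv")
        contrasts = {}
        pairs = (("post", "pre"), ("gray", "pre"), ("post", "gray"))
        for a, b in pairs:
            res = cluster_permutation_timecourse(
                within[a] - within[b], 0.0, config.n_perm_rdm, seeds["rdm_stats"]
            )
            contrasts[f"{a}>{b}"] = int(np.sum(res.pvalues < 0.05))
        intra = {
            "stimulus_based": np.stack(
                [intra_rdm_correlation(s, ("pre", "pre"), ("post", "post")) for s in series]
            ),
            "recognition_based": np.stack(
                [intra_rdm_correlation(s, ("post", "post"), ("gray", "gray")) for s in series]
            ),
        }
        save_timecourse_table(intra, epochs.time, out / "intra_rdm.tsv")
        summary["rsa"] = {"condition_contrast_clusters": contrasts}

        stage = "separability"
        sep_series = subject_separability_series(epochs)
        sep_curves = {}
        for pair in COND_PAIRS:
            name = f"{pair[0]}-{pair[1]}"
            sep_curves[f"diag:{name}"] = np.stack(
                [cross_condition_diagonal_timecourse(s, pair) for s in sep_series]
            )
            sep_curves[f"offdiag-diag:{name}"] = np.stack(
                [offdiagonal_minus_diagonal_timecourse(s, pair) for s in sep_series]
            )
        save_timecourse_table(sep_curves, epochs.time, out / "separability.tsv")

        stage = "models"
        models = {k: build_model_rdm(k, config.n_real_sets) for k in MODEL_KINDS}
        model_rsa = {}
        model_sig = {}
        for k, mdl in models.items():
            res = rdm_order_permutation_null(
                group,
                lambda s, mdl=mdl: model_rsa_timecourse(s, mdl),
                n_perm=config.n_perm_model,
                seed=seeds["model_stats"],
            )
            model_rsa[k] = res.observed
            model_sig[k] = int(np.sum(res.clusters.mask))
        save_timecourse_table(model_rsa, epochs.time, out / "model_rsa.tsv")
        summary["model_rsa"] = {
            k: {
                "peak_time": float(epochs.time[int(np.nanargmax(v))]),
                "significant_timepoints": model_sig[k],
            }
            for k, v in model_rsa.items()
        }

        stage = "fuse"
        rois = simulate_roi_patterns(
            gt,
            {k: tuple(v) for k, v in config.roi_profiles.items()},
            seed=seeds["roi"],
            n_real_sets=config.n_real_sets,
        )
        fmap = fusion_map(
            group,
            roi_rdm(rois),
            models,
            n_perm=config.n_perm_model,
            seed=seeds["fusion"],
        )
        summary["fusion"] = {
            "onsets": {
                k: {r: (None if np.isnan(v) else float(v)) for r, v in d.items()}
                for k, d in fmap.onsets.items()
            }
        }
        np.savez(
            out / "fusion_map.npz",
            time=fmap.time,
            rois=np.array(fmap.rois),
            **{f"commonality_{k}": v for k, v in fmap.commonality.items()},
            **{f"mask_{k}": v for k, v in fmap.mask.items()},
        )
    except Exception as err:  # pragma: no cover - defensive reporting
        raise StageError(
            f"pipeline stage {stage!r} failed (master seed {config.seed}): {err}"
        ) from err

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    return out
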