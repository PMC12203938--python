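"""End-to-end pipeline: correct -> register -> detect -> extract ->
classify -> step-fit -> unit step -> count -> colocalise -> complex table ->
summaries.

Every intermediate table is written as schema-versioned CSV; the run log
records parameter values, per-stage seeds, and molecule counts in and out of
every filter, so that ``n(input) = n(accepted) + sum(n(rejected by reason))``
can be audited at each stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import io, register, simulate, steps, stoich
from .config import FieldEntry, RunConfig
from .errors import BorderExclusionError, EstimationError, SmstoichError
from .types import ChannelTransform, MoleculeSize, Trajectory

logger = logging.getLogger(__name__)

CHANNELS = ("client", "shsp")


# --------------------------------------------------------------------------
# dataset simulation (writes the file layout run_pipeline consumes)


def simulate_dataset(
    out_dir: str | Path,
    seed: int,
    preset: str = "aBc-FLUC",
    timepoints_h: list[float] | None = None,
    replicates: int = 2,
    n_molecules: int = 40,
    acq: simulate.AcquisitionParams | None = None,
    transform: ChannelTransform | None = None,
    labelling: simulate.LabellingModel | None = None,
    fluor: simulate.FluorophoreModel | None = None,
    n_beads: int = 12,
) -> RunConfig:
    """Render a complete simulated experiment (bead pair + dual-channel
    stacks per timepoint and replicate, with manifests) and return a
    ready-to-run :class:`RunConfig` pointing at it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = acq or simulate.AcquisitionParams()
    transform = transform or ChannelTransform.translation(2.3, -1.1)
    labelling = labelling or simulate.LabellingModel({1: 0.5, 2: 0.5})
    fluor = fluor or simulate.FluorophoreModel()
    kin = simulate.preset_kinetics(preset)
    timepoints_h = timepoints_h or kin.timepoints_h

    rng = np.random.default_rng(seed)
    img_a, img_b, _ = simulate.make_bead_pair(
        n_beads, transform, acq, int(rng.integers(2**31))
    )
    io.write_stack(out / "beads_a.tif", img_a[None])
    io.write_stack(out / "beads_b.tif", img_b[None])

    fields = []
    for tp in timepoints_h:
        for rep in range(replicates):
            sub_seed = int(rng.integers(2**31))
            molecules = simulate.simulate_population(
                kin, labelling, n_molecules, tp, sub_seed
            )
            st = kin.state(tp)
            molecules = simulate.add_free_shsp(
                molecules,
                n_free=max(1, n_molecules // 3),
                median_subunits=st.shsp_median_free,
                label_shsp=simulate.LabellingModel({1: 1.0}),
                seed=sub_seed + 1,
            )
            stack_c, stack_s, manifest = simulate.render_field(
                molecules, acq, transform, sub_seed + 2, fluor_client=fluor,
                fluor_shsp=fluor,
            )
            stem = f"tp{tp:g}_rep{rep}"
            io.write_stack(out / f"{stem}_client.tif", stack_c)
            io.write_stack(out / f"{stem}_shsp.tif", stack_s)
            io.write_manifest(manifest, out, stem)
            fields.append(
                FieldEntry(
                    client_stack=str(out / f"{stem}_client.tif"),
                    shsp_stack=str(out / f"{stem}_shsp.tif"),
                    timepoint_h=float(tp),
                    replicate=f"rep{rep}",
                )
            )
    cfg = RunConfig(
        out_dir=str(out / "results"),
        bead_image_a=str(out / "beads_a.tif"),
        bead_image_b=str(out / "beads_b.tif"),
        fields=fields,
        seed=seed,
        field_px=acq.field_px,
        frame_interval_s=acq.exposure_s,
        client_fluors_per_monomer=labelling.mean,
        shsp_fluors_per_monomer=1.0,
    )
    cfg.save(out / "config.yaml")
    return cfg


# --------------------------------------------------------------------------
# pipeline stages


def _get_classifier(config: RunConfig):
    """Either the heuristic filter or a simulator-trained model."""
    if config.classifier == "heuristic":
        return lambda traj: steps.heuristic_classify(traj)
    train_seed = config.stage_seed("classifier")
    rng = np.random.default_rng(train_seed)
    acq = simulate.AcquisitionParams(
        n_frames=300, field_px=config.field_px, shot_noise=False,
        read_noise_sd=25.0, background_mean=0.0,
    )
    fluor = simulate.FluorophoreModel()
    trajs, labels = [], []
    for _ in range(400):
        n = int(rng.integers(1, 12))
        t, _ = simulate.simulate_trajectory(n, fluor, acq, rng)
        trajs.append(t)
        labels.append("stepwise")
    for kind in ("flat", "drift", "non_bleaching", "erratic"):
        for _ in range(100):
            trajs.append(simulate.make_artefact_trace(kind, acq, fluor, rng))
            labels.append("reject")
    model = steps.train_classifier(trajs, labels, seed=train_seed)
    logger.info("trained classifier: validation accuracy %.3f", model.validation_accuracy)
    return lambda traj: steps.classify_trajectory(traj, model)


def _process_field(
    entry: FieldEntry,
    transform: ChannelTransform,
    config: RunConfig,
    classify,
    counts: list[dict],
) -> dict:
    """Detect, extract, classify and step-fit both channels of one field."""
    out: dict = {"entry": entry}
    for channel, path in (("client", entry.client_stack), ("shsp", entry.shsp_stack)):
        stack = io.read_stack(path)
        flat = io.read_stack(config.flatfield_path)[0] if config.flatfield_path else None
        stack = register.correct_stack(stack, config.dark_offset, flat)
        spots = register.detect_spots(
            stack,
            detect_frames=config.detect_frames,
            min_sigma=config.min_sigma,
            max_sigma=config.max_sigma,
            threshold_nsigma=config.threshold_nsigma,
            channel=channel,
            field_id=f"{entry.timepoint_h}h/{entry.replicate}",
        )
        trajs: dict[int, Trajectory] = {}
        fits: dict[int, object] = {}
        n_border = n_reject = n_short = 0
        for s in spots:
            try:
                traj = register.extract_trajectory(
                    stack,
                    s,
                    aperture_radius_px=config.aperture_radius_px,
                    annulus=config.annulus_px,
                    frame_interval_s=config.frame_interval_s,
                )
            except BorderExclusionError:
                n_border += 1
                continue
            traj.timepoint_h = entry.timepoint_h
            traj.replicate = entry.replicate
            if len(traj) < config.k_initial:
                n_short += 1
                continue
            label, _conf = classify(traj)
            if label != "stepwise":
                n_reject += 1
                continue
            fit = steps.detect_steps(
                traj, method=config.step_method, penalty_beta=config.penalty_beta
            )
            trajs[s.index] = traj
            fits[s.index] = fit
        counts.append(
            {
                "field": f"{entry.timepoint_h}h/{entry.replicate}",
                "channel": channel,
                "n_spots": len(spots),
                "n_border_excluded": n_border,
                "n_too_short": n_short,
                "n_classifier_rejected": n_reject,
                "n_accepted": len(trajs),
            }
        )
        out[channel] = {"spots": spots, "trajs": trajs, "fits": fits}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``.

    Returns a dict of result tables (also written to ``config.out_dir``).
    Stage failures halt with the stage name and the molecule counts at the
    point of failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("smstoich")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

        # -- registration --------------------------------------------------
        if not config.bead_image_a or not Path(config.bead_image_a).exists():
            raise SmstoichError(
                "registration: bead image pair missing "
                f"({config.bead_image_a!r}); supply bead_image_a/bead_image_b"
            )
        transform = register.estimate_transform(
            io.read_stack(config.bead_image_a)[0],
            io.read_stack(config.bead_image_b)[0],
            model=config.transform_model,
        )
        logger.info(
            "registration: %d beads, residual %.4f px",
            transform.n_beads,
            transform.residual_rms_px,
        )

        classify = _get_classifier(config)

        # -- per-field detection/extraction/step fitting -------------------
        counts: list[dict] = []
        fields = [
            _process_field(e, transform, config, classify, counts)
            for e in config.fields
        ]
        counts_df = pd.DataFrame(counts)
        io.write_table(counts_df, out_dir / "filter_counts.csv", "filter_counts")

        # -- unit step per channel (pooled over the experiment) ------------
        i_step: dict[str, float] = {}
        for channel in CHANNELS:
            all_fits = [f for fl in fields for f in fl[channel]["fits"].values()]
            try:
                i_step[channel] = steps.estimate_unit_step(all_fits)
            except EstimationError:
                raise SmstoichError(
                    f"unit-step estimation failed for channel {channel!r}: "
                    f"{len(all_fits)} accepted trajectories"
                )
        logger.info("I_step per channel: %s", i_step)

        # -- counting + colocalisation + complex records -------------------
        fluors = {
            "client": config.client_fluors_per_monomer,
            "shsp": config.shsp_fluors_per_monomer,
        }
        all_records = []
        coloc_rows = []
        spot_rows = []
        fit_rows = []
        for fl in fields:
            entry: FieldEntry = fl["entry"]
            sizes: dict[str, dict[int, MoleculeSize]] = {}
            for channel in CHANNELS:
                sizes[channel] = {}
                for idx, traj in fl[channel]["trajs"].items():
                    size = steps.count_subunits(
                        traj, i_step[channel], k_initial=config.k_initial
                    )
                    size = steps.correct_for_labelling(size, fluors[channel])
                    size.spot_index = idx
                    sizes[channel][idx] = size
                for s in fl[channel]["spots"]:
                    spot_rows.append(
                        {
                            "field": f"{entry.timepoint_h}h/{entry.replicate}",
                            "channel": channel,
                            "index": s.index,
                            "x": s.x,
                            "y": s.y,
                            "peak_intensity": s.peak_intensity,
                        }
                    )
                for idx, fit in fl[channel]["fits"].items():
                    fit_rows.append(
                        {
                            "field": f"{entry.timepoint_h}h/{entry.replicate}",
                            "channel": channel,
                            "index": idx,
                            "n_steps": fit.n_steps,
                            "final_step": fit.final_step,
                            "incomplete_bleach": fit.incomplete_bleach,
                        }
                    )
            res = coloc_mod.colocalise(
                fl["client"]["spots"],
                fl["shsp"]["spots"],
                transform,
                radius_px=config.match_radius_px,
                field_px=config.field_px,
            )
            coloc_rows.append(
                {
                    "timepoint_h": entry.timepoint_h,
                    "replicate": entry.replicate,
                    "raw_fraction": res.raw_fraction,
                    "chance_fraction": res.chance_fraction,
                    "corrected_fraction": res.corrected_fraction,
                    "n_client": res.n_client,
                    "n_shsp": res.n_shsp,
                }
            )
            all_records.extend(
                stoich.build_complex_table(
                    sizes["client"],
                    sizes["shsp"],
                    res.pairs,
                    entry.timepoint_h,
                    entry.replicate,
                )
            )

        coloc_df = pd.DataFrame(coloc_rows)
        records_df = stoich.records_to_frame(all_records)
        io.write_table(pd.DataFrame(spot_rows), out_dir / "spots.csv", "spots")
        io.write_table(pd.DataFrame(fit_rows), out_dir / "stepfits.csv", "stepfits")
        io.write_table(coloc_df, out_dir / "colocalisation.csv", "colocalisation")
        io.write_table(records_df, out_dir / "complexes.csv", "complexes")

        summary = stoich.summarize_timecourse(
            records_df,
            coloc_fractions=coloc_df,
            n_boot=config.bootstrap_resamples,
            seed=config.stage_seed("bootstrap"),
        )
        io.write_table(summary, out_dir / "timecourse.csv", "timecourse")
        io.write_table(
            pd.DataFrame([i_step]), out_dir / "unit_step.csv", "unit_step"
        )
        logger.info("pipeline complete: %d molecules", len(records_df))
        return {
            "transform": transform,
            "i_step": i_step,
            "filter_counts": counts_df,
            "colocalisation": coloc_df,
            "complexes": records_df,
            "timecourse": summary,
        }
    except SmstoichError:
        logger.exception("pipeline halted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
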