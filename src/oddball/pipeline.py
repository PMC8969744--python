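"""End-to-end experiment runner: simulate -> preprocess -> ERP -> decode -> markers.

Reproduces the full two-state (PRE vs. HYP) odd-ball session structure on
synthetic data: per state, two blocks (a and b) of 78 five-sound series
are scheduled and rendered into a continuous recording; both states then
flow through the ERP, decoding and pseudo-resting-state marker analyses.
Every stage writes its results under the output directory and is recorded
in a manifest with the seeds, config hash and per-stage wall time, so a
rerun with the same config and seed regenerates identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as obio
from .containers import EpochSet, concatenate_epochs
from .erp_stats import (
    COMPONENT_WINDOWS,
    component_amplitude,
    component_tests,
    mass_univariate_anova,
    roi_trial_series,
)
from .montage import default_rois, disc_montage
from .paradigm import EventTimeline, build_block, schedule_events
from .preprocess import (
    BASELINE_ERP,
    BASELINE_SPECTRAL,
    FilterSpec,
    bandpass,
    baseline_correct,
    epoch_and_align,
    realign_to_fifth,
    reject_artifacts,
    rereference_average,
)
from .synth import SimulationConfig, default_components, simulate_recording

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_experiment", "derive_seed",
           "simulate_session", "preprocess_session"]

#: ROI name used for each component
COMPONENT_ROI = {"P1": "P1", "MMN": "MMN_P3a", "P3a": "MMN_P3a", "P3b": "P3b"}


def derive_seed(base: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(base) * 1000003 + zlib.crc32(label.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Declarative description of a full synthetic experiment run.

    Amplitude parameters are deviant-minus-standard effects in uV except
    ``p1_amplitude`` (an unconditional response to every sound).  The
    effect dictionaries map state name to effect size, e.g. the
    reference configuration injects a P3b effect in PRE only and a P3a
    effect in HYP only.
    """

    # paradigm
    states: tuple = ("PRE", "HYP")
    blocks: tuple = ("a", "b")
    n_series_per_block: int = 78
    deviant_fraction: float = 0.33
    soa: float = 0.150
    isi_min: float = 1.350
    isi_max: float = 1.650
    isi_step: float = 0.050
    sound_duration: float = 0.050
    inter_block_gap: float = 5.0
    # simulation
    n_channels: int = 64
    eeg_rate: float = 250.0
    noise_std: float = 7.0
    spatial_mixing: float = 0.6
    topo_noise_std: float = 1.0
    alpha_osc_amp: float = 1.0
    p1_amplitude: float = 1.0
    mmn_effect: float = 0.0
    p3a_effect: dict = field(default_factory=lambda: {"PRE": 0.0, "HYP": 2.23})
    p3b_effect: dict = field(default_factory=lambda: {"PRE": 1.36, "HYP": 0.0})
    # analysis toggles and sizes
    run_erp: bool = True
    run_decoding: bool = True
    run_gat: bool = False
    run_markers: bool = True
    decoding_decim: int = 20
    decoding_window: tuple | None = None  # e.g. (0.0, 0.8) re fifth sound
    decoding_folds: int = 7
    gat_folds: int = 5
    n_perm_decoding: int = 100
    n_perm_cluster: int = 1000
    wsmi_bands: tuple = ("alpha",)
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("states", "blocks", "wsmi_bands", "decoding_window"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return RunConfig(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as f:
            return RunConfig.from_dict(yaml.safe_load(f))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def small(self, **overrides) -> "RunConfig":
        """A reduced-size copy for quick runs (fewer channels / series)."""
        d = self.to_dict()
        d.update(
            n_channels=16, n_series_per_block=30, n_perm_decoding=50,
            n_perm_cluster=200,
        )
        d.update(overrides)
        return RunConfig.from_dict(d)


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, outputs, wall_s: float) -> None:
        self.stages.append(
            {"name": name, "outputs": [str(p) for p in outputs], "wall_s": wall_s}
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_session_timeline(config: RunConfig, state: str, seed: int) -> EventTimeline:
    """Schedule the state's blocks back-to-back into one absolute timeline."""
    parts = []
    t0 = 1.0
    for b in config.blocks:
        plan = build_block(
            b, config.n_series_per_block, config.deviant_fraction,
            rng_seed=derive_seed(seed, f"block-{state}-{b}"), soa=config.soa,
        )
        tl = schedule_events(
            plan, soa=config.soa, isi_min=config.isi_min, isi_max=config.isi_max,
            isi_step=config.isi_step, rng_seed=derive_seed(seed, f"events-{state}-{b}"),
            t_start=t0, sound_duration=config.sound_duration,
        )
        parts.append(tl)
        t0 = tl.end_time + config.inter_block_gap
    return EventTimeline.concatenate(parts).with_state(state)


def _simulation_config(config: RunConfig, montage, seed: int, state: str) -> SimulationConfig:
    comps = default_components(
        montage,
        p1=config.p1_amplitude,
        mmn=config.mmn_effect,
        p3a=config.p3a_effect,
        p3b=config.p3b_effect,
    )
    return SimulationConfig(
        montage=montage,
        components=comps,
        eeg_rate=config.eeg_rate,
        noise_std=config.noise_std,
        spatial_mixing=config.spatial_mixing,
        topo_noise_std=config.topo_noise_std,
        oscillations={10.0: config.alpha_osc_amp},
        rng_seed=derive_seed(seed, f"noise-{state}"),
    )


def simulate_session(config: RunConfig, seed: int):
    """Simulate one continuous recording per state.

    Returns ``(montage, {state: (timeline, continuous, ground_truth)})``.
    """
    montage = disc_montage(config.n_channels)
    sessions = {}
    for state in config.states:
        tl = build_session_timeline(config, state, seed)
        cont, gt = simulate_recording(_simulation_config(config, montage, seed, state), tl)
        sessions[state] = (tl, cont, gt)
    return montage, sessions


def preprocess_session(sessions, mode: str = "erp", soa: float = 0.150):
    """Filter, epoch, reject, re-reference, realign and baseline all states.

    ``mode`` selects the ERP (0.5-10 Hz, 800-ms pre-fifth baseline) or
    spectral (0.5-45 Hz, 200-ms pre-first-sound baseline) path.  Returns
    ``(EpochSet, {state: RejectionReport})`` with all states concatenated.
    """
    spec = FilterSpec.erp() if mode == "erp" else FilterSpec.spectral()
    baseline = BASELINE_ERP if mode == "erp" else BASELINE_SPECTRAL
    parts, reports = [], {}
    for state, (tl, cont, _gt) in sessions.items():
        filt = bandpass(cont, spec)
        epochs = epoch_and_align(filt, tl)
        epochs, report = reject_artifacts(epochs)
        epochs = rereference_average(epochs)
        epochs = realign_to_fifth(epochs, soa=soa)
        epochs = baseline_correct(epochs, baseline)
        parts.append(epochs)
        reports[state] = report
    return concatenate_epochs(parts), reports


def erp_analysis(epochs: EpochSet, alpha: float = 0.05) -> dict:
    """ROI mass-univariate ANOVA traces plus component-level statistics."""
    rois = default_rois(epochs.montage)
    results = {"components": {}, "anova": {}}
    for comp, roi_name in COMPONENT_ROI.items():
        series, meta = roi_trial_series(epochs, rois[roi_name])
        amps = component_amplitude(series, epochs.times, COMPONENT_WINDOWS[comp])
        results["components"][comp] = component_tests(amps, meta, name=comp,
                                                      alpha=alpha).to_dict()
    for roi_name, sensors in rois.items():
        series, meta = roi_trial_series(epochs, sensors)
        trace = mass_univariate_anova(series, meta, alpha=alpha, times=epochs.times)
        results["anova"][roi_name] = {
            "times": trace.times,
            "interaction_mask": trace.mask["interaction"],
            "stimulus_mask": trace.mask["stimulus"],
            "state_mask": trace.mask["state"],
        }
    return results


def run_experiment(config: RunConfig, outdir, seed: int = 0) -> RunManifest:
    """Execute the configured stages and write results + manifest to outdir."""
    from .decoding import DecoderSpec, permutation_null, temporal_generalization

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), config_hash=config.config_hash(),
                           seed=seed)

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    montage, sessions = simulate_session(config, seed)
    outputs = []
    for state, (tl, cont, gt) in sessions.items():
        ev = outdir / f"events_{state}.tsv"
        obio.write_events_tsv(ev, tl)
        gtp = outdir / f"ground_truth_{state}.json"
        obio.write_json(gtp, {"injected": {k: {f"{a}_{b}": v for (a, b), v in d.items()}
                                          for k, d in gt.injected.items()},
                              "rng_seed": gt.rng_seed})
        outputs += [ev, gtp]
    manifest.add_stage("simulate", outputs, time.perf_counter() - t0)

    # --- preprocess (ERP mode) -----------------------------------------
    t0 = time.perf_counter()
    epochs_erp, reports = preprocess_session(sessions, mode="erp", soa=config.soa)
    rp = outdir / "rejection_erp.json"
    obio.write_json(rp, {st: r.to_dict() for st, r in reports.items()})
    manifest.add_stage("preprocess_erp", [rp], time.perf_counter() - t0)
    for st, r in reports.items():
        if not r.passed:
            manifest.warnings.append(f"{st}: rejection pass criterion not met")

    results_files = []

    # --- ERP statistics -------------------------------------------------
    if config.run_erp:
        t0 = time.perf_counter()
        erp = erp_analysis(epochs_erp)
        p = outdir / "erp_results.json"
        obio.write_json(p, erp)
        cell_rows = []
        for comp, res in erp["components"].items():
            for cell, mean in res["cell_means"].items():
                st, stim = cell.split("_")
                cell_rows.append({"component": comp, "state": st,
                                  "stimulus": stim, "mean_uV": mean})
        import pandas as pd

        tsv = outdir / "component_cell_means.tsv"
        pd.DataFrame(cell_rows).to_csv(tsv, sep="\t", index=False)
        manifest.add_stage("erp", [p, tsv], time.perf_counter() - t0)
        results_files.append(p)

    # --- decoding -------------------------------------------------------
    if config.run_decoding:
        t0 = time.perf_counter()
        dec_out = {}
        outputs = []
        for state in config.states:
            sub = epochs_erp.select_trials(
                epochs_erp.metadata["state"].to_numpy() == state
            )
            if config.decoding_window is not None:
                sub = sub.crop(tuple(config.decoding_window))
            spec = DecoderSpec(cv_folds=config.decoding_folds,
                               rng_seed=derive_seed(seed, f"folds-{state}"),
                               decim=config.decoding_decim)
            res = permutation_null(sub, spec, n_perm=config.n_perm_decoding,
                                   rng_seed=derive_seed(seed, f"perm-{state}"))
            dec_out[state] = {
                "times": res.times, "auc": res.auc, "p": res.p,
                "p_fdr": res.p_adj, "significant": res.mask,
                "n_permutations": res.n_permutations,
            }
            if config.run_gat:
                gat = temporal_generalization(
                    sub, DecoderSpec(cv_folds=config.gat_folds,
                                     rng_seed=derive_seed(seed, f"gat-{state}"),
                                     decim=config.decoding_decim))
                dec_out[state]["gat_times"] = gat.times
                dec_out[state]["gat_auc"] = gat.auc_matrix
        p = outdir / "decoding_results.json"
        obio.write_json(p, dec_out)
        outputs.append(p)
        manifest.add_stage("decoding", outputs, time.perf_counter() - t0)

    # --- pseudo-resting-state markers ----------------------------------
    if config.run_markers:
        from .state_markers import (
            BANDS, WSMI_TAU_SAMPLES, cluster_permutation_contrast,
            normalized_band_power, sensor_bayes_map, wsmi,
        )

        t0 = time.perf_counter()
        epochs_sp, _ = preprocess_session(sessions, mode="spectral", soa=config.soa)
        states = epochs_sp.metadata["state"].to_numpy()
        marker_sets = dict(normalized_band_power(epochs_sp))
        for band in config.wsmi_bands:
            res = wsmi(epochs_sp, tau=WSMI_TAU_SAMPLES[band])
            res.topography.name = f"wsmi_{band}"
            marker_sets[f"wsmi_{band}"] = res.topography
        contrasts = {}
        for name, topo in marker_sets.items():
            A = topo.values[states == config.states[1]]  # HYP
            B = topo.values[states == config.states[0]]  # PRE
            ct = cluster_permutation_contrast(
                A, B, epochs_sp.montage.adjacency, n_perm=config.n_perm_cluster,
                rng_seed=derive_seed(seed, f"cluster-{name}"),
            )
            contrasts[name] = {
                "t_map": ct.t_map,
                "clusters": [
                    {"sensors": c.sensors, "mass": c.mass, "p": c.p, "sign": c.sign}
                    for c in ct.clusters
                ],
                "bf10_map": sensor_bayes_map(A, B),
                "n_permutations": ct.n_permutations,
            }
        p = outdir / "marker_results.json"
        obio.write_json(p, contrasts)
        manifest.add_stage("markers", [p], time.perf_counter() - t0)

    if config.make_plots:
        try:
            from . import viz

            figs = viz.standard_report_figures(outdir)
            manifest.add_stage("figures", figs, 0.0)
        except Exception as err:  # pragma: no cover - plotting is best-effort
            manifest.warnings.append(f"figure generation failed: {err}")

    mp = outdir / "manifest.json"
    obio.write_json(mp, manifest.to_dict())
    return manifest
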