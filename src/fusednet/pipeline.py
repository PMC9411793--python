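"""End-to-end orchestration: simulate -> preprocess -> fMRI prior ->
source localization -> ROI/PLI connectivity -> network analysis.

Every stage reads and writes plain TSV/JSON so each can be run (and tested)
in isolation; a run manifest records the configuration hash, seed, package
version and a checksum for every written file, making byte-identical
reproduction checkable.  Wall-clock timestamps go to ``run.log`` only, so
two runs with the same config and seed produce identical manifests.
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
from .fmriprior import (
    build_fmri_prior,
    build_regressor,
    canonical_hrf,
    glm_fit,
    map_voxels_to_sources,
    threshold_map,
)
from .inverse import (
    DEFAULT_WINDOWS,
    estimate_noise_cov,
    fmne_solve,
    mne_kernel,
    window_covariance,
    window_indices,
)
from .netgraph import (
    BinaryNetwork,
    binarize,
    betweenness,
    network_summary,
    paired_edge_ttest,
    select_threshold,
    significant_network,
)
from .preprocess import (
    DEFAULT_BANDS,
    BandDefinition,
    bandpass_fir_array,
    baseline_correct,
    SensorEpochs,
    rereference_common_average,
)
from .roiconn import (
    DK_LABELS,
    default_parcellation,
    extract_roi_timeseries,
    pli_matrix,
)
from .synthdata import StudyConfig, SimulatedStudy, generate_study, load_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "network_stage", "report"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables in one flat, JSON-serializable record.

    Defaults equal the printed analysis values wherever the study states
    them: 15 subjects, three conditions, five bands, the three analysis
    windows, PLI threshold 0.30, FDR q = 0.05, SNR-based regularization with
    snr = 3.
    """

    # study generation
    n_subjects: int = 15
    n_trials: int = 30
    n_sensors: int = 16
    n_sources: int = 200
    sampling_rate: float = 250.0
    snr: float = 3.0
    n_voxels: int = 400
    n_volumes: int = 200
    tr: float = 2.0
    bold_noise_sd: float = 1.0
    # preprocessing
    rereference: bool = True
    filter_lo: float = 0.01
    filter_hi: float = 40.0
    baseline: tuple[float, float] = (-0.2, 0.0)
    # fMRI prior
    hrf_dt: float = 0.1
    p_unc: float = 0.001
    voxel_radius_factor: float = 2.0  # x source spacing
    # inverse
    inverse_snr: float = 3.0
    lam2: float | None = None
    loading_frac: float = 0.05
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    floor_frac: float = 0.01
    # connectivity
    roi_agg: str = "mean"  # mean | abs_mean | first_pc
    connectivity_scope: str = "full_epoch"  # full_epoch | windows
    trim_frac: float = 0.05
    bands: tuple[tuple[str, float, float], ...] = tuple(
        (b.name, b.lo, b.hi) for b in DEFAULT_BANDS
    )
    # network
    contrast: tuple[str, str] = ("negative-watch", "negative-reappraisal")
    q: float = 0.05
    threshold: float | str = 0.30  # value in (0,1) or "auto"
    edge_rule: str = "intersection"  # intersection | threshold_only | significance_only
    sigma_n_random: int = 20
    sigma_seed: int = 0

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(n, lo, hi) for n, lo, hi in self.bands)

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            n_subjects=self.n_subjects,
            n_trials=self.n_trials,
            n_sensors=self.n_sensors,
            n_sources=self.n_sources,
            sampling_rate=self.sampling_rate,
            snr=self.snr,
            n_voxels=self.n_voxels,
            n_volumes=self.n_volumes,
            tr=self.tr,
            bold_noise_sd=self.bold_noise_sd,
            hrf_dt=self.hrf_dt,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = [list(w) for w in d["windows"]]
        d["bands"] = [list(b) for b in d["bands"]]
        d["baseline"] = list(d["baseline"])
        d["contrast"] = list(d["contrast"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key, caster in (
            ("windows", lambda v: tuple(tuple(w) for w in v)),
            ("bands", lambda v: tuple(tuple(b) for b in v)),
            ("baseline", tuple),
            ("contrast", tuple),
        ):
            if key in d:
                d[key] = caster(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# helpers


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix_tsv(path: Path, values: np.ndarray, labels=DK_LABELS) -> None:
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def _read_matrix_tsv(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def _centering(m: int) -> np.ndarray:
    return np.eye(m) - np.ones((m, m)) / m


def _preprocess_subject(
    eeg: dict[str, np.ndarray], time_axis: np.ndarray, cfg: PipelineConfig
) -> dict[str, SensorEpochs]:
    out = {}
    for cond, arr in eeg.items():
        ep = SensorEpochs(arr, time_axis, cfg.sampling_rate, condition=cond)
        if cfg.rereference:
            ep = rereference_common_average(ep)
        from .preprocess import bandpass_fir

        ep = bandpass_fir(ep, cfg.filter_lo, cfg.filter_hi)
        ep = baseline_correct(ep, *cfg.baseline)
        out[cond] = ep
    return out


def _subject_prior(study: SimulatedStudy, rec, cfg: PipelineConfig):
    hrf = canonical_hrf(cfg.hrf_dt)
    reg = build_regressor(
        rec.trial_features, rec.onsets, hrf, study.tr, rec.bold.shape[1]
    )
    glm = glm_fit(rec.bold, reg)
    mask = threshold_map(glm, p_unc=cfg.p_unc)
    radius = (
        cfg.voxel_radius_factor
        * study.head_model.source_spacing
        * np.linalg.norm(study.head_model.source_positions[0])
    )
    active = map_voxels_to_sources(
        mask, study.voxel_positions, study.head_model.source_positions, radius
    )
    prior = build_fmri_prior(active, study.head_model.n_sources)
    return prior, glm, mask, active


def _fused_source_trials(
    ep: SensorEpochs, G: np.ndarray, C, prior, cfg: PipelineConfig
) -> np.ndarray:
    """Per-trial fused source estimates feeding connectivity.

    full_epoch scope: FWMNE with one window spanning the whole epoch (fMNE
    pass, then a fused re-estimate).  windows scope: the three analysis
    windows, concatenated in time order.
    """
    t = ep.time_axis
    k_fmne = mne_kernel(G, C, prior, snr=cfg.inverse_snr, lam2=cfg.lam2)
    if cfg.connectivity_scope == "full_epoch":
        spans = [(0, ep.n_samples)]
    elif cfg.connectivity_scope == "windows":
        spans = [window_indices(t, w) for w in cfg.windows]
    else:
        raise ValueError(f"unknown connectivity_scope {cfg.connectivity_scope!r}")
    out = []
    for tr in range(ep.n_trials):
        y = ep.data[:, :, tr]
        j_fmne = k_fmne @ y
        parts = []
        for lo, hi in spans:
            r_win = window_covariance(j_fmne, (lo, hi), floor_frac=cfg.floor_frac)
            k_win = mne_kernel(G, C, r_win, snr=cfg.inverse_snr, lam2=cfg.lam2)
            parts.append(k_win @ y[:, lo:hi])
        out.append(np.concatenate(parts, axis=1))
    return np.stack(out)  # (n_trials, s, d_used)


# ---------------------------------------------------------------------------
# stages


def connectivity_stage(
    study: SimulatedStudy, cfg: PipelineConfig, out_dir: Path | None = None
) -> dict:
    """Per subject x condition x band trial-averaged PLI matrices.

    Returns {band: {condition: [PLIMatrix per subject]}} and optionally
    writes one TSV per matrix.
    """
    bands = cfg.band_definitions()
    parc = default_parcellation(study.head_model)
    G = study.lead_field.G
    if cfg.rereference:
        G = _centering(G.shape[0]) @ G
    result: dict = {b.name: {} for b in bands}
    for rec in study.subjects:
        epochs = _preprocess_subject(rec.eeg, study.time_axis, cfg)
        pooled = np.concatenate([ep.data for ep in epochs.values()], axis=2)
        C = estimate_noise_cov(
            (pooled, study.time_axis), baseline=cfg.baseline,
            loading_frac=cfg.loading_frac,
        )
        prior, _, _, _ = _subject_prior(study, rec, cfg)
        for cond, ep in epochs.items():
            trials = _fused_source_trials(ep, G, C, prior, cfg)
            roi = np.stack(
                [
                    extract_roi_timeseries(j, parc, agg=cfg.roi_agg).data
                    for j in trials
                ]
            )  # (n_trials, 68, d)
            for band in bands:
                filt = bandpass_fir_array(
                    roi, band.lo, band.hi, cfg.sampling_rate, axis=2
                )
                mat = pli_matrix(
                    list(filt), band=band.name, condition=cond,
                    subject=rec.subject, trim_frac=cfg.trim_frac,
                )
                result[band.name].setdefault(cond, []).append(mat)
                if out_dir is not None:
                    _write_matrix_tsv(
                        out_dir
                        / f"sub-{rec.subject:02d}_{cond}_{band.name}_pli.tsv",
                        mat.values,
                    )
        logger.info("connectivity: subject %d done", rec.subject)
    return result


def network_stage(
    pli: dict, cfg: PipelineConfig, out_dir: Path | None = None
) -> dict:
    """Group network analysis per band: edge t-tests with FDR, threshold
    binarization of the group-mean PLI, edge retention, and graph metrics."""
    results = {}
    cond_a, cond_b = cfg.contrast
    for band_name, by_cond in pli.items():
        if cond_a not in by_cond or cond_b not in by_cond:
            raise ValueError(
                f"band {band_name}: contrast conditions {cfg.contrast} not present"
            )
        mats_a, mats_b = by_cond[cond_a], by_cond[cond_b]
        stats_ = paired_edge_ttest(mats_a, mats_b, q=cfg.q)
        from .netgraph import _pli_values

        group_mean = np.mean(
            [_pli_values(m) for m in mats_a] + [_pli_values(m) for m in mats_b],
            axis=0,
        )
        if cfg.threshold == "auto":
            thr = select_threshold(
                group_mean, n_random=cfg.sigma_n_random, seed=cfg.sigma_seed
            )
        else:
            thr = float(cfg.threshold)
        thresholded = binarize(group_mean, thr)
        if cfg.edge_rule == "intersection":
            net = significant_network(thresholded, stats_)
        elif cfg.edge_rule == "threshold_only":
            net = thresholded
        elif cfg.edge_rule == "significance_only":
            net = BinaryNetwork(stats_.significant_matrix(), threshold=thr)
        else:
            raise ValueError(f"unknown edge_rule {cfg.edge_rule!r}")
        metrics = betweenness(net)
        summ = network_summary(
            net, n_random=cfg.sigma_n_random, seed=cfg.sigma_seed
        )
        results[band_name] = {
            "edge_stats": stats_,
            "group_mean_pli": group_mean,
            "threshold": thr,
            "network": net,
            "metrics": metrics,
            "summary": summ,
        }
        if out_dir is not None:
            _write_matrix_tsv(
                out_dir / f"{band_name}_group_mean_pli.tsv", group_mean
            )
            _write_matrix_tsv(
                out_dir / f"{band_name}_adjacency.tsv",
                net.adjacency.astype(int),
            )
            iu = np.triu_indices(stats_.K, k=1)
            edges = pd.DataFrame(
                {
                    "node_i": [DK_LABELS[i] for i in iu[0]],
                    "node_j": [DK_LABELS[j] for j in iu[1]],
                    "t": stats_.t,
                    "p": stats_.p,
                    "significant": stats_.significant.astype(int),
                    "zero_variance": stats_.zero_variance.astype(int),
                }
            )
            edges.to_csv(
                out_dir / f"{band_name}_edge_stats.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
            nodes = pd.DataFrame(
                {
                    "label": list(DK_LABELS),
                    "betweenness": metrics.betweenness,
                    "degree": metrics.degree,
                }
            )
            nodes.to_csv(
                out_dir / f"{band_name}_nodes.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
            (out_dir / f"{band_name}_summary.json").write_text(
                json.dumps(
                    {
                        "band": band_name,
                        "threshold": thr,
                        "dof": stats_.dof,
                        "q": stats_.q_threshold,
                        "n_significant_edges": int(stats_.significant.sum()),
                        "density": summ.density,
                        "M_edges": summ.M_edges,
                        "mean_degree": summ.mean_degree,
                        "small_world_sigma": summ.small_world_sigma,
                        "sigma_note": summ.sigma_note,
                    },
                    indent=1,
                )
            )
    return results


def network_stage_from_dir(
    pli_dir: str | Path, cfg: PipelineConfig, out_dir: str | Path | None = None
) -> dict:
    """Run the network stage alone on precomputed PLI TSVs
    (``sub-XX_<condition>_<band>_pli.tsv``)."""
    from .roiconn import PLIMatrix

    pli_dir = Path(pli_dir)
    pli: dict = {}
    for path in sorted(pli_dir.glob("sub-*_pli.tsv")):
        stem = path.name[: -len("_pli.tsv")]
        sub_tag, cond, band = stem.split("_", 2)
        mat = PLIMatrix(
            values=_read_matrix_tsv(path),
            band=band,
            condition=cond,
            subject=int(sub_tag.split("-")[1]),
        )
        pli.setdefault(band, {}).setdefault(cond, []).append(mat)
    if not pli:
        raise FileNotFoundError(f"no PLI TSV files found in {pli_dir}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    return network_stage(pli, cfg, out)


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "fusednet_run",
    study: SimulatedStudy | None = None,
) -> dict:
    """Execute the full pipeline and write all outputs plus a manifest.

    Returns the manifest dictionary.  A precomputed ``study`` (for example
    loaded from disk) bypasses the simulation stage.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    (out / "pli").mkdir(parents=True, exist_ok=True)
    (out / "network").mkdir(exist_ok=True)
    log_lines = []

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{name}")

    stage("simulate")
    if study is None:
        study = generate_study(cfg.study_config(), seed=seed)
    stage("preprocess+prior+localize+connect")
    pli = connectivity_stage(study, cfg, out / "pli")
    stage("network")
    network_stage(pli, cfg, out / "network")
    stage("report")
    report(out)

    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    files = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": int(seed),
        "version": __version__,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest


def report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-band ranking of nodes by betweenness centrality, plus density and
    small-world index, read back from a completed run."""
    run_dir = Path(run_dir)
    net_dir = run_dir / "network"
    if not net_dir.is_dir():
        raise FileNotFoundError(f"no network outputs under {run_dir}")
    rep_dir = run_dir / "report"
    rep_dir.mkdir(exist_ok=True)
    tables = {}
    for nodes_path in sorted(net_dir.glob("*_nodes.tsv")):
        band = nodes_path.name[: -len("_nodes.tsv")]
        nodes = pd.read_csv(nodes_path, sep="\t")
        summary = json.loads((net_dir / f"{band}_summary.json").read_text())
        ranked = nodes.sort_values(
            ["betweenness", "label"], ascending=[False, True]
        ).reset_index(drop=True)
        ranked = ranked[ranked["betweenness"] > 0]
        ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
        ranked["density"] = summary["density"]
        ranked["small_world_sigma"] = summary["small_world_sigma"]
        ranked.to_csv(
            rep_dir / f"{band}_ranking.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        tables[band] = ranked
    if not tables:
        raise FileNotFoundError("no band outputs to report on")
    return tables
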