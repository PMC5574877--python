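"""End-to-end orchestration: simulate or ingest -> preprocess -> spectrogram
-> dB normalization -> PCA -> k-means -> Markov/dwell statistics -> reports.

`analyze_cohort` is the library entry point (used by tests and the
acceptance script); `run_pipeline` adds file I/O, stage logging and a run
manifest for command-line use.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from . import markov, spectral, states
from .errors import InsufficientDataError
from .synthgen import simulate_cohort
from .types import (
    DbDeviationSpectrogram,
    DwellRecord,
    ReportMatrix,
    SignalTrace,
    StateSequence,
)

log = logging.getLogger("lfpstates.pipeline")

__all__ = ["AnalysisResult", "RunManifest", "analyze_cohort", "run_pipeline"]


@dataclass
class AnalysisResult:
    """Everything the analysis chain produces, in memory."""

    feature_index: pd.MultiIndex
    scores: np.ndarray
    explained_variance: np.ndarray
    labeling: states.Labeling
    label_sequences: list[StateSequence]
    pooled_transition: markov.TransitionMatrix
    pooled_report: ReportMatrix
    jackknife: tuple[ReportMatrix, ReportMatrix] | None
    per_condition: dict[str, ReportMatrix]
    dwells: list[DwellRecord]
    dwell_fits: dict[int, markov.DwellFit]
    stickiness: float
    window_duration_s: float
    agreement: float | None = None
    label_mapping: dict[int, int] | None = None
    db_spectrograms: list[DbDeviationSpectrogram] = field(default_factory=list)

    def mean_dwell_s(self, uncensored_only: bool = True) -> float:
        ds = [d.duration_s for d in self.dwells if not (uncensored_only and d.censored)]
        return float(np.mean(ds))


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config_snapshot: dict
    seeds: dict
    input_digests: dict
    outputs: list[str]
    stages: list[dict]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return path


def _preprocess(trace: SignalTrace, params: dict) -> SignalTrace:
    if params.get("lowpass_hz"):
        trace = spectral.zero_phase_lowpass(trace, float(params["lowpass_hz"]))
    if params.get("target_rate_hz"):
        trace = spectral.decimate_to(trace, float(params["target_rate_hz"]))
    return trace


def analyze_cohort(
    traces: list[SignalTrace],
    params: dict,
    truths: list[StateSequence] | None = None,
) -> AnalysisResult:
    """Run the full analysis chain on a cohort of traces.

    ``params`` keys (all optional, with defaults): window_duration_s (10),
    band_hz ((0.5, 120)), n_components (3), k (8), n_restarts (20),
    floor (1e-3), lowpass_hz, target_rate_hz, seed (0).

    When ground-truth sequences are supplied, cluster labels are aligned to
    them (optimal one-to-one matching) and the agreement fraction recorded.
    """
    wd = float(params.get("window_duration_s", 10.0))
    band = tuple(params.get("band_hz", (0.5, 120.0)))
    n_comp = int(params.get("n_components", 3))
    k = int(params.get("k", 8))
    n_restarts = int(params.get("n_restarts", 20))
    floor = float(params.get("floor", markov.REPORT_FLOOR))
    seed = int(params.get("seed", 0))

    specs = []
    for trace in traces:
        x = _preprocess(trace, params)
        # clamp the default feature band to the trace's Nyquist frequency
        band_t = (band[0], min(band[1], x.sampling_rate_hz / 2.0))
        specs.append(spectral.compute_spectrogram(x, wd, band_t))
    # normalization is per subject across all its conditions, so that state
    # signatures survive in segments that dwell in a single state throughout
    dbs: list[DbDeviationSpectrogram] = spectral.db_deviation_cohort(specs)
    F = states.assemble_feature_matrix(dbs, band)
    scores, evr = states.pca_project(F, n_comp)
    labeling = states.kmeans_cluster(scores, k=k, n_restarts=n_restarts, seed=seed)

    labels = labeling.labels
    agreement = None
    mapping = None
    if truths is not None:
        truth_by_cell = {(t.subject_id, t.condition): t for t in truths}
        truth_rows = np.concatenate(
            [
                truth_by_cell[key].labels[: _cell_len(F.index, key)]
                for key in _cell_order(F.index)
            ]
        )
        mapping, agreement = states.align_labels(labels, truth_rows)
        labels = np.array([mapping.get(int(l), int(l)) for l in labels])

    # split pooled labels back into per-cell sequences (sequence boundaries
    # are subject x condition cells; transitions are never counted across them)
    sequences: list[StateSequence] = []
    frame = F.index.to_frame(index=False)
    for (subj, cond), grp in frame.groupby(["subject_id", "condition"], sort=True):
        sequences.append(
            StateSequence(labels[grp.index.to_numpy()], wd, str(subj), str(cond))
        )

    _, pooled = markov.estimate_transition_matrix(sequences, k)
    pooled_report = markov.apply_report_floor(pooled, floor)

    by_subject: dict[str, list[StateSequence]] = {}
    for s in sequences:
        by_subject.setdefault(s.subject_id, []).append(s)
    jk = None
    if len(by_subject) >= 2:
        jk = markov.jackknife_bounds(by_subject, k, floor=floor)
    else:
        log.warning("jackknife skipped: only %d subject(s)", len(by_subject))

    by_condition: dict[str, list[StateSequence]] = {}
    for s in sequences:
        by_condition.setdefault(s.condition, []).append(s)
    per_cond = markov.per_concentration_matrices(by_condition, k, floor)

    dwells = markov.extract_dwells(sequences)
    fits: dict[int, markov.DwellFit] = {}
    for sid in sorted({d.state for d in dwells}):
        state_dwells = [d for d in dwells if d.state == sid]
        try:
            fits[sid] = markov.dwell_distribution_fit(state_dwells, wd)
        except InsufficientDataError:
            log.info("dwell fit skipped for state %d: too few dwells", sid)

    return AnalysisResult(
        feature_index=F.index,
        scores=scores,
        explained_variance=evr,
        labeling=labeling,
        label_sequences=sequences,
        pooled_transition=pooled,
        pooled_report=pooled_report,
        jackknife=jk,
        per_condition=per_cond,
        dwells=dwells,
        dwell_fits=fits,
        stickiness=markov.stickiness_ratio(pooled),
        window_duration_s=wd,
        agreement=agreement,
        label_mapping=mapping,
        db_spectrograms=dbs,
    )


def _cell_order(index: pd.MultiIndex):
    seen = []
    for subj, cond, _ in index:
        if (subj, cond) not in seen:
            seen.append((subj, cond))
    return seen


def _cell_len(index: pd.MultiIndex, key) -> int:
    frame = index.to_frame(index=False)
    return int(((frame["subject_id"] == key[0]) & (frame["condition"] == key[1])).sum())


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> RunManifest:
    """Simulate (per config) and analyze, writing all artifacts + manifest."""
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg, params = lio.load_config(config_path)

    stages: list[dict] = []
    outputs: list[Path] = []

    t0 = time.perf_counter()
    members = simulate_cohort(cohort_cfg)
    stages.append(
        {"stage": "simulate", "seconds": time.perf_counter() - t0, "rows": len(members)}
    )
    log.info("simulated %d cohort cells", len(members))

    cohort_dir = out_dir / "cohort"
    t0 = time.perf_counter()
    outputs += lio.write_cohort(members, cohort_dir)
    stages.append(
        {"stage": "write_cohort", "seconds": time.perf_counter() - t0, "rows": len(members)}
    )

    traces = [m.trace for m in members]
    truths = [m.truth for m in members]
    t0 = time.perf_counter()
    result = analyze_cohort(traces, params, truths=truths)
    stages.append(
        {
            "stage": "analyze",
            "seconds": time.perf_counter() - t0,
            "rows": int(result.feature_index.size),
        }
    )
    log.info(
        "analysis done: %d windows, agreement=%s, stickiness=%.3g",
        result.feature_index.size,
        f"{result.agreement:.3f}" if result.agreement is not None else "n/a",
        result.stickiness,
    )

    outputs += _write_results(result, out_dir)

    manifest = RunManifest(
        config_snapshot={"cohort_seed": cohort_cfg.seed, "analysis": params},
        seeds={"master": cohort_cfg.seed, "kmeans": params.get("seed", cohort_cfg.seed)},
        input_digests={str(config_path): _digest(config_path)},
        outputs=[str(p) for p in outputs],
        stages=stages,
    )
    mpath = manifest.write(out_dir / "manifest.json")
    log.info("manifest written to %s", mpath)
    return manifest


def _write_results(result: AnalysisResult, out_dir: Path) -> list[Path]:
    outputs: list[Path] = []
    kstates = tuple(range(result.labeling.k))
    labels = np.concatenate([s.labels for s in result.label_sequences])
    outputs.append(
        lio.write_labels_csv(
            result.feature_index, labels, result.window_duration_s, out_dir / "labels.csv"
        )
    )
    outputs += lio.write_report_matrix(
        result.pooled_report, kstates, out_dir / "transition_pooled"
    )
    if result.jackknife is not None:
        lo, hi = result.jackknife
        outputs += lio.write_report_matrix(lo, kstates, out_dir / "transition_lower95")
        outputs += lio.write_report_matrix(hi, kstates, out_dir / "transition_upper95")
    for cond, R in result.per_condition.items():
        outputs += lio.write_report_matrix(
            R, kstates, out_dir / f"transition_{cond}"
        )
    outputs.append(lio.write_dwells_csv(result.dwells, out_dir / "dwells.csv"))

    summary = {
        "stickiness_ratio": result.stickiness,
        "mean_uncensored_dwell_s": result.mean_dwell_s(),
        "agreement": result.agreement,
        "explained_variance": list(map(float, result.explained_variance)),
        "dwell_fits": {
            str(sid): {
                "mean_dwell_s": f.mean_dwell_s,
                "rate_per_s": f.rate_per_s,
                "preferred": f.preferred,
                "loglik_exponential": f.loglik_exponential,
                "loglik_powerlaw": f.loglik_powerlaw,
                "powerlaw_exponent": f.powerlaw_exponent,
            }
            for sid, f in result.dwell_fits.items()
        },
    }
    spath = out_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2) + "\n")
    outputs.append(spath)
    return outputs
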