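"""Persistence: HDF5 traces and spectrograms, CSV exports, YAML configuration.

File conventions
----------------
* One HDF5 file per subject x condition cell, with dataset ``lfp`` (float)
  and attributes ``sampling_rate_hz``, ``subject_id``, ``condition``; the
  ground-truth labels (when known) live in a sidecar CSV with columns
  ``window_index,start_time_s,state_id``.
* Spectrograms are HDF5 with datasets ``power``/``times_s``/``freqs_hz``
  plus the same attributes.
* Matrices are CSV with a header row/column of state ids; a log10 variant is
  written for display. Labels, dwells and spectra are plain CSV.
* Cohort/analysis configuration is a nested YAML document; the schema is
  documented in the README.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError
from .synthgen import (
    CohortConfig,
    CohortMember,
    ConditionSpec,
    build_transition_matrix,
)
from .types import (
    DwellRecord,
    ReportMatrix,
    SignalTrace,
    SpectralPeak,
    SpectralStateModel,
    Spectrogram,
    StateSequence,
    TransitionMatrix,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_spectrogram",
    "read_spectrogram",
    "write_matrix_csv",
    "write_report_matrix",
    "write_labels_csv",
    "write_dwells_csv",
    "write_spectrum_csv",
    "load_config",
    "parse_config",
]

FLOAT_FMT = "%.12g"


def _cell_stem(subject_id: str, condition: str) -> str:
    return f"{subject_id}__{condition}"


def write_cohort(members: list[CohortMember], out_dir: str | Path) -> list[Path]:
    """Write each cohort cell as HDF5 trace + ground-truth CSV; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for m in members:
        stem = _cell_stem(m.trace.subject_id, m.trace.condition)
        h5path = out_dir / f"{stem}.h5"
        with h5py.File(h5path, "w") as f:
            d = f.create_dataset("lfp", data=m.trace.samples)
            d.attrs["sampling_rate_hz"] = m.trace.sampling_rate_hz
            d.attrs["subject_id"] = m.trace.subject_id
            d.attrs["condition"] = m.trace.condition
        truth_path = out_dir / f"{stem}.truth.csv"
        wd = m.truth.window_duration_s
        df = pd.DataFrame(
            {
                "window_index": np.arange(m.truth.n_windows),
                "start_time_s": np.arange(m.truth.n_windows) * wd,
                "state_id": m.truth.labels,
            }
        )
        df.to_csv(truth_path, index=False)
        written.extend([h5path, truth_path])
    return written


def read_cohort(
    in_dir: str | Path, window_duration_s: float = 10.0
) -> list[tuple[SignalTrace, StateSequence | None]]:
    """Read all HDF5 traces in a directory, with ground truth when present."""
    in_dir = Path(in_dir)
    pairs = []
    for h5path in sorted(in_dir.glob("*.h5")):
        with h5py.File(h5path, "r") as f:
            d = f["lfp"]
            trace = SignalTrace(
                d[...],
                float(d.attrs["sampling_rate_hz"]),
                str(d.attrs.get("subject_id", "")),
                str(d.attrs.get("condition", "")),
            )
        truth = None
        truth_path = h5path.parent / (h5path.stem + ".truth.csv")
        if truth_path.exists():
            df = pd.read_csv(truth_path)
            wd = window_duration_s
            if len(df) > 1:
                wd = float(df["start_time_s"].iloc[1] - df["start_time_s"].iloc[0])
            truth = StateSequence(
                df["state_id"].to_numpy(), wd, trace.subject_id, trace.condition
            )
        pairs.append((trace, truth))
    return pairs


def write_spectrogram(S: Spectrogram, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=S.power)
        f.create_dataset("times_s", data=S.times_s)
        f.create_dataset("freqs_hz", data=S.freqs_hz)
        f.attrs["window_duration_s"] = S.window_duration_s
        f.attrs["subject_id"] = S.subject_id
        f.attrs["condition"] = S.condition
    return path


def read_spectrogram(path: str | Path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        return Spectrogram(
            f["power"][...],
            f["times_s"][...],
            f["freqs_hz"][...],
            float(f.attrs["window_duration_s"]),
            str(f.attrs.get("subject_id", "")),
            str(f.attrs.get("condition", "")),
        )


def write_matrix_csv(
    M: np.ndarray, states: list[int] | tuple[int, ...], path: str | Path
) -> Path:
    """k x k matrix as CSV with state ids as header row and column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(M), index=list(states), columns=list(states))
    df.index.name = "state"
    df.to_csv(path, float_format=FLOAT_FMT)
    return path


def write_report_matrix(
    R: ReportMatrix, states: tuple[int, ...], stem: str | Path
) -> list[Path]:
    """Report matrix plus its log10 display variant."""
    stem = Path(stem)
    p1 = write_matrix_csv(R.P_report, states, stem.with_suffix(".csv"))
    p2 = write_matrix_csv(
        np.log10(R.P_report), states, stem.parent / (stem.name + ".log10.csv")
    )
    return [p1, p2]


def write_labels_csv(
    index: pd.MultiIndex, labels: np.ndarray, window_duration_s: float, path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = index.to_frame(index=False)
    df["start_time_s"] = df["window_index"] * window_duration_s
    df["cluster"] = labels
    df = df[["subject_id", "condition", "window_index", "start_time_s", "cluster"]]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def write_dwells_csv(dwells: list[DwellRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in dwells],
            "condition": [d.condition for d in dwells],
            "state": [d.state for d in dwells],
            "duration_s": [d.duration_s for d in dwells],
            "censored": [d.censored for d in dwells],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def write_spectrum_csv(
    freqs_hz: np.ndarray, values: np.ndarray, path: str | Path, value_name: str = "value"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"freq_hz": freqs_hz, value_name: values}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    return path


# ---------------------------------------------------------------------------
# configuration


def parse_config(doc: dict) -> tuple[CohortConfig, dict]:
    """Build a CohortConfig and analysis-parameter dict from a parsed YAML doc.

    See the README for the schema. Raises InvalidConfigError naming the
    offending key on any inconsistency.
    """
    if "cohort" not in doc:
        raise InvalidConfigError("missing section", key="cohort")
    c = doc["cohort"]
    try:
        states = []
        for s in c["states"]:
            peaks = tuple(
                SpectralPeak(p["center_hz"], p["bandwidth_hz"], p["relative_power"])
                for p in s["peaks"]
            )
            states.append(
                SpectralStateModel(
                    state_id=int(s["state_id"]),
                    peaks=peaks,
                    background_exponent=float(s.get("background_exponent", 1.0)),
                    background_power=float(s.get("background_power", 1.0)),
                )
            )
    except KeyError as e:
        raise InvalidConfigError("malformed state model", key=f"cohort.states.{e}") from e

    wd = float(c.get("window_duration_s", 10.0))
    state_ids = tuple(m.state_id for m in states)
    if "transition" in c:
        P = np.asarray(c["transition"], dtype=float)
        base = TransitionMatrix(state_ids, P, wd)
    else:
        base = build_transition_matrix(
            len(states), float(c.get("mean_dwell_windows", 60.0)), wd, states=state_ids
        )

    conditions = []
    for cond in c.get("conditions", [{"label": "default"}]):
        conditions.append(
            ConditionSpec(
                label=str(cond["label"]),
                dwell_multiplier=float(cond.get("dwell_multiplier", 1.0)),
                available_states=tuple(cond.get("available_states", ())),
                duration_s=float(cond.get("duration_s", 3600.0)),
            )
        )

    cohort = CohortConfig(
        n_subjects=int(c.get("n_subjects", 5)),
        conditions=tuple(conditions),
        base_transition=base,
        state_models=tuple(states),
        sampling_rate_hz=float(c.get("sampling_rate_hz", 1000.0)),
        noise_sd=float(c.get("noise_sd", 0.1)),
        seed=int(c.get("seed", 0)),
    )

    a = doc.get("analysis", {})
    analysis = {
        "window_duration_s": float(a.get("window_duration_s", wd)),
        "band_hz": tuple(a.get("band_hz", (0.5, 120.0))),
        "n_components": int(a.get("n_components", 3)),
        "k": int(a.get("k", 8)),
        "n_restarts": int(a.get("n_restarts", 20)),
        "floor": float(a.get("floor", 1e-3)),
        "lowpass_hz": a.get("lowpass_hz"),
        "target_rate_hz": a.get("target_rate_hz"),
        "seed": int(a.get("seed", cohort.seed)),
    }
    if analysis["band_hz"][0] >= analysis["band_hz"][1]:
        raise InvalidConfigError("band must be (low, high)", key="analysis.band_hz")
    return cohort, analysis


def load_config(path: str | Path) -> tuple[CohortConfig, dict]:
    with open(path) as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict):
        raise InvalidConfigError("config must be a mapping", key="<root>")
    return parse_config(doc)
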