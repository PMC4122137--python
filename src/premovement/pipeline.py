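"""End-to-end premovement decoding runs: ingest -> preprocess -> select -> classify.

The pipeline mirrors the study protocol: electrode/band selection (and its
bootstrap validation) uses the *first session only*; the selected bands are
frozen and re-evaluated verbatim on every later session; when both prefrontal
and motor-area features exist, the motor+prefrontal vs motor-only comparison
is run on matched folds. All seeds are recorded in the report, and a rerun
with the same config yields a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .features import (
    ComparisonResult,
    CVResult,
    build_features,
    compare_feature_sets,
    crossval_svm,
    session_transfer,
)
from .preprocess import (
    EpochSet,
    EventOnsets,
    Recording,
    downsample_to_200,
    emg_onset_preonset_ratio,
    epoch_trials,
    exclude_channels,
    reject_artifact_trials,
)
from .spectral import (
    BootstrapResult,
    SelectedBand,
    bootstrap_selection_null,
    canonical_band_overlap,
    compute_contrast,
    select_bands,
    CANONICAL_BANDS,
)
from .synthetic import EMG_LABEL, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

MOTOR_AREAS = ("premotor_sma", "sensorimotor")


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    The defaults are the analysis parameters of the emulated protocol:
    3 dB / 4 Hz selection criterion over 1-80 Hz on the -2..0 s window at
    200 Hz, a 500-iteration bootstrap null, and fivefold cross-validation.
    """

    synthetic: SyntheticConfig | None = None
    edf_paths: list[str] = field(default_factory=list)
    events_path: str | None = None
    area_map_path: str | None = None
    bad_channels: list[str] = field(default_factory=list)
    db_threshold: float = 3.0
    width_hz: float = 4.0
    selection_mode: str = "strict"
    bootstrap_iters: int = 500
    cv_folds: int = 5
    reject_k: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and not self.edf_paths:
            raise ValueError("config needs either a synthetic block or EDF paths")


@dataclass
class RunReport:
    """Serializable record of one pipeline run; every number comes from an
    operation output and the report round-trips losslessly through JSON."""

    status: str
    config: dict
    qc: list[dict]
    selections: list[dict]
    taxonomy: dict
    bootstrap: dict | None
    sessions: list[dict]
    comparison: dict | None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "config": self.config,
            "qc": self.qc,
            "selections": self.selections,
            "taxonomy": self.taxonomy,
            "bootstrap": self.bootstrap,
            "sessions": self.sessions,
            "comparison": self.comparison,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        pio.write_selections_csv(
            [_band_from_dict(d) for d in self.selections], out / "selections.csv"
        )
        import pandas as pd

        pd.DataFrame(self.sessions).to_csv(out / "accuracies.csv", index=False)
        return out / "report.json"


def _band_to_dict(b: SelectedBand) -> dict:
    return {
        "channel": b.channel,
        "area": b.area,
        "f_lo_hz": b.f_lo,
        "f_hi_hz": b.f_hi,
        "peak_diff_db": b.peak_diff_db,
        "favored_class": b.favored_class,
        "canonical_bands": sorted(canonical_band_overlap(b)),
    }


def _band_from_dict(d: dict) -> SelectedBand:
    return SelectedBand(
        channel=d["channel"],
        area=d["area"],
        f_lo=d["f_lo_hz"],
        f_hi=d["f_hi_hz"],
        peak_diff_db=d["peak_diff_db"],
        favored_class=d["favored_class"],
    )


def _cv_to_dict(cv: CVResult) -> dict:
    return {
        "session_id": cv.session_id,
        "n_trials": cv.n_trials,
        "fold_accuracies": [float(a) for a in cv.fold_accuracies],
        "mean_accuracy": cv.mean_accuracy,
        "mean_accuracy_pct": round(100.0 * cv.mean_accuracy, 1),
        "chance_level": cv.chance_level,
        "exceeds_chance": cv.exceeds_chance,
    }


def band_taxonomy_summary(bands: list[SelectedBand]) -> dict:
    """Counts of selected bands per canonical band and electrodes per area."""
    band_counts = {name: 0 for name in CANONICAL_BANDS}
    for b in bands:
        for name in canonical_band_overlap(b):
            band_counts[name] += 1
    area_channels: dict[str, set[str]] = {}
    for b in bands:
        area_channels.setdefault(b.area, set()).add(b.channel)
    return {
        "bands": band_counts,
        "areas": {a: len(chs) for a, chs in sorted(area_channels.items())},
        "n_bands": len(bands),
        "n_electrodes": len({b.channel for b in bands}),
    }


# ---------------------------------------------------------------------------
# Session ingest and preprocessing
# ---------------------------------------------------------------------------

def _load_sessions(config: RunConfig) -> tuple[list[Recording], list[EventOnsets]]:
    if config.synthetic is not None:
        ds = generate_dataset(config.synthetic)
        recs = ds.recordings
        events = [EventOnsets(onsets=list(ev)) for ev in ds.events]
        return recs, events
    area_map = (
        pio.read_area_map_csv(config.area_map_path) if config.area_map_path else {}
    )
    recs, events = [], []
    for p in config.edf_paths:
        rec = pio.read_edf(p, area_of_channel=area_map)
        recs.append(rec)
        events.append(pio.read_events_csv(config.events_path, session=rec.session_id))
    return recs, events


def preprocess_session(
    rec: Recording,
    events: EventOnsets,
    bad_channels: list[str] | None = None,
    reject_k: float = 8.0,
) -> tuple[EpochSet, dict]:
    """Downsample, separate EMG, epoch, reject artifacts; returns epochs + QC dict."""
    rec200 = downsample_to_200(rec)
    if bad_channels:
        rec200 = exclude_channels(rec200, bad_channels)
    emg_labels = [
        c for c in rec200.channel_labels
        if c == EMG_LABEL or rec200.area_of_channel.get(c) == "emg"
    ]
    qc: dict = {"session_id": rec.session_id}
    if emg_labels:
        emg = rec200.signal[rec200.channel_index(emg_labels[0])]
        ratio = emg_onset_preonset_ratio(emg, rec200.fs, events.times)
        qc["emg_ratio_mean_db"] = ratio.mean_db
        qc["emg_ratio_sd_db"] = ratio.sd_db
        rec200 = exclude_channels(rec200, emg_labels)
    es = epoch_trials(rec200, events)
    n_valid = int(es.kept_mask.sum())
    es = reject_artifact_trials(es, k=reject_k)
    qc["n_trials"] = es.n_trials
    qc["n_valid"] = n_valid
    qc["n_rejected"] = n_valid - int(es.kept_mask.sum())
    qc["n_kept"] = int(es.kept_mask.sum())
    return es, qc


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and assemble a report.

    Selection and its bootstrap null use session 1 only; classification runs
    on all sessions with the frozen bands. When no band passes the criterion
    the report carries status ``"no_features"`` with empty classification.
    """
    recordings, events = _load_sessions(config)
    epoch_sets, qc = [], []
    for rec, ev in zip(recordings, events):
        es, q = preprocess_session(rec, ev, config.bad_channels, config.reject_k)
        epoch_sets.append(es)
        qc.append(q)

    # --- selection on session 1 only
    es1 = epoch_sets[0]
    contrast = compute_contrast(es1)
    bands = select_bands(
        contrast,
        threshold_db=config.db_threshold,
        min_width_hz=config.width_hz,
        mode=config.selection_mode,
    )
    observed = len({b.channel for b in bands})
    logger.info("session 1 selection: %d bands on %d electrodes", len(bands), observed)

    # --- bootstrap null on session 1 (ECoG channels only, EMG already dropped)
    rec1 = downsample_to_200(recordings[0])
    emg_labels = [
        c for c in rec1.channel_labels
        if c == EMG_LABEL or rec1.area_of_channel.get(c) == "emg"
    ]
    drop = list(dict.fromkeys(emg_labels + list(config.bad_channels)))
    if drop:
        rec1 = exclude_channels(rec1, drop)
    counts1 = es1.kept_counts()
    class_sizes = tuple(counts1[c] for c in sorted(counts1))[:2]
    boot = bootstrap_selection_null(
        rec1,
        n_trials_per_class=class_sizes,
        observed_count=observed,
        n_iter=config.bootstrap_iters,
        seed=config.seed,
        threshold_db=config.db_threshold,
        min_width_hz=config.width_hz,
        mode=config.selection_mode,
    )

    taxonomy = band_taxonomy_summary(bands)

    # --- classification: session 1, then frozen-band transfer to later sessions
    sessions_out: list[dict] = []
    comparison_out: dict | None = None
    status = "ok"
    if not bands:
        status = "no_features"
    else:
        cv1 = crossval_svm(build_features(es1, bands), k=config.cv_folds, seed=config.seed)
        results = [cv1] + session_transfer(
            epoch_sets[1:], bands, k=config.cv_folds, seed=config.seed
        )
        sessions_out = [_cv_to_dict(cv) for cv in results]

        # --- motor+prefrontal vs motor-only comparison on matched folds
        motor_cols = [j for j, b in enumerate(bands) if b.area in MOTOR_AREAS]
        prefrontal_cols = [j for j, b in enumerate(bands) if b.area == "prefrontal"]
        if motor_cols and prefrontal_cols and len(epoch_sets) >= 2:
            fm_full = [build_features(es, bands) for es in epoch_sets]
            fm_motor = [fm.subset(motor_cols) for fm in fm_full]
            cmp_res = compare_feature_sets(
                fm_full, fm_motor, k=config.cv_folds, seed=config.seed
            )
            comparison_out = _comparison_to_dict(cmp_res)

    cfg_out = {
        "seed": config.seed,
        "db_threshold": config.db_threshold,
        "width_hz": config.width_hz,
        "selection_mode": config.selection_mode,
        "bootstrap_iters": config.bootstrap_iters,
        "cv_folds": config.cv_folds,
        "reject_k": config.reject_k,
        "source": "synthetic" if config.synthetic is not None else "edf",
    }
    return RunReport(
        status=status,
        config=cfg_out,
        qc=qc,
        selections=[_band_to_dict(b) for b in bands],
        taxonomy=taxonomy,
        bootstrap=_bootstrap_to_dict(boot),
        sessions=sessions_out,
        comparison=comparison_out,
    )


def _bootstrap_to_dict(boot: BootstrapResult) -> dict:
    return {
        "n_iterations": boot.n_iterations,
        "observed_count": boot.observed_count,
        "p_value": boot.p_value,
        "null_counts": [int(c) for c in boot.null_counts],
        "null_count_max": int(np.max(boot.null_counts)) if boot.n_iterations else 0,
    }


def _comparison_to_dict(cmp_res: ComparisonResult) -> dict:
    return {
        "session_ids": cmp_res.session_ids,
        "case1_accuracies": [float(a) for a in cmp_res.case1_accuracies],
        "case2_accuracies": [float(a) for a in cmp_res.case2_accuracies],
        "mean_case1": cmp_res.mean_case1,
        "mean_case2": cmp_res.mean_case2,
        "mean_case1_pct": round(100.0 * cmp_res.mean_case1, 1),
        "mean_case2_pct": round(100.0 * cmp_res.mean_case2, 1),
        "paired_t_p": cmp_res.paired_t_p,
    }
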