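"""End-to-end pipeline orchestration and plain-text outputs.

A :class:`RunConfig` (typically loaded from YAML) names the input (synthetic
generator settings or dataset directories) and the analyses to run; the
pipeline executes the stages in dependency order, writes diff-able TSV
outputs plus a machine-readable JSON summary, and is byte-identical across
reruns with the same configuration (all randomness is seeded).
"""

from __future__ import annotations

import contextlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decode, flow, selectivity, timestats
from .dataset import EpochedDataset, read_epochs, write_epochs
from .design import VARIATION_TYPES, generate_design
from .model_layers import (
    layer_profile,
    layer_sliding_correlation,
    mean_variation_profile,
    synthetic_layer_cascade,
)
from .synth import EffectSpec, SynthConfig, generate_group

logger = logging.getLogger(__name__)

KNOWN_ANALYSES = ("decode", "stats", "selectivity", "flow", "layers")


@dataclass
class RunConfig:
    analyses: tuple[str, ...] = ("decode", "stats")
    synth: dict = field(default_factory=dict)      # SynthConfig fields (effects as dicts)
    data_dirs: tuple[str, ...] = ()                # load instead of simulate when set
    dimensions: tuple[str, ...] = ("category",)    # decoding dimensions
    scheme: str = "pooled"
    electrodes: str | None = None
    alpha: float = 0.05
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    selectivity_times: tuple[float, ...] = (-100.0, 50.0, 104.0, 200.0)
    flow_front: str = "peri_frontal"
    flow_back: str = "peri_occipital"
    n_perm: int = 1000
    layer_category_separation: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
    layer_variation_separation: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 1.5, 1.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [a for a in self.analyses if a not in KNOWN_ANALYSES]
        if unknown:
            raise ValueError(f"unknown analyses {unknown}; known: {KNOWN_ANALYSES}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})


def build_synth_config(raw: dict) -> SynthConfig:
    raw = dict(raw)
    effects = tuple(EffectSpec(**e) for e in raw.pop("effects", ()))
    if "epoch_window" in raw:
        raw["epoch_window"] = tuple(raw["epoch_window"])
    if "channel_names" in raw:
        raw["channel_names"] = tuple(raw["channel_names"])
    return SynthConfig(effects=effects, **raw)


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.10g}" if isinstance(x, (float, np.floating)) else str(x)


def write_curve_tsv(curve: decode.DecodabilityCurve, path) -> None:
    rows = ["time_ms\tvalue\tsem\tn_subjects\tcontrast\tscheme\telectrode_set"]
    eset = ",".join(curve.electrode_set)
    for t, v, s in zip(curve.time_ms, curve.mean, curve.sem):
        rows.append("\t".join([_fmt(t), _fmt(v), _fmt(s), str(curve.n_subjects),
                               curve.contrast, curve.scheme, eset]))
    Path(path).write_text("\n".join(rows) + "\n")


def write_trace_tsv(curve: decode.DecodabilityCurve, trace: timestats.SignificanceTrace,
                    path) -> None:
    rows = ["time_ms\tstat\tp\tq\tsignificant"]
    for j, t in enumerate(trace.time_ms):
        rows.append("\t".join([_fmt(t), _fmt(curve.mean[j]), _fmt(trace.p_values[j]),
                               _fmt(trace.q_values[j]), _fmt(bool(trace.significant[j]))]))
    Path(path).write_text("\n".join(rows) + "\n")


def write_flow_tsv(result: flow.FlowResult, path) -> None:
    rows = ["time_ms\tff\tfb\tdiff\tff_thresh\tfb_thresh\tsig_ff\tsig_fb"]
    for j, t in enumerate(result.time_ms):
        rows.append("\t".join([
            _fmt(t), _fmt(result.ff[j]), _fmt(result.fb[j]), _fmt(result.diff[j]),
            _fmt(result.ff_threshold[j]), _fmt(result.fb_threshold[j]),
            _fmt(bool(result.significant_ff[j])), _fmt(bool(result.significant_fb[j])),
        ]))
    Path(path).write_text("\n".join(rows) + "\n")


def write_matrix_tsv(matrix: selectivity.SelectivityMatrix, path) -> None:
    names = [f"{d}:{c}" for d, c in matrix.aspects]
    rows = ["aspect\t" + "\t".join(names)]
    for i, name in enumerate(names):
        rows.append(name + "\t" + "\t".join(_fmt(v) for v in matrix.corr[i]))
    Path(path).write_text("\n".join(rows) + "\n")


def flow_stages(result: flow.FlowResult) -> list[dict]:
    """Maximal runs of bins with one-signed significant FF-FB dominance."""
    pos = ~np.isnan(result.diff_upper) & (result.diff > result.diff_upper)
    neg = ~np.isnan(result.diff_lower) & (result.diff < result.diff_lower)
    state = np.where(pos, 1, np.where(neg, -1, 0))
    stages = []
    j, n = 0, state.size
    while j < n:
        if state[j] == 0:
            j += 1
            continue
        k = j
        while k + 1 < n and state[k + 1] == state[j]:
            k += 1
        stages.append({
            "direction": "feedforward" if state[j] > 0 else "feedback",
            "start_ms": float(result.time_ms[j]),
            "end_ms": float(result.time_ms[k]),
        })
        j = k + 1
    return stages


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage."""


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Run the configured stages; returns (and writes) the summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(cfg).items()},
                    "stages": {}}

    with _stage("input"):
        if cfg.data_dirs:
            datasets = [read_epochs(d) for d in cfg.data_dirs]
        else:
            synth_cfg = build_synth_config({"seed": cfg.seed, **cfg.synth})
            logger.info("simulating %d subjects (seed %d)", synth_cfg.n_subjects, synth_cfg.seed)
            datasets = generate_group(synth_cfg)

    group_curves: dict[str, decode.DecodabilityCurve] = {}
    with _stage("decode"):
        for dim in cfg.dimensions:
            raw = decode.group_dimension_curve(
                datasets, dim, cfg.scheme, cfg.electrodes, baseline=False)
            group_curves[dim] = raw

    if "decode" in cfg.analyses:
        for dim, raw in group_curves.items():
            corrected = decode.baseline_correct(raw, cfg.baseline_window)
            write_curve_tsv(corrected, out / f"decode_{dim}_{cfg.scheme}.tsv")
        report["stages"]["decode"] = {
            "dimensions": list(cfg.dimensions), "scheme": cfg.scheme,
            "files": [f"decode_{d}_{cfg.scheme}.tsv" for d in cfg.dimensions],
        }

    if "stats" in cfg.analyses:
        with _stage("stats"):
            stats_report = {}
            for dim, raw in group_curves.items():
                trace = timestats.signed_rank_vs_baseline(
                    raw, cfg.baseline_window, cfg.alpha)
                corrected = decode.baseline_correct(raw, cfg.baseline_window)
                lp = timestats.latency_peak(corrected, trace)
                write_trace_tsv(corrected, trace, out / f"stats_{dim}_{cfg.scheme}.tsv")
                stats_report[dim] = {
                    "latency_ms": lp.latency_ms, "peak_ms": lp.peak_ms,
                    "peak_value": lp.peak_value,
                }
            report["stages"]["stats"] = stats_report

    if "selectivity" in cfg.analyses:
        with _stage("selectivity"):
            trace = selectivity.selectivity_index_trace(datasets)
            idx_at = {}
            for t in cfg.selectivity_times:
                vecs = selectivity.aspect_vectors(datasets[0], t)
                mat = selectivity.selectivity_matrix(vecs, t)
                write_matrix_tsv(mat, out / f"selectivity_matrix_{int(t)}ms.tsv")
                idx_at[str(t)] = selectivity.selectivity_index(mat)
            rows = ["time_ms\tindex_mean\tindex_sem"]
            for j, t in enumerate(trace.time_ms):
                rows.append(f"{_fmt(t)}\t{_fmt(trace.mean[j])}\t{_fmt(trace.sem[j])}")
            (out / "selectivity_index.tsv").write_text("\n".join(rows) + "\n")
            report["stages"]["selectivity"] = {"index_at_times_subject1": idx_at}

    if "flow" in cfg.analyses:
        with _stage("flow"):
            result = flow.flow_curves(
                datasets, front=cfg.flow_front, back=cfg.flow_back,
                n_perm=cfg.n_perm, seed=cfg.seed)
            write_flow_tsv(result, out / "flow_category.tsv")
            report["stages"]["flow"] = {"stage_boundaries": flow_stages(result)}

    if "layers" in cfg.analyses:
        with _stage("layers"):
            layers = synthetic_layer_cascade(
                cfg.layer_category_separation, cfg.layer_variation_separation, seed=cfg.seed)
            cat = layer_profile(layers, "category")
            var = mean_variation_profile(layers)
            corr3 = layer_sliding_correlation(cat, var)
            rows = ["layer\tcategory_dprime\tvariation_dprime"]
            for k in range(len(layers)):
                rows.append(f"{k + 1}\t{_fmt(cat[k])}\t{_fmt(var[k])}")
            (out / "layers.tsv").write_text("\n".join(rows) + "\n")
            report["stages"]["layers"] = {
                "category_profile": [float(v) for v in cat],
                "variation_profile": [float(v) for v in var],
                "sliding_corr_3layer": [None if np.isnan(v) else float(v) for v in corr3],
            }

    (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
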