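"""Run configuration, pipeline orchestration and report rendering."""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import conductance as cond
from . import event_detection as det
from . import pathways_profiles as paths
from . import permeation_stats as pstats
from . import synthetic_data as synth
from .core_model import TrajectoryBundle, load_ion_traces, write_ion_traces
from .event_detection import BT, TB, CrossingEvent, EventLedger

__all__ = [
    "RunConfig",
    "run_pipeline",
    "render_table1",
    "segment_ledger",
    "write_events",
    "read_events",
]

_DIR_LABEL = {TB: "TB", BT: "BT"}
_DIR_FROM_LABEL = {"TB": TB, "BT": BT}


@dataclass
class RunConfig:
    """Every pipeline knob, mergeable from a config file and CLI overrides."""

    mode: str = "simulate"  # simulate | ingest | counts
    out_dir: str = "permkit_out"
    seed: int = 0
    duration: float = 200.0  # ns, simulate mode
    segment_ns: float | None = 200.0
    traces: str | None = None  # ingest mode input
    ve: float | None = None  # mV override
    model: str = "double-poisson"  # poisson | double-poisson
    method: str = "mle"  # mle | lsq
    direction: str = "TB"
    lookback_ns: float = 5.0
    min_waiting_times: int = 10

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Event-ledger TSV format: segment, ion_id, species, direction, t_start,
# t_end, pathway (tab-separated, '#' comments, one header line).


def write_events(ledger: EventLedger, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# permkit-events v1 dt_ns={ledger.dt:.6f}\n")
        fh.write("segment\tion_id\tspecies\tdirection\tt_start\tt_end\tpathway\n")
        for ev in ledger.events:
            fh.write(
                f"{ev.segment}\t{ev.ion_id}\t{ev.species}\t{_DIR_LABEL[ev.direction]}\t"
                f"{ev.t_start:.6f}\t{ev.t_end:.6f}\t{ev.pathway}\n"
            )


def read_events(path) -> EventLedger:
    events = []
    dt = 200.0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("segment\t"):
                continue
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("dt_ns="):
                        dt = float(tok.split("=", 1)[1])
                continue
            seg, ion_id, species, direction, t0, t1, pathway = line.split("\t")
            events.append(
                CrossingEvent(
                    ion_id=ion_id,
                    species=species,
                    direction=_DIR_FROM_LABEL[direction],
                    t_start=float(t0),
                    t_end=float(t1),
                    pathway=pathway,
                    segment=seg,
                )
            )
    return EventLedger(events=events, dt=dt)


def segment_ledger(ledger: EventLedger, segment_ns: float) -> list[EventLedger]:
    """Split a ledger into fixed-length analysis windows.

    An event belongs to the window containing its start time. Windows are
    labelled "<seg>.1", "<seg>.2", ... after the parent segment.
    """
    if segment_ns <= 0:
        raise ValueError("segment_ns must be positive")
    n_seg = max(int(np.ceil(ledger.dt / segment_ns - 1e-9)), 1)
    if n_seg == 1:
        return [ledger]
    out = []
    for i in range(n_seg):
        lo, hi = i * segment_ns, (i + 1) * segment_ns
        label = f"{ledger.segment}.{i + 1}"
        evs = [
            dataclasses.replace(ev, segment=label)
            for ev in ledger.events
            if lo <= ev.t_start < hi
        ]
        out.append(EventLedger(events=evs, dt=min(segment_ns, ledger.dt - lo), segment=label))
    return out


# ---------------------------------------------------------------------------
# Rendering


def render_table1(summaries, aggregate_row: bool = True) -> str:
    """Format per-segment summaries as the standard event-count table.

    Columns: Index, TBK+, BTK+, TBCl−, BTCl−, Net Events, Conductance [pS];
    an average row with standard errors closes the table.
    """
    header = ["Index", "TBK+", "BTK+", "TBCl-", "BTCl-", "Net Events", "Conductance [pS]"]
    lines = ["\t".join(header)]
    for s in summaries:
        lines.append(
            f"{s.segment}\t{s.tb_k}\t{s.bt_k}\t{s.tb_cl}\t{s.bt_cl}\t"
            f"{s.net_events}\t{s.conductance_pS:.0f}"
        )
    if aggregate_row and len(summaries) >= 1:
        if len(summaries) >= 2:
            agg = cond.aggregate(summaries)
            cells = ["Average"]
            for col in ("tb_k", "bt_k", "tb_cl", "bt_cl", "net_events", "conductance_pS"):
                cells.append(f"{agg.means[col]:.0f} ± {agg.sems[col]:.0f}")
        else:
            s = summaries[0]
            cells = ["Average"] + [
                f"{v} ± 0"
                for v in (s.tb_k, s.bt_k, s.tb_cl, s.bt_cl, s.net_events, round(s.conductance_pS))
            ]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline


class _StageLogger:
    def __init__(self, log_path: Path | None):
        self.log_path = log_path
        self.records: list[dict] = []

    def log(self, stage: str, **info) -> None:
        rec = {"stage": stage, "wall_time": time.time(), **info}
        self.records.append(rec)
        line = json.dumps(rec, default=str)
        print(line, file=sys.stderr)
        if self.log_path is not None:
            with open(self.log_path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Ingest/simulate → detect → summarize → fit → classify, writing artifacts.

    Deterministic given the config's seed; each stage appends a structured
    log record (stage name, parameters, counts, wall time) to stderr and to
    ``pipeline.log`` in the output directory. Any stage error aborts with
    the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = _StageLogger(out / "pipeline.log")
    report: dict = {"config": config.to_dict()}

    stage = "setup"
    try:
        if config.mode == "counts":
            stage = "counts"
            summaries = [cond.summary_from_counts(c) for c in synth.table1_fixture()]
            agg = cond.aggregate(summaries)
            table = render_table1(summaries)
            (out / "table1.tsv").write_text(table, encoding="utf-8")
            logger.log(stage, n_segments=len(summaries), mean_net=agg.means["net_events"])
            report["aggregate"] = {
                "means": agg.means, "sems": agg.sems,
                "sd_to_mean": agg.sd_to_mean, "totals": agg.totals,
            }
            report["table"] = table
            (out / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
            return report

        if config.mode == "simulate":
            stage = "simulate"
            spec = synth.SyntheticSpec(duration=config.duration, seed=config.seed)
            bundle, truth = synth.generate_run(spec)
            write_ion_traces(bundle, out / "traces.tsv")
            logger.log(stage, n_traces=len(bundle.traces), n_true_events=len(truth.events),
                       duration_ns=spec.duration, seed=config.seed)
        elif config.mode == "ingest":
            stage = "ingest"
            if not config.traces:
                raise ValueError("ingest mode requires a traces path")
            bundle = load_ion_traces(config.traces)
            logger.log(stage, n_traces=len(bundle.traces))
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

        if config.ve is not None:
            bundle.metadata.membrane_voltage = config.ve
            bundle.metadata.field_strength = config.ve / bundle.metadata.box_height
        if not bundle.metadata.membrane_voltage:
            raise ValueError("membrane voltage is zero or missing; conductance undefined")

        stage = "detect"
        ledger = det.detect_crossings(bundle)
        write_events(ledger, out / "events.tsv")
        logger.log(stage, n_events=len(ledger), counts={f"{k[0]}:{_DIR_LABEL[k[1]]}": v
                                                        for k, v in ledger.counts().items()})

        stage = "conductance"
        if config.segment_ns and config.segment_ns < ledger.dt:
            ledgers = segment_ledger(ledger, config.segment_ns)
        else:
            ledgers = [ledger]
        summaries = []
        for lg in ledgers:
            md = dataclasses.replace(bundle.metadata, duration=lg.dt, segment=lg.segment)
            summaries.append(cond.summarize_segment(lg, md))
        table = render_table1(summaries)
        (out / "table1.tsv").write_text(table, encoding="utf-8")
        mean_g = float(np.mean([s.conductance_pS for s in summaries]))
        logger.log(stage, n_segments=len(summaries), mean_conductance_pS=mean_g)
        report["summaries"] = [dataclasses.asdict(s) | {
            "net_events": s.net_events, "conductance_pS": s.conductance_pS}
            for s in summaries]
        report["mean_conductance_pS"] = mean_g

        stage = "fit"
        w = det.waiting_times(ledger, TB, "K+")
        fits: dict = {"n_waiting_times": int(len(w))}
        if len(w) >= max(config.min_waiting_times, 3):
            pm = pstats.fit_poisson_quantile(w)
            fits["poisson_quantile_lam"] = pm.lam
            if config.model == "double-poisson" and len(w) >= 10:
                dp = pstats.fit_double_poisson(w, method=config.method)
                fits["double_poisson"] = {
                    "lam_lag": dp.lam_lag, "lam_cond": dp.lam_cond,
                    "log_likelihood": dp.log_likelihood,
                    "near_degenerate": dp.near_degenerate,
                    "predicted_events_per_segment": pstats.predicted_events(
                        dp, config.segment_ns or ledger.dt),
                }
        durs = det.event_durations(ledger)
        if len(durs) >= 5:
            df = pstats.fit_durations(durs)
            fits["duration_lognormal"] = {"mu": df.mu, "sigma": df.sigma,
                                          "implied_mean_ns": df.implied_mean}
        logger.log(stage, **{k: v for k, v in fits.items() if not isinstance(v, dict)})
        report["fits"] = fits
        (out / "fits.json").write_text(json.dumps(fits, indent=2), encoding="utf-8")

        stage = "pathways"
        window = paths.LateralWindow.from_geometry(bundle.geometry, config.lookback_ns)
        pw = paths.classify_pathways(ledger, bundle, window, pooled_time_ns=ledger.dt)
        report["pathways"] = {
            "lateral_count": pw.lateral_count,
            "lateral_fraction_tb_k": pw.lateral_fraction_tb_k,
            "lateral_rate_per_us": pw.lateral_rate_per_us,
        }
        logger.log(stage, **report["pathways"])

        (out / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
        return report
    except Exception as exc:
        logger.log("error", failed_stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
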