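"""Currents, single-channel conductance and I–V fits from event ledgers.

The current through the channel over a window Δt is the net translocated
charge: I = (e/Δt)·Σ qᵢnᵢ, summing over complete crossing events with
direction nᵢ = ±1 and ion charge qᵢ (elementary units). With the sign
conventions here — TB is the inward direction, cation TB events at negative
membrane voltage carry inward current — the net event count is
TBK+ + BTCl− − BTK+ − TBCl− and the conductance magnitude is
G = |net|·e/(Δt·|Ve|), reported in pS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_model import ELEMENTARY_CHARGE_C, SystemMetadata
from .event_detection import BT, TB, EventLedger

__all__ = [
    "RunSummary",
    "AggregateSummary",
    "IVFit",
    "summarize_segment",
    "summary_from_counts",
    "aggregate",
    "fit_iv",
]


@dataclass
class RunSummary:
    """Per-segment event bookkeeping and conductance (one table row)."""

    segment: str
    tb_k: int
    bt_k: int
    tb_cl: int
    bt_cl: int
    dt: float  # ns
    ve: float  # mV
    inward: bool = True

    @property
    def net_events(self) -> int:
        return self.tb_k + self.bt_cl - self.bt_k - self.tb_cl

    @property
    def current_pA(self) -> float:
        # e [C] * net / (dt [ns]) -> A; 1 A = 1e12 pA
        return ELEMENTARY_CHARGE_C * self.net_events / (self.dt * 1e-9) * 1e12

    @property
    def conductance_pS(self) -> float:
        # magnitude convention: inward cation flux at negative Ve is positive G
        return self.current_pA / abs(self.ve) * 1e3  # pA/mV = nS -> pS


@dataclass
class AggregateSummary:
    """Column means ± standard errors, variability ratios, pooled totals."""

    n: int
    means: dict[str, float]
    sems: dict[str, float]
    sd_to_mean: dict[str, float]
    totals: dict[str, int]


def summarize_segment(ledger: EventLedger, metadata: SystemMetadata) -> RunSummary:
    """Tally one segment's ledger into counts, current and conductance."""
    if metadata.duration <= 0:
        raise ValueError("segment duration must be positive")
    ve = metadata.membrane_voltage
    if ve is None or ve == 0:
        raise ValueError("conductance undefined at Ve = 0 (or missing voltage)")
    return RunSummary(
        segment=ledger.segment,
        tb_k=ledger.count("K+", TB),
        bt_k=ledger.count("K+", BT),
        tb_cl=ledger.count("Cl-", TB),
        bt_cl=ledger.count("Cl-", BT),
        dt=metadata.duration,
        ve=ve,
    )


def summary_from_counts(counts) -> RunSummary:
    """RunSummary from a published per-segment count record."""
    return RunSummary(
        segment=counts.segment,
        tb_k=counts.tb_k,
        bt_k=counts.bt_k,
        tb_cl=counts.tb_cl,
        bt_cl=counts.bt_cl,
        dt=counts.dt,
        ve=counts.ve,
    )


_COLUMNS = ("tb_k", "bt_k", "tb_cl", "bt_cl", "net_events", "conductance_pS")


def aggregate(summaries: Sequence[RunSummary]) -> AggregateSummary:
    """Column means ± standard error, sd-to-mean ratios and pooled totals.

    Standard errors use the population sd/√n (the convention the published
    average row follows); the variability (sd-to-mean) ratios use the
    sample standard deviation. Segments of unequal length cannot be
    averaged without normalization and raise.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 segment summaries")
    if len({s.dt for s in summaries}) > 1:
        raise ValueError("mixed segment lengths: normalize before aggregating")
    n = len(summaries)
    means, sems, ratios, totals = {}, {}, {}, {}
    for col in _COLUMNS:
        vals = np.asarray([getattr(s, col) for s in summaries], dtype=float)
        m = float(vals.mean())
        sd = float(vals.std(ddof=1))
        means[col] = m
        sems[col] = float(vals.std(ddof=0)) / np.sqrt(n)
        ratios[col] = sd / m if m != 0 else 0.0
        if col != "conductance_pS":
            totals[col] = int(round(vals.sum()))
    return AggregateSummary(n=n, means=means, sems=sems, sd_to_mean=ratios, totals=totals)


@dataclass
class IVFit:
    """Linear current–voltage fit for one voltage-sign branch."""

    branch: str  # "negative" | "positive"
    slope_pS: float
    intercept_pA: float | None
    slope_ci_pS: tuple[float, float] | None
    n: int


def _fit_branch(v: np.ndarray, i: np.ndarray, branch: str, through_origin: bool) -> IVFit:
    if through_origin:
        slope = float(np.dot(v, i) / np.dot(v, v))
        n, dof = len(v), len(v) - 1
        resid = i - slope * v
        ci = None
        if dof > 0 and np.dot(v, v) > 0:
            se = float(np.sqrt(np.sum(resid**2) / dof / np.dot(v, v)))
            tcrit = stats.t.ppf(0.975, dof)
            ci = ((slope - tcrit * se) * 1e3, (slope + tcrit * se) * 1e3)
        return IVFit(branch, slope * 1e3, None, ci, n)
    if len(np.unique(v)) < 2:
        raise ValueError(f"singular I-V fit: all {branch}-branch points at one voltage")
    res = stats.linregress(v, i)
    dof = len(v) - 2
    ci = None
    if dof > 0 and np.isfinite(res.stderr) and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, dof)
        ci = ((res.slope - tcrit * res.stderr) * 1e3, (res.slope + tcrit * res.stderr) * 1e3)
    return IVFit(branch, float(res.slope) * 1e3, float(res.intercept), ci, len(v))


def fit_iv(points: Sequence[tuple[float, float]], through_origin: bool = False) -> dict[str, IVFit]:
    """Least-squares I–V line per voltage-sign branch.

    ``points`` are (Ve [mV], I [pA]); slopes come back in pS (pA/mV = nS).
    Branches are fitted separately; a branch with fewer than 2 points is
    simply absent from the result.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (Ve, I) pairs")
    out: dict[str, IVFit] = {}
    for branch, mask in (("negative", pts[:, 0] < 0), ("positive", pts[:, 0] > 0)):
        if mask.sum() >= 2:
            out[branch] = _fit_branch(pts[mask, 0], pts[mask, 1], branch, through_origin)
    return out
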