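"""Ensemble statistics and fits computed from recorded trajectories.

Every function here is a pure function of :class:`~topocoil.state.Trajectory`
data, so all results are recomputable offline from saved runs.  Rates are
*empirical*: realized event counts per unit time and realized
transcript-length-over-duration speeds, as opposed to the configured rate
constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .state import GeneSpec, SimulationConfig, Trajectory

__all__ = [
    "FitResult",
    "SweepTable",
    "empirical_initiation_rate",
    "empirical_elongation_rate",
    "transcript_rates",
    "fano_factor",
    "ensemble_fano",
    "adjacent_rnap_correlation",
    "adjacent_spacing_and_load",
    "report_window_segments",
    "piecewise_linear_fit",
    "mse_vs_reference",
    "load_reference_elongation",
    "build_sweep_table",
    "state_conditioned_histograms",
    "stall_durations",
    "kymograph",
    "loop_state_conditioned_rates",
    "mean_mrna_trace",
]


# ---------------------------------------------------------------- rates


def _gene_spec(traj: Trajectory, gene: int) -> GeneSpec:
    cfg: SimulationConfig = traj.metadata["config"]
    return cfg.genes[gene]


def empirical_initiation_rate(
    trajs: Sequence[Trajectory], window: Tuple[float, float], gene: int = 0
) -> float:
    """Realized initiation rate: initiation events inside ``window`` per
    unit time, averaged over replicates."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    n = 0
    for tr in trajs:
        ev = tr.events_of("initiation")
        ev = ev[ev["gene"] == gene]
        n += int(((ev["t"] >= t0) & (ev["t"] <= t1)).sum())
    return n / ((t1 - t0) * len(trajs))


def transcript_rates(
    trajs: Sequence[Trajectory],
    window: Tuple[float, float],
    gene: int = 0,
    by_start_time: bool = False,
) -> np.ndarray:
    """Per-transcript elongation rates (bp/s) for completed transcripts.

    A transcript's rate is its scored length over its duration.  When the
    gene declares a ``report_window_bp``, scoring uses the crossing of that
    prefix (rounded up to whole segments); otherwise the full-length
    termination event.  Transcripts are selected by completion time inside
    ``window`` (or by initiation time when ``by_start_time``).
    """
    t0, t1 = window
    spec = _gene_spec(trajs[0], gene)
    cfg: SimulationConfig = trajs[0].metadata["config"]
    seg = cfg.lattice.segment_bp
    if spec.report_window_bp is not None:
        kind = "window"
        length = math.ceil(spec.report_window_bp / seg) * seg
    else:
        kind = "termination"
        length = spec.length_bp(seg)
    rates: List[float] = []
    for tr in trajs:
        ev = tr.events_of(kind)
        ev = ev[ev["gene"] == gene]
        tref = ev["t"] - ev["value"] if by_start_time else ev["t"]
        sel = ev[(tref >= t0) & (tref <= t1) & (ev["value"] > 0)]
        rates.extend(length / sel["value"])
    return np.asarray(rates)


def empirical_elongation_rate(
    trajs: Sequence[Trajectory],
    window: Tuple[float, float],
    gene: int = 0,
    by_start_time: bool = False,
) -> Optional[float]:
    """Mean per-transcript elongation rate (bp/s) in the window, or None
    (flagged missing, not zero) when no transcript completed."""
    r = transcript_rates(trajs, window, gene=gene, by_start_time=by_start_time)
    return float(r.mean()) if r.size else None


# ---------------------------------------------------------------- noise


def fano_factor(counts: Sequence[float]) -> Optional[float]:
    """Variance/mean of a count sample (ddof=1); None when the mean is 0."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("fano_factor needs >= 2 observations")
    m = c.mean()
    if m == 0:
        return None
    return float(c.var(ddof=1) / m)


def ensemble_fano(
    trajs: Sequence[Trajectory],
    gene: int = 0,
    at_time: Optional[float] = None,
    pooled_frames_after: Optional[float] = None,
) -> Tuple[Optional[float], float]:
    """(Fano factor, mean) of the mRNA copy number across replicates.

    Default: one snapshot per replicate at ``at_time`` (the final frame when
    omitted).  ``pooled_frames_after`` switches to pooling all frames past a
    burn-in instead (alternative ensemble definition).
    """
    counts: List[float] = []
    for tr in trajs:
        if pooled_frames_after is not None:
            sel = tr.times >= pooled_frames_after
            counts.extend(tr.mrna[sel, gene])
        else:
            idx = -1 if at_time is None else int(np.argmin(np.abs(tr.times - at_time)))
            counts.append(tr.mrna[idx, gene])
    m = float(np.mean(counts))
    return fano_factor(counts), m


# ---------------------------------------------------------------- RNAP geometry


def _positions_by_id(tr: Trajectory, gene: int) -> Dict[int, Dict[int, int]]:
    """rnap id -> {frame index: segment} for one gene."""
    out: Dict[int, Dict[int, int]] = {}
    for f, arr in enumerate(tr.rnap_frames):
        for row in arr:
            if row[1] == gene:
                out.setdefault(int(row[0]), {})[f] = int(row[2])
    return out


def _adjacent_increment_pairs(
    tr: Trajectory, gene: int, frames: Iterable[int]
) -> Tuple[List[float], List[float]]:
    """Pooled 1-frame displacement increments of genomically adjacent RNAP
    pairs over their co-transcription overlap."""
    xs: List[float] = []
    ys: List[float] = []
    frames = list(frames)
    fset = set(frames)
    for f in frames:
        if f + 1 not in fset and f + 1 >= len(tr.rnap_frames):
            continue
        arr0 = tr.rnap_frames[f]
        arr1 = tr.rnap_frames[f + 1] if f + 1 < len(tr.rnap_frames) else None
        if arr1 is None:
            continue
        g0 = arr0[arr0[:, 1] == gene]
        g1 = arr1[arr1[:, 1] == gene]
        if len(g0) < 2:
            continue
        pos1 = {int(r[0]): int(r[2]) for r in g1}
        order = np.argsort(g0[:, 2])
        g0 = g0[order]
        for i in range(len(g0) - 1):
            a, b = int(g0[i, 0]), int(g0[i + 1, 0])
            if a in pos1 and b in pos1:
                xs.append(pos1[a] - int(g0[i, 2]))
                ys.append(pos1[b] - int(g0[i + 1, 2]))
    return xs, ys


def adjacent_rnap_correlation(
    trajs: Sequence[Trajectory],
    window: Tuple[float, float],
    gene: int = 0,
    min_pairs: int = 10,
) -> Optional[float]:
    """Raw Pearson correlation of 1-frame position increments of adjacent
    RNAP pairs, pooled over their co-transcription overlap; None (flagged)
    when fewer than ``min_pairs`` increment pairs exist."""
    t0, t1 = window
    xs: List[float] = []
    ys: List[float] = []
    for tr in trajs:
        fsel = [i for i, t in enumerate(tr.times) if t0 <= t <= t1]
        x, y = _adjacent_increment_pairs(tr, gene, fsel)
        xs.extend(x)
        ys.extend(y)
    if len(xs) < min_pairs:
        return None
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def independence_surrogate_correlation(
    trajs: Sequence[Trajectory],
    window: Tuple[float, float],
    gene: int = 0,
) -> float:
    """The "independently transcribing" anchor for normalization: increments
    of RNAPs paired across different replicates, which share no supercoiling
    field and hence no mechanical coupling."""
    t0, t1 = window
    per_rep: List[np.ndarray] = []
    for tr in trajs:
        fsel = [i for i, t in enumerate(tr.times) if t0 <= t <= t1]
        x, _ = _adjacent_increment_pairs(tr, gene, fsel)
        if x:
            per_rep.append(np.asarray(x, float))
    if len(per_rep) < 2:
        return 0.0
    xs: List[float] = []
    ys: List[float] = []
    for i in range(len(per_rep) - 1):
        a, b = per_rep[i], per_rep[i + 1]
        n = min(len(a), len(b))
        xs.extend(a[:n])
        ys.extend(b[:n])
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def normalize_correlation(r: float, r0: float, r1: float) -> float:
    """r' = (r - r0)/(r1 - r0): 0 = independent RNAPs, 1 = the co-transcribing
    correlation of the most highly expressed condition in the same sweep."""
    if r1 == r0:
        raise ValueError("degenerate normalization anchors")
    return (r - r0) / (r1 - r0)


def report_window_segments(cfg: SimulationConfig, gene: int = 0) -> Optional[Tuple[int, int]]:
    """Segment interval (inclusive) covering the gene's scored prefix
    (``report_window_bp``, rounded up to whole segments), strand-aware;
    None when the gene scores its full length."""
    spec = cfg.genes[gene]
    if spec.report_window_bp is None:
        return None
    n_win = math.ceil(spec.report_window_bp / cfg.lattice.segment_bp)
    if spec.direction > 0:
        lo = spec.tss_segment
        return lo, lo + n_win - 1
    hi = spec.tss_segment
    return hi - n_win + 1, hi


def adjacent_spacing_and_load(
    trajs: Sequence[Trajectory],
    window: Tuple[float, float],
    gene: int = 0,
    segment_range: Optional[Tuple[int, int]] = None,
) -> Tuple[Optional[float], Optional[float]]:
    """(mean adjacent-RNAP distance in bp, mean co-transcribing RNAP count).

    Distances are per-frame gaps between successive RNAPs on the gene; the
    load average uses only frames with at least one RNAP present (frames
    without active transcription carry no information about co-transcription).
    ``segment_range`` restricts both statistics to RNAPs inside an interval
    — used to score only the reported prefix of a longer transcription unit.
    """
    t0, t1 = window
    cfg: SimulationConfig = trajs[0].metadata["config"]
    seg_bp = cfg.lattice.segment_bp
    gaps: List[float] = []
    loads: List[int] = []
    for tr in trajs:
        for f, t in enumerate(tr.times):
            if not (t0 <= t <= t1):
                continue
            arr = tr.rnap_frames[f]
            g = arr[arr[:, 1] == gene]
            if segment_range is not None:
                lo, hi = segment_range
                g = g[(g[:, 2] >= lo) & (g[:, 2] <= hi)]
            if len(g) == 0:
                continue
            loads.append(len(g))
            if len(g) > 1:
                pos = np.sort(g[:, 2])
                gaps.extend(np.diff(pos) * seg_bp)
    return (
        float(np.mean(gaps)) if gaps else None,
        float(np.mean(loads)) if loads else None,
    )


# ---------------------------------------------------------------- fits


@dataclass
class FitResult:
    """Continuous-hinge fit y = k*min(x, x*) + b of elongation vs initiation.

    ``slope`` quantifies cooperativity (how strongly elongation rises with
    initiation before saturating at the breakpoint ``breakpoint``).
    ``fitted`` is False when the condition never reached an empirical
    initiation rate of 0.05/s (the fit is not performed there).
    """

    slope: float
    intercept: float
    breakpoint: float
    r_squared: float
    fitted: bool = True

    @property
    def plateau(self) -> float:
        return self.slope * self.breakpoint + self.intercept


def piecewise_linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    min_max_x: float = 0.05,
    n_grid: int = 201,
) -> FitResult:
    """Least-squares continuous hinge fit with the breakpoint searched over
    a grid spanning the observed x-range (observed x values included, so
    noiseless hinge data is recovered exactly)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need >= 4 points for the piecewise fit")
    if np.unique(x).size == 1:
        raise ValueError("degenerate x: all values equal")
    fitted = bool(x.max() >= min_max_x)
    grid = np.unique(
        np.concatenate([np.linspace(x.min(), x.max(), n_grid), np.unique(x)])
    )
    # x* at or below min(x) makes the hinge column constant (collinear with
    # the intercept); the breakpoint must lie inside the data's x-range
    grid = grid[grid > x.min()]

    def sse_at(xstar):
        xx = np.minimum(x, xstar)
        A = np.column_stack([xx, np.ones_like(xx)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(((A @ coef - y) ** 2).sum()), coef

    sst = float(((y - y.mean()) ** 2).sum())
    best = None
    for i, xstar in enumerate(grid):
        sse, coef = sse_at(xstar)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, coef[0], coef[1], xstar, i)
    sse, k, b, xstar, i_best = best
    # refine between the neighbouring grid points (SSE is piecewise smooth)
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    if hi > lo:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda s: sse_at(s)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        sse_r, coef_r = sse_at(float(res.x))
        if sse_r < sse:
            sse, k, b, xstar = sse_r, coef_r[0], coef_r[1], float(res.x)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return FitResult(slope=float(k), intercept=float(b), breakpoint=float(xstar), r_squared=float(r2), fitted=fitted)


def mse_vs_reference(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """Mean squared error (1/n) sum (Y_i - Yhat_i)^2 between measured and
    simulated elongation rates at matched initiation rates."""
    p = np.asarray(predicted, float)
    r = np.asarray(reference, float)
    if p.shape != r.shape:
        raise ValueError("length mismatch between predicted and reference")
    return float(np.mean((r - p) ** 2))


@dataclass
class SweepTable:
    """Phase-diagram grid over (diffusion coefficient, Topo I unbinding).

    ``table`` has one row per cell with the cooperativity fit parameters,
    the optional MSE against reference elongation data, and a mask column
    marking cells where the fit was not performed or r^2 < 0.85.
    """

    table: pd.DataFrame
    r2_threshold: float = 0.85

    def masked(self) -> pd.DataFrame:
        return self.table[self.table["mask"]]


def load_reference_elongation(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read measured (initiation rate, elongation rate) pairs from a
    2-column CSV (header optional); returns sorted arrays."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError("reference CSV needs two columns: initiation, elongation")
    if not np.issubdtype(df.iloc[:, 0].dtype, np.number):
        raise ValueError("reference CSV has non-numeric values")
    x = df.iloc[:, 0].to_numpy(float)
    y = df.iloc[:, 1].to_numpy(float)
    order = np.argsort(x)
    return x[order], y[order]


def build_sweep_table(
    cell_summaries: "pd.DataFrame",
    reference: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    r2_threshold: float = 0.85,
) -> SweepTable:
    """Assemble the cooperativity phase diagram from per-cell sweep output.

    ``cell_summaries`` concatenates the per-replicate rows written by the
    sweep driver (columns ``D``, ``topoI_unbind``, ``k_max``,
    ``empirical_initiation_rate_per_s``, ``mean_elongation_rate_bp_per_s``).
    For every (D, topoI_unbind) cell the empirical elongation-initiation
    curve across promoter strengths is fitted with the continuous hinge;
    cells whose maximum empirical initiation rate stays below 0.05/s are
    not fitted, and ``mask`` flags those plus fits with r^2 below the
    threshold.  When ``reference`` measurements are given, each fitted
    cell's hinge prediction at the reference initiation rates is compared
    by mean squared error.
    """
    rows = []
    for (D, ku), grp in cell_summaries.groupby(["D", "topoI_unbind"]):
        cond = grp.groupby("k_max").agg(
            x=("empirical_initiation_rate_per_s", "mean"),
            y=("mean_elongation_rate_bp_per_s", "mean"),
        )
        cond = cond.dropna()
        row = {"D": D, "topoI_unbind": ku, "n_conditions": len(cond)}
        fit = None
        if len(cond) >= 4 and cond["x"].nunique() > 1:
            fit = piecewise_linear_fit(cond["x"], cond["y"])
        if fit is None or not fit.fitted:
            row.update(
                slope=np.nan, intercept=np.nan, breakpoint=np.nan,
                r_squared=np.nan, fitted=False, mask=True, mse=np.nan,
            )
        else:
            row.update(
                slope=fit.slope, intercept=fit.intercept, breakpoint=fit.breakpoint,
                r_squared=fit.r_squared, fitted=True,
                mask=bool(fit.r_squared < r2_threshold),
            )
            if reference is not None:
                xr, yr = reference
                pred = fit.slope * np.minimum(xr, fit.breakpoint) + fit.intercept
                row["mse"] = mse_vs_reference(pred, yr)
            else:
                row["mse"] = np.nan
        rows.append(row)
    return SweepTable(table=pd.DataFrame(rows), r2_threshold=r2_threshold)


# ---------------------------------------------------------------- histograms


def state_conditioned_histograms(
    trajs: Sequence[Trajectory],
    window: Tuple[float, float],
    gene: int = 0,
    bins: Optional[np.ndarray] = None,
) -> Dict[str, pd.DataFrame]:
    """Histograms of flank supercoiling density and net torque per RNAP per
    frame, partitioned by mode (processive vs stalled)."""
    from . import mechanics

    cfg: SimulationConfig = trajs[0].metadata["config"]
    mech = cfg.mechanics
    t0, t1 = window
    rows = {"sigma_up": [], "sigma_down": [], "torque": [], "stalled": []}
    for tr in trajs:
        fsel = {f for f, t in enumerate(tr.times) if t0 <= t <= t1}
        for su, sd, stalled in _flank_sigma_frames_window(tr, gene, fsel):
            rows["sigma_up"].append(su)
            rows["sigma_down"].append(sd)
            rows["torque"].append(mechanics.net_torque(sd, su, mech))
            rows["stalled"].append(stalled)
    df = pd.DataFrame(rows)
    out: Dict[str, pd.DataFrame] = {"samples": df}
    for col in ("sigma_up", "sigma_down", "torque"):
        b = bins
        if b is None:
            b = np.linspace(-1, 1, 41) if col != "torque" else np.linspace(-40, 40, 41)
        hists = {}
        for lab, sel in (("processive", ~df["stalled"].astype(bool)), ("stalled", df["stalled"].astype(bool))):
            h, edges = np.histogram(df.loc[sel, col], bins=b)
            hists[lab] = h
        out[col] = pd.DataFrame(hists, index=pd.IntervalIndex.from_breaks(np.asarray(b)))
    return out


def _flank_sigma_frames_window(tr: Trajectory, gene: int, fsel):
    cfg: SimulationConfig = tr.metadata["config"]
    lk0 = cfg.lattice.lk0_units
    S = cfg.lattice.n_segments
    d = cfg.genes[gene].direction
    if tr.turn is None:
        raise ValueError("state-conditioned histograms require record_turn=True")
    for f in sorted(fsel):
        arr = tr.rnap_frames[f]
        g = arr[arr[:, 1] == gene]
        occupied = set(int(r[2]) for r in arr)
        prof = tr.turn[f]
        for row in g:
            k = int(row[2])
            flanks = []
            for side in (-d, +d):
                j = k + side
                while 0 <= j < S and j in occupied:
                    j += side
                j = min(max(j, 0), S - 1)
                flanks.append((prof[j] - lk0) / lk0)
            yield flanks[0], flanks[1], bool(row[3])


def stall_durations(trajs: Sequence[Trajectory], gene: int = 0) -> np.ndarray:
    """Completed stall-episode durations (s); episodes censored at the run
    end are never logged and are therefore excluded by construction."""
    out: List[float] = []
    for tr in trajs:
        ev = tr.events_of("stall")
        ev = ev[ev["gene"] == gene]
        out.extend(ev["value"])
    return np.asarray(out)


# ---------------------------------------------------------------- kymograph


def kymograph(tr: Trajectory) -> Tuple[np.ndarray, List[np.ndarray]]:
    """(sigma matrix of shape (frames, segments), RNAP overlay).

    The overlay is a list of (n, 3) arrays per frame: (id, segment, mode).
    Requires ``record_turn=True``.
    """
    if tr.turn is None:
        raise ValueError("kymograph requires record_turn=True")
    cfg: SimulationConfig = tr.metadata["config"]
    lk0 = cfg.lattice.lk0_units
    sigma = (tr.turn - lk0) / lk0
    overlay = [arr[:, [0, 2, 3]] for arr in tr.rnap_frames]
    return sigma, overlay


def save_kymograph_csv(tr: Trajectory, path: str) -> None:
    sigma, _ = kymograph(tr)
    pd.DataFrame(sigma, index=tr.times).to_csv(path, index_label="t_s")


def plot_kymograph(tr: Trajectory, ax=None, cmap: str = "RdBu_r"):
    """Render sigma(segment, time) with RNAP trajectories overlaid
    (positive supercoiling in warm colors downstream of moving RNAPs)."""
    import matplotlib.pyplot as plt

    sigma, overlay = kymograph(tr)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    vmax = max(0.2, np.abs(sigma).max())
    im = ax.imshow(
        sigma,
        aspect="auto",
        origin="lower",
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        extent=[0, sigma.shape[1], tr.times[0], tr.times[-1]],
    )
    for f, arr in enumerate(overlay):
        for row in arr:
            ax.plot(row[1] + 0.5, tr.times[f], "k.", ms=1)
    ax.set_xlabel("segment")
    ax.set_ylabel("time (s)")
    plt.colorbar(im, ax=ax, label="supercoiling density")
    return ax


# ---------------------------------------------------------------- loop-conditioned


def _loop_intervals(tr: Trajectory, barrier: int, t_end: float) -> List[Tuple[float, float, bool]]:
    """(t0, t1, looped) intervals reconstructed from the initial loop state
    and the loop/unloop event log."""
    state = bool(tr.loop_state[0, barrier])
    t_prev = float(tr.times[0])
    out: List[Tuple[float, float, bool]] = []
    ev = tr.events[np.isin(tr.events["kind"], ("loop", "unloop"))]
    ev = ev[ev["value"] == barrier]
    for e in np.sort(ev, order="t"):
        out.append((t_prev, float(e["t"]), state))
        state = e["kind"] == "loop"
        t_prev = float(e["t"])
    out.append((t_prev, t_end, state))
    return out


def loop_state_conditioned_rates(
    trajs: Sequence[Trajectory],
    gene: int = 0,
    barrier: int = 0,
    window: Optional[Tuple[float, float]] = None,
) -> Dict[str, float]:
    """Initiation rate with exposure time split by loop state.

    Returns open/closed exposure times, event counts and rates; for a
    permanent barrier all exposure is 'closed'.
    """
    t_open = t_closed = 0.0
    n_open = n_closed = 0
    for tr in trajs:
        t_end = float(tr.metadata["t_end"])
        t0, t1 = window if window is not None else (0.0, t_end)
        ivs = _loop_intervals(tr, barrier, t_end)
        ini = tr.events_of("initiation")
        ini = ini[ini["gene"] == gene]
        for a, b, looped in ivs:
            a2, b2 = max(a, t0), min(b, t1)
            if b2 <= a2:
                continue
            n = int(((ini["t"] > a2) & (ini["t"] <= b2)).sum())
            if looped:
                t_closed += b2 - a2
                n_closed += n
            else:
                t_open += b2 - a2
                n_open += n
    return {
        "open_exposure_s": t_open,
        "closed_exposure_s": t_closed,
        "open_initiations": n_open,
        "closed_initiations": n_closed,
        "open_rate": n_open / t_open if t_open > 0 else float("nan"),
        "closed_rate": n_closed / t_closed if t_closed > 0 else float("nan"),
    }


def mean_mrna_trace(trajs: Sequence[Trajectory], gene: int = 0) -> pd.DataFrame:
    """Ensemble mean (and SD / SEM) mRNA copy number versus time."""
    m = np.stack([tr.mrna[:, gene] for tr in trajs])
    return pd.DataFrame(
        {
            "t": trajs[0].times,
            "mean": m.mean(axis=0),
            "sd": m.std(axis=0, ddof=1) if m.shape[0] > 1 else 0.0,
            "sem": (m.std(axis=0, ddof=1) / math.sqrt(m.shape[0])) if m.shape[0] > 1 else 0.0,
        }
    )


def intergenic_sigma_summary(
    trajs: Sequence[Trajectory], region: str = "intergenic", window: Optional[Tuple[float, float]] = None
) -> Dict[str, float]:
    """Time-averaged supercoiling density of a recorded region across the
    ensemble (mean, SD over replicate means, SEM)."""
    means = []
    for tr in trajs:
        if not tr.region_means or region not in tr.region_means:
            raise ValueError(f"region {region!r} was not recorded")
        v = tr.region_means[region]
        if window is not None:
            sel = (tr.times >= window[0]) & (tr.times <= window[1])
            v = v[sel]
        means.append(float(np.mean(v)))
    means = np.asarray(means)
    return {
        "mean": float(means.mean()),
        "sd": float(means.std(ddof=1)) if means.size > 1 else 0.0,
        "sem": float(means.std(ddof=1) / math.sqrt(means.size)) if means.size > 1 else 0.0,
        "n": int(means.size),
    }
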