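"""End-point and per-step statistics of adaptation ensembles.

Summarises trajectory ensembles the way the study's results are reported:
growth ratio ``g / g_FBA`` at absorption, Pearson correlation of the
end-point flux with the pFBA flux, the norm ratio ``||v|| / ||v_pFBA||``
(growth is proportional to the norm once a flux is aligned with the pFBA
ray), absorption times, trajectory lengths, active-reaction counts, the
joint (correlation x growth) and (norm x growth) histograms, and a census
of which polytope bounds become active along a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import FluxVector, MetabolicNetwork

__all__ = [
    "flux_correlation",
    "EndpointRecord",
    "EnsembleSummary",
    "endpoint_summary",
    "adaptation_curves",
    "active_bound_census",
]


def flux_correlation(v, v_ref, method: str = "pearson") -> float:
    """Correlation between two flux distributions over all reactions.

    Pearson (default) or uncentred cosine; silenced reactions contribute
    their zeros.  Both are invariant to positive rescaling of either
    vector, which is what makes the statistic blind to the norm (and hence
    the growth) of the flux.  Returns NaN when undefined (constant input
    under Pearson, zero vector under cosine).
    """
    a = np.asarray(v.values if isinstance(v, FluxVector) else v, dtype=float)
    b = np.asarray(v_ref.values if isinstance(v_ref, FluxVector) else v_ref,
                   dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if method == "pearson":
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            return float("nan")
        return float(a @ b / (na * nb))
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass(frozen=True)
class EndpointRecord:
    """Per-trajectory end-point statistics."""

    growth_ratio: float
    corr_pfba: float
    norm_ratio: float
    absorption_step: int
    length: int
    active_count: int
    absorbed: bool


@dataclass
class EnsembleSummary:
    """Ensemble-level end-point summary with its defining histograms."""

    n_trajectories: int
    mean_growth_ratio: float
    median_growth_ratio: float
    mean_corr: float
    median_corr: float
    frac_corr_ge_09: float
    frac_growth_ge_085: float
    frac_max_growth: float  #: growth_ratio >= 0.999
    mean_absorption_step: float
    std_absorption_step: float
    mean_length: float
    hist_growth: tuple = field(repr=False, default=None)
    hist_corr: tuple = field(repr=False, default=None)
    hist2d_corr_growth: tuple = field(repr=False, default=None)
    hist2d_norm_growth: tuple = field(repr=False, default=None)


def endpoint_summary(
    trajectories,
    v_pfba: FluxVector,
    g_fba: float,
    correlation: str = "pearson",
    bins: int = 25,
) -> tuple[list[EndpointRecord], EnsembleSummary]:
    """End-point records and their ensemble summary.

    ``v_pfba`` and ``g_fba`` must come from the unreduced polytope of the
    same network the trajectories ran on.
    """
    if not trajectories:
        raise ValueError("empty trajectory list")
    if g_fba <= 0:
        raise ValueError("g_fba must be positive")
    pfba_norm = v_pfba.norm
    records = []
    for tr in trajectories:
        last = tr.steps[-1]
        v_end = tr.final_state.flux
        records.append(
            EndpointRecord(
                growth_ratio=last.growth / g_fba,
                corr_pfba=flux_correlation(v_end, v_pfba, method=correlation),
                norm_ratio=v_end.norm / pfba_norm if pfba_norm > 0 else float("nan"),
                absorption_step=tr.absorption_step,
                length=tr.length,
                active_count=last.n_active,
                absorbed=tr.absorbed,
            )
        )
    g = np.array([rec.growth_ratio for rec in records])
    c = np.array([rec.corr_pfba for rec in records])
    nr = np.array([rec.norm_ratio for rec in records])
    ab = np.array([rec.absorption_step for rec in records], dtype=float)
    c_ok = c[~np.isnan(c)]
    summary = EnsembleSummary(
        n_trajectories=len(records),
        mean_growth_ratio=float(g.mean()),
        median_growth_ratio=float(np.median(g)),
        mean_corr=float(c_ok.mean()) if c_ok.size else float("nan"),
        median_corr=float(np.median(c_ok)) if c_ok.size else float("nan"),
        frac_corr_ge_09=float(np.mean(c_ok >= 0.9)) if c_ok.size else float("nan"),
        frac_growth_ge_085=float(np.mean(g >= 0.85)),
        frac_max_growth=float(np.mean(g >= 0.999)),
        mean_absorption_step=float(ab.mean()),
        std_absorption_step=float(ab.std()),
        mean_length=float(np.mean([rec.length for rec in records])),
        hist_growth=np.histogram(g, bins=bins, range=(0.0, max(1.0, g.max()))),
        hist_corr=np.histogram(np.nan_to_num(c, nan=0.0), bins=bins,
                               range=(-1.0, 1.0)),
        hist2d_corr_growth=np.histogram2d(
            np.nan_to_num(c, nan=0.0), g, bins=bins,
            range=[[-1.0, 1.0], [0.0, max(1.0, g.max())]],
        ),
        hist2d_norm_growth=np.histogram2d(
            np.nan_to_num(nr, nan=0.0), g, bins=bins,
            range=[[0.0, max(1.0, np.nanmax(nr))], [0.0, max(1.0, g.max())]],
        ),
    )
    return records, summary


def adaptation_curves(trajectories, g_fba: float | None = None) -> pd.DataFrame:
    """Per-step ensemble mean/std/median of growth ratio and correlation.

    Absorbed (or simply shorter) trajectories are padded with their final
    values so every step averages over the full ensemble, matching how
    mean-over-trajectories adaptation curves are drawn.  The returned frame
    carries ``monotone_*`` flags for the two mean curves.
    """
    if not trajectories:
        raise ValueError("empty trajectory list")
    horizon = max(len(tr.steps) for tr in trajectories)
    n = len(trajectories)
    growth = np.empty((n, horizon))
    corr = np.empty((n, horizon))
    for j, tr in enumerate(trajectories):
        gs = [s.growth for s in tr.steps]
        cs = [s.corr_ref for s in tr.steps]
        pad = horizon - len(gs)
        growth[j] = np.concatenate([gs, np.full(pad, gs[-1])])
        corr[j] = np.concatenate([cs, np.full(pad, cs[-1])])
    if g_fba:
        growth = growth / g_fba
    df = pd.DataFrame(
        {
            "step": np.arange(horizon),
            "mean_growth_ratio": growth.mean(axis=0),
            "std_growth_ratio": growth.std(axis=0),
            "median_growth_ratio": np.median(growth, axis=0),
            "mean_corr_pfba": np.nanmean(corr, axis=0),
            "std_corr_pfba": np.nanstd(corr, axis=0),
            "median_corr_pfba": np.nanmedian(corr, axis=0),
        }
    )
    tol = 1e-10
    df.attrs["monotone_mean_growth"] = bool(
        np.all(np.diff(df["mean_growth_ratio"]) >= -tol)
    )
    df.attrs["monotone_mean_corr"] = bool(
        np.all(np.diff(df["mean_corr_pfba"].dropna()) >= -tol)
    )
    return df


def active_bound_census(
    trajectory,
    network: MetabolicNetwork,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Count, per step, the polytope bounds the flux sits on.

    A bound is active when ``|v_i - l_i| <= tol`` or ``|v_i - u_i| <= tol``
    for a non-silenced reaction ``i`` (bounds of the current reduced
    polytope).  Counts are returned in long form: total, exchange/internal
    split, and per-subsystem groups.  Requires the trajectory to have been
    run with per-step flux retention.
    """
    if trajectory.fluxes is None:
        raise ValueError(
            "trajectory has no per-step fluxes; re-run with retain_fluxes=True"
        )
    lo0, hi0 = network.lower_bounds, network.upper_bounds
    silenced: set[int] = set()
    rows = []
    sub_labels = np.asarray(network.subsystems)
    for step, (rec, v) in enumerate(zip(trajectory.steps, trajectory.fluxes)):
        if rec.action == "silence" and rec.silenced_reaction:
            silenced.add(network.index(rec.silenced_reaction))
        mask = np.ones(network.r, dtype=bool)
        if silenced:
            mask[list(silenced)] = False
        at = mask & (
            (np.abs(v - lo0) <= tol) | (np.abs(v - hi0) <= tol)
        )
        rows.append({"step": step, "group": "total", "count": int(at.sum())})
        rows.append({"step": step, "group": "exchange",
                     "count": int((at & network.is_exchange).sum())})
        rows.append({"step": step, "group": "internal",
                     "count": int((at & ~network.is_exchange).sum())})
        for sub in sorted(set(network.subsystems) - {""}):
            rows.append(
                {"step": step, "group": f"subsystem:{sub}",
                 "count": int((at & (sub_labels == sub)).sum())}
            )
    return pd.DataFrame(rows)
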