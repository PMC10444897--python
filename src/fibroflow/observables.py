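"""Lysis metrics and ensemble experiments.

Metrics operate on a :class:`SimulationRecord` (time series sampled during a
coupled clot-flow-lysis run) or directly on fibrin/velocity fields:

- front position: contiguous lysed depth from the inlet face (a slice counts
  as lysed when its transverse-average fibrin drops strictly below Fstar);
- remaining mass fraction; volumetric throughput through the clot region;
- quartile lysis times t_1/4, t_1/2, t_3/4 (first instants at which 25/50/75%
  of the initial fibrin mass is gone, linearly interpolated, NaN-censored
  when never reached, mirroring how unfinished lyses are excluded from
  ensemble boxplots);
- recanalization onset: first instant the throughput exceeds a configurable
  fraction (default 50%) of the final, end-of-run throughput.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationRecord",
    "EnsembleSummary",
    "front_from_field",
    "mass_fraction",
    "throughput",
    "lysis_quartiles",
    "recanalization_onset",
    "run_ensemble",
]


@dataclass
class SimulationRecord:
    """Sampled observables of one coupled lysis run.

    throughput is volume flow per unit depth (m^2/s) in 2D.  slice_times[j]
    is the first instant the j-th clot slice (counted from the inlet face)
    reached the lysis threshold; NaN if it never did.
    """

    times: np.ndarray
    front_m: np.ndarray
    mass_frac: np.ndarray
    throughput: np.ndarray
    u_mean_clot: np.ndarray
    slice_times: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("times", "front_m", "mass_frac", "throughput",
                     "u_mean_clot", "slice_times"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any((self.mass_frac < -1e-12) | (self.mass_frac > 1 + 1e-12)):
            raise ValueError("mass fraction out of [0, 1]")
        if np.any(np.diff(self.front_m) < -1e-12):
            raise ValueError("front position must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "front_position_m": self.front_m,
                "mass_fraction": self.mass_frac,
                "throughput_m2_per_s": self.throughput,
                "mean_velocity_m_per_s": self.u_mean_clot,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def meta_json(self) -> str:
        return json.dumps(self.meta, indent=2, sort_keys=True, default=str)


def front_from_field(F: np.ndarray, Fstar: float, mask: np.ndarray,
                     dx: float, axis: int = 1) -> float:
    """Contiguous lysed depth (m) from the inlet face of the clot.

    A transverse slice is lysed when its mean fibrin over clot voxels is
    strictly below Fstar; trapped unlysed pockets stop the front.
    """
    cols = np.flatnonzero(mask.any(axis=1 - axis))
    if cols.size == 0:
        return 0.0
    means = np.array(
        [F[..., c][mask[..., c]].mean() if axis == 1 else F[c][mask[c]].mean()
         for c in cols]
    )
    lysed = means < Fstar
    not_lysed = np.flatnonzero(~lysed)
    depth_slices = cols.size if not_lysed.size == 0 else int(not_lysed[0])
    return depth_slices * dx


def mass_fraction(F: np.ndarray, initial_mass: float, mask: np.ndarray) -> float:
    """Remaining fibrin mass over the clot voxels, as a fraction of initial."""
    if initial_mass <= 0:
        raise ValueError("initial mass must be positive")
    return float(F[mask].sum() / initial_mass)


def throughput(u_axial: np.ndarray, dx: float, cols: np.ndarray,
               open_rows: np.ndarray) -> float:
    """Volume flow per unit depth (m^2/s): the axial velocity integrated over
    a transverse section, averaged over the given axial sections."""
    q = u_axial[np.ix_(np.flatnonzero(open_rows), np.asarray(cols))].sum(axis=0) * dx
    return float(q.mean())


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float,
                    direction: str) -> float:
    """First instant y crosses level (linear interpolation); NaN if never."""
    if direction == "down":
        hit = y <= level
    else:
        hit = y >= level
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return float("nan")
    i = int(idx[0])
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def lysis_quartiles(record: SimulationRecord) -> tuple[float, float, float]:
    """Times to remove 25, 50 and 75% of the clot mass (NaN when censored)."""
    if len(record.times) < 2:
        raise ValueError("record needs at least 2 samples")
    t, m = record.times, record.mass_frac
    return tuple(_first_crossing(t, m, level, "down") for level in (0.75, 0.50, 0.25))


def recanalization_onset(record: SimulationRecord,
                         fraction_of_final: float = 0.5) -> float:
    """First instant the throughput exceeds fraction_of_final * final
    throughput (end-of-run value); NaN for a flat zero-flow record."""
    if not 0 < fraction_of_final <= 1:
        raise ValueError("fraction_of_final must lie in (0, 1]")
    q = record.throughput
    q_final = q[-1]
    if q_final <= 0:
        return float("nan")
    return _first_crossing(record.times, q, fraction_of_final * q_final, "up")


@dataclass
class EnsembleSummary:
    """Per-replicate metrics plus aggregate spread statistics."""

    table: pd.DataFrame
    aggregate: dict
    records: list = dc_field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _replicate_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def run_ensemble(config, n_replicates: int, base_seed: int,
                 keep_records: bool = False,
                 onset_fraction: float = 0.5) -> EnsembleSummary:
    """Lyse ``n_replicates`` independently generated clots.

    Replicate seeds are derived deterministically from ``base_seed``; each
    replicate reuses ``config`` with only the clot seed replaced.  Failures
    (e.g. an infeasible disk layout) are recorded per replicate and the
    ensemble continues.  The aggregate reports the mean and the relative
    half-spread ((max-min)/2 / mean) of the half-lysis time and of the
    recanalization-onset time over the replicates that reached them.
    """
    from .transport import run_lysis  # local import to avoid a cycle

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = _replicate_seeds(base_seed, n_replicates)
    rows = []
    records = []
    for i, seed in enumerate(seeds):
        row = {"replicate": i, "seed": seed}
        try:
            rec = run_lysis(config, seed_override=seed)
            tq, th, t3q = lysis_quartiles(rec)
            row.update(
                t_quarter_s=tq, t_half_s=th, t_three_quarter_s=t3q,
                onset_s=recanalization_onset(rec, onset_fraction),
                final_throughput_m2_per_s=float(rec.throughput[-1]),
                termination=rec.meta.get("termination", ""),
                error="",
            )
            if keep_records:
                records.append(rec)
        except Exception as exc:  # noqa: BLE001 - per-replicate isolation
            row.update(
                t_quarter_s=np.nan, t_half_s=np.nan, t_three_quarter_s=np.nan,
                onset_s=np.nan, final_throughput_m2_per_s=np.nan,
                termination="error", error=str(exc),
            )
            if keep_records:
                records.append(None)
        rows.append(row)
    table = pd.DataFrame(rows)

    def _spread(col: str) -> dict:
        vals = table[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        out = {f"n_{col}": int(vals.size)}
        if vals.size:
            out[f"mean_{col}"] = float(vals.mean())
            if vals.mean() > 0:
                out[f"rel_half_spread_{col}"] = float(
                    (vals.max() - vals.min()) / 2.0 / vals.mean()
                )
        return out

    aggregate = {"base_seed": base_seed, "onset_fraction": onset_fraction,
                 "n_replicates": n_replicates}
    for col in ("t_half_s", "onset_s"):
        aggregate.update(_spread(col))
    return EnsembleSummary(table=table, aggregate=aggregate, records=records)
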