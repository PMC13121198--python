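"""Sweep orchestration, outcome classification and suppression statistics.

The study design: fibres of three diameter classes (abundance-weighted) and
two cell types are placed on a 6x6 grid of cross-section positions with
three longitudinal z-shifts; a sinusoidal nerve current is swept over an
amplitude grid (0-400 uA in 40 uA steps) and a frequency grid (10 Hz-10 kHz)
while a soma current step drives a baseline spike train.  The spike count at
the most distal node (node B) per condition feeds:

* outcome classes -- maximal suppression (n_spike <= 1), partial
  suppression, excitation, unaffected;
* the suppression probability SP(x, y, f): the abundance-weighted fraction
  of (diameter, z-shift, amplitude) conditions that are maximally
  suppressed;
* suppression thresholds th_sup(f): the smallest amplitude above which
  maximal suppression persists for every higher tested amplitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .membrane_dynamics import MechanismSet, default_bindings, scale_conductance
from .morphology import (
    DIAMETER_WEIGHTS,
    FIBRE_DIAMETERS_UM,
    FibreSpec,
    build_fibre,
    grid_positions,
    place_fibre,
)
from .simulator import StimulusProtocol, simulate
from .volume_conductor import PotentialMap

__all__ = [
    "SweepConfig",
    "DEFAULT_AMPLITUDES_UA",
    "DEFAULT_FREQUENCIES_HZ",
    "classify_outcome",
    "suppression_probability",
    "sp_grid",
    "find_th_sup",
    "th_sup_table",
    "run_sweep",
    "fin_alone",
    "gna_experiment",
    "refine_th_sup",
]

DEFAULT_AMPLITUDES_UA = tuple(float(a) for a in range(0, 401, 40))
DEFAULT_FREQUENCIES_HZ = (10.0, 25.0, 50.0, 100.0, 250.0, 350.0, 450.0,
                          500.0, 550.0, 650.0, 750.0) + tuple(
    float(f) for f in range(1000, 10001, 1000))

RESULT_COLUMNS = ["cell_type", "d_f", "x", "y", "z_shift", "amplitude_ua",
                  "frequency_hz", "n_spike", "baseline_n_spike", "outcome"]


@dataclass(frozen=True)
class SweepConfig:
    """Parameter grids for one sweep."""

    amplitudes_ua: tuple[float, ...] = DEFAULT_AMPLITUDES_UA
    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    positions_um: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    z_shifts: tuple[float, ...] = (0.0, 0.25, 0.5)
    diameters_um: tuple[float, ...] = FIBRE_DIAMETERS_UM
    cell_types: tuple[str, ...] = ("ON",)
    fine_amplitude_step_ua: float = 5.0
    fine_frequency_step_hz: float = 10.0
    protocol: StimulusProtocol = StimulusProtocol()

    @classmethod
    def full_study(cls) -> "SweepConfig":
        """Both cell types on the whole 36-position quadrant grid."""
        return cls(positions_um=tuple(grid_positions()),
                   cell_types=("ON", "OFF"))

    @property
    def n_conditions(self) -> int:
        return (len(self.cell_types) * len(self.diameters_um)
                * len(self.positions_um) * len(self.z_shifts)
                * len(self.amplitudes_ua) * len(self.frequencies_hz))


def classify_outcome(n_spike: int, baseline_n_spike: int) -> str:
    """Suppression class from distal spike counts.

    maximal: n_spike <= 1 (the single remaining spike is the onset spike
    evoked by the sinusoid itself); excitation: more spikes than baseline;
    partial: reduced but more than one; unaffected: unchanged.
    """
    if n_spike < 0 or baseline_n_spike < 0:
        raise ValueError("spike counts must be >= 0")
    if n_spike <= 1:
        return "maximal"
    if n_spike > baseline_n_spike:
        return "excitation"
    if n_spike < baseline_n_spike:
        return "partial"
    return "unaffected"


# ---------------------------------------------------------------------------
# Suppression probability (weighted over diameter x z-shift x amplitude)
# ---------------------------------------------------------------------------


def suppression_probability(results: pd.DataFrame, x_um: float, y_um: float,
                            f_int_hz: float,
                            weights: Mapping[float, float] | None = None,
                            cell_type: str | None = None,
                            include_zero_amplitude: bool = True) -> float:
    """Weighted probability of maximal suppression at one location/frequency.

    ``SP = sum_{d,z,a} p(d) * [n_spike <= 1] / sum_{d,z,a} p(d)`` with the
    sums over every tested (diameter, z-shift, amplitude) combination.  The
    amplitude grid includes the 0 uA baseline by default, matching how the
    published worked example divides by all 11 amplitudes;
    ``include_zero_amplitude=False`` switches to the FIN-only denominator.
    """
    weights = dict(weights) if weights is not None else dict(DIAMETER_WEIGHTS)
    df = results
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    elif df["cell_type"].nunique() > 1:
        raise ValueError("results contain several cell types; pass cell_type")
    sel = df[(df["x"] == x_um) & (df["y"] == y_um)
             & (df["frequency_hz"] == f_int_hz)]
    if not include_zero_amplitude:
        sel = sel[sel["amplitude_ua"] > 0]

    diameters = sorted(weights)
    z_shifts = sorted(sel["z_shift"].unique())
    amplitudes = sorted(sel["amplitude_ua"].unique())
    missing = []
    for d, z, a in itertools.product(diameters, z_shifts, amplitudes):
        m = ((sel["d_f"] == d) & (sel["z_shift"] == z)
             & (sel["amplitude_ua"] == a))
        if not m.any():
            missing.append((d, z, a))
    if missing or not z_shifts or not amplitudes:
        raise ValueError(
            f"incomplete sweep at (x={x_um}, y={y_um}, f={f_int_hz}); "
            f"missing (d_f, z_shift, amplitude) conditions: {missing[:10]}"
        )

    p = sel["d_f"].map(weights).to_numpy()
    suppressed = (sel["n_spike"].to_numpy() <= 1)
    denom = float(p.sum())
    if denom == 0:
        raise ValueError("zero total probability weight")
    return float((p * suppressed).sum() / denom)


def sp_grid(results: pd.DataFrame, cell_type: str | None = None,
            **kwargs) -> pd.DataFrame:
    """SP for every (x, y, frequency) present in a sweep table."""
    df = results if cell_type is None else results[results["cell_type"] == cell_type]
    rows = []
    combos = df[["x", "y", "frequency_hz"]].drop_duplicates()
    for _, r in combos.iterrows():
        sp = suppression_probability(df, r["x"], r["y"], r["frequency_hz"],
                                     cell_type=cell_type, **kwargs)
        rows.append({"x": r["x"], "y": r["y"], "frequency_hz": r["frequency_hz"],
                     "sp": sp})
    out = pd.DataFrame(rows)
    if len(out) and not ((out["sp"] >= 0) & (out["sp"] <= 1)).all():
        raise AssertionError("SP outside [0, 1]")
    return out


# ---------------------------------------------------------------------------
# Suppression threshold
# ---------------------------------------------------------------------------


def find_th_sup(amplitudes_ua: Sequence[float],
                n_spikes: Sequence[int]) -> float | None:
    """Smallest tested amplitude > 0 beyond which maximal suppression holds
    for every higher tested amplitude; ``None`` when spikes reappear at the
    top of the grid or no amplitude suppresses."""
    a = np.asarray(amplitudes_ua, dtype=float)
    n = np.asarray(n_spikes)
    if len(a) != len(n):
        raise ValueError("amplitude and spike-count series differ in length")
    if np.any(np.diff(a) <= 0):
        raise ValueError("amplitudes must be sorted ascending")
    suppressed = n <= 1
    # suffix[i]: every tested amplitude >= a[i] is suppressive
    suffix = np.logical_and.accumulate(suppressed[::-1])[::-1]
    ok = suffix & (a > 0)
    if not ok.any():
        return None
    return float(a[np.argmax(ok)])


def th_sup_table(results: pd.DataFrame,
                 x_um: float = 0.0, y_um: float = 0.0,
                 z_shift: float = 0.0) -> pd.DataFrame:
    """th_sup per (cell type, diameter, frequency) at one fibre placement."""
    sel = results[(results["x"] == x_um) & (results["y"] == y_um)
                  & (results["z_shift"] == z_shift)]
    rows = []
    for (ct, d, f), g in sel.groupby(["cell_type", "d_f", "frequency_hz"]):
        g = g.sort_values("amplitude_ua")
        th = find_th_sup(g["amplitude_ua"].to_numpy(), g["n_spike"].to_numpy())
        rows.append({"cell_type": ct, "d_f": d, "frequency_hz": f,
                     "th_sup_ua": th})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sweep execution
# ---------------------------------------------------------------------------


def run_sweep(config: SweepConfig, field_map: PotentialMap,
              bindings: Mapping[str, MechanismSet] | None = None,
              cache: dict | None = None,
              progress: Callable[[str], None] | None = None) -> pd.DataFrame:
    """Simulate every configured condition; long-form table, one row each.

    Deterministic and resumable: ``cache`` maps a condition key to its spike
    count and is filled as conditions complete, so a partially filled cache
    resumes where it stopped.  The 0 uA baseline is simulated once per
    (cell type, diameter) -- without electrode current the field does not
    enter -- and replicated across positions, z-shifts and frequencies.
    """
    bindings = dict(bindings) if bindings is not None else default_bindings()
    cache = cache if cache is not None else {}
    proto = config.protocol
    rows = []

    baselines: dict[tuple, int] = {}
    for ct, d in itertools.product(config.cell_types, config.diameters_um):
        key = ("baseline", ct, d, proto.i_stim_na)
        if key not in cache:
            model = build_fibre(ct, d)
            res = simulate(model, bindings, None,
                           replace(proto, fin_amplitude_ua=0.0,
                                   fin_frequency_hz=0.0))
            cache[key] = res.n_spike
        baselines[(ct, d)] = cache[key]

    for ct, d, (x, y), z in itertools.product(
            config.cell_types, config.diameters_um, config.positions_um,
            config.z_shifts):
        base_n = baselines[(ct, d)]
        model = place_fibre(build_fibre(ct, d),
                            FibreSpec(ct, d, x, y, z))
        for f in config.frequencies_hz:
            for a in config.amplitudes_ua:
                if a == 0:
                    n = base_n
                else:
                    key = (ct, d, x, y, z, a, f, proto.i_stim_na)
                    if key not in cache:
                        p = replace(proto, fin_amplitude_ua=a,
                                    fin_frequency_hz=f)
                        cache[key] = simulate(model, bindings, field_map, p).n_spike
                    n = cache[key]
                rows.append((ct, d, x, y, z, a, f, n, base_n,
                             classify_outcome(n, base_n)))
            if progress is not None:
                progress(f"{ct} d={d} ({x},{y}) z={z} f={f}")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def fin_alone(config: SweepConfig, field_map: PotentialMap,
              bindings: Mapping[str, MechanismSet] | None = None,
              **kwargs) -> pd.DataFrame:
    """The sweep with the soma drive turned off (sinusoid only)."""
    cfg = replace(config, protocol=replace(config.protocol, i_stim_na=0.0))
    return run_sweep(cfg, field_map, bindings, **kwargs)


def gna_experiment(config: SweepConfig, field_map: PotentialMap,
                   factors: Sequence[float],
                   region: str = "AIS", channel: str = "na_rgc",
                   bindings: Mapping[str, MechanismSet] | None = None,
                   x_um: float = 0.0, y_um: float = 0.0,
                   z_shift: float = 0.0) -> pd.DataFrame:
    """Suppression thresholds after scaling one maximal conductance.

    Reproduces the perturbation study in which the AIS sodium density of the
    OFF fibre is raised (factor 1.8) and th_sup re-measured per frequency.
    """
    base = dict(bindings) if bindings is not None else default_bindings()
    out = []
    for factor in factors:
        if factor <= 0:
            raise ValueError("conductance factors must be > 0")
        b = scale_conductance(base, region, channel, factor)
        res = run_sweep(config, field_map, b)
        tab = th_sup_table(res, x_um, y_um, z_shift)
        tab.insert(0, "factor", factor)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def refine_th_sup(coarse_th_ua: float, cell_type: str, d_f: float,
                  frequency_hz: float, field_map: PotentialMap,
                  bindings: Mapping[str, MechanismSet] | None = None,
                  config: SweepConfig | None = None,
                  x_um: float = 0.0, y_um: float = 0.0,
                  z_shift: float = 0.0) -> float | None:
    """Fine amplitude scan (5 uA steps by default) around a coarse threshold.

    Simulates amplitudes from one coarse step below ``coarse_th_ua`` up to
    the top of the coarse grid and re-applies the threshold rule on the
    refined series.
    """
    config = config or SweepConfig()
    bindings = dict(bindings) if bindings is not None else default_bindings()
    coarse = np.asarray(sorted(config.amplitudes_ua))
    step = config.fine_amplitude_step_ua
    below = coarse[coarse < coarse_th_ua]
    start = below[-1] if len(below) else 0.0
    fine = np.arange(start + step, coarse_th_ua + step / 2, step)
    amps = np.unique(np.concatenate([fine, coarse[coarse >= coarse_th_ua]]))

    model = place_fibre(build_fibre(cell_type, d_f),
                        FibreSpec(cell_type, d_f, x_um, y_um, z_shift))
    n = []
    for a in amps:
        p = replace(config.protocol, fin_amplitude_ua=float(a),
                    fin_frequency_hz=frequency_hz)
        n.append(simulate(model, bindings, field_map, p).n_spike)
    return find_th_sup(amps, n)
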