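"""Flow-cytometry quantification of CRISPRa reporter activation.

Implements the gating and arithmetic used to quantify conditional
activation from two-channel fluorescence data: scatter gates select
intact single cells, an iBlue (transfection-marker) threshold is
calibrated on an untransfected control so that only 0.1% of control
cells fall above it, an ECFP (reporter) threshold is calibrated the same
way on a non-targeting reporter control, and the displayed quantity is

    percent activated transfected cells
        = count(ECFP+ & iBlue+) / [count(ECFP+ & iBlue+) + count(ECFP- & iBlue+)]

Synthetic event tables stand in for acquisitions: events are drawn from
log-normal mixtures of three archetypes (untransfected, transfected-OFF,
transfected-ON) in the five channels FSC-A, SSC-A, SSC-H, iBlue, ECFP.
Real FCS ingestion can be hooked in by building an EventTable from any
parser's DataFrame output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CHANNELS = ("FSC-A", "SSC-A", "SSC-H", "iBlue", "ECFP")
DEFAULT_N_EVENTS = 100_000


class CytometryError(ValueError):
    """Raised for invalid event tables, gates or population specs."""


@dataclass(frozen=True)
class EventTable:
    """Per-event channel values (arbitrary fluorescence units, >= 0)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise CytometryError(f"event table missing channels {missing}")
        values = self.data[list(CHANNELS)].to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise CytometryError("event values must be finite and >= 0")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()


@dataclass(frozen=True)
class PopulationSpec:
    """Log-normal archetype for one event population.

    ``*_mu``/``*_sigma`` are the location/scale of the natural-log normal
    per channel. ``doublet_fraction`` of events get a depressed SSC-H/SSC-A
    ratio so the singlet gate has something to remove.
    """

    name: str
    weight: float
    fsc_mu: float = 11.0
    fsc_sigma: float = 0.20
    ssc_mu: float = 10.5
    ssc_sigma: float = 0.25
    iblue_mu: float = 4.0
    iblue_sigma: float = 0.80
    ecfp_mu: float = 4.0
    ecfp_sigma: float = 0.80
    doublet_fraction: float = 0.05


def archetypes(
    on_fraction: float = 0.0,
    transfection_rate: float = 0.60,
    iblue_pos_mu: float = 8.5,
    ecfp_pos_mu: float = 8.5,
) -> Tuple[PopulationSpec, ...]:
    """Standard three-population mixture for a transfection condition.

    ``on_fraction`` is the planted fraction of transfected cells with an
    active reporter; ``transfection_rate`` the fraction of cells carrying
    the iBlue marker.
    """
    if not 0.0 <= on_fraction <= 1.0:
        raise CytometryError("on_fraction must be in [0, 1]")
    untrans = 1.0 - transfection_rate
    return (
        PopulationSpec("untransfected", untrans),
        PopulationSpec(
            "transfected_off",
            transfection_rate * (1.0 - on_fraction),
            iblue_mu=iblue_pos_mu,
        ),
        PopulationSpec(
            "transfected_on",
            transfection_rate * on_fraction,
            iblue_mu=iblue_pos_mu,
            ecfp_mu=ecfp_pos_mu,
        ),
    )


def simulate_events(
    populations: Sequence[PopulationSpec],
    n: int = DEFAULT_N_EVENTS,
    seed: int | np.random.Generator = 0,
) -> EventTable:
    """Seeded mixture sample of ``n`` events across the populations."""
    weights = np.array([p.weight for p in populations], dtype=float)
    if (weights < 0).any() or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise CytometryError(
            f"population weights must be >= 0 and sum to 1, got {weights.tolist()}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    frames = []
    for pop, m in zip(populations, counts):
        if m == 0:
            continue
        fsc = rng.lognormal(pop.fsc_mu, pop.fsc_sigma, m)
        ssc = rng.lognormal(pop.ssc_mu, pop.ssc_sigma, m)
        ratio = np.exp(rng.normal(0.0, 0.03, m))
        doublet = rng.random(m) < pop.doublet_fraction
        ratio[doublet] *= 0.55
        frames.append(
            pd.DataFrame(
                {
                    "FSC-A": fsc,
                    "SSC-A": ssc,
                    "SSC-H": ssc * ratio,
                    "iBlue": rng.lognormal(pop.iblue_mu, pop.iblue_sigma, m),
                    "ECFP": rng.lognormal(pop.ecfp_mu, pop.ecfp_sigma, m),
                    "population": pop.name,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    data = data.iloc[rng.permutation(len(data))].reset_index(drop=True)
    return EventTable(data)


@dataclass(frozen=True)
class GateSet:
    """Scatter regions plus calibrated fluorescence thresholds."""

    cell_gate_fsc: Tuple[float, float] = (25_000.0, 150_000.0)
    cell_gate_ssc: Tuple[float, float] = (12_000.0, 120_000.0)
    singlet_ratio_min: float = 0.75  # SSC-H / SSC-A floor
    iblue_threshold: Optional[float] = None
    ecfp_threshold: Optional[float] = None
    calibration_fraction: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_fraction <= 0.05:
            raise CytometryError("calibration_fraction must be in (0, 0.05]")


def scatter_mask(events: EventTable, gates: GateSet) -> np.ndarray:
    """Boolean mask of events inside the cell and singlet gates."""
    fsc, ssc, ssch = events["FSC-A"], events["SSC-A"], events["SSC-H"]
    cells = (
        (fsc >= gates.cell_gate_fsc[0]) & (fsc <= gates.cell_gate_fsc[1])
        & (ssc >= gates.cell_gate_ssc[0]) & (ssc <= gates.cell_gate_ssc[1])
    )
    singlets = ssch / ssc >= gates.singlet_ratio_min
    return cells & singlets


def calibrate_gate(
    control: EventTable,
    channel: str,
    fraction: float = 0.001,
) -> float:
    """Threshold above which ~``fraction`` of control events lie.

    The threshold is the empirical (1 - fraction) quantile of the raw
    control channel: the value such that round(n * fraction) control
    events sit strictly above it. The realised fraction is within 1/n of
    the request (ties aside).
    """
    if channel not in CHANNELS:
        raise CytometryError(f"unknown channel {channel!r}")
    values = control[channel]
    n = len(values)
    if n * fraction < 1:
        raise CytometryError(
            f"control too small: n*fraction = {n * fraction:.3f} < 1 event"
        )
    k = int(round(n * fraction))
    return float(np.sort(values)[::-1][k])


def calibrate_gateset(
    untransfected: EventTable,
    reporter_control: EventTable,
    fraction: float = 0.001,
    gates: Optional[GateSet] = None,
) -> GateSet:
    """Calibrate both fluorescence thresholds from their control tables.

    iBlue on the untransfected control; ECFP on the reporter control
    (non-complementary sgRNA, so reporter-positive cells are spurious).
    """
    gates = gates or GateSet(calibration_fraction=fraction)
    return replace(
        gates,
        iblue_threshold=calibrate_gate(untransfected, "iBlue", fraction),
        ecfp_threshold=calibrate_gate(reporter_control, "ECFP", fraction),
        calibration_fraction=fraction,
    )


@dataclass(frozen=True)
class ActivationResult:
    fraction: Optional[float]   # None when no transfected events survive
    n_double_positive: int      # ECFP+ & iBlue+
    n_iblue_only: int           # ECFP- & iBlue+
    n_gated: int

    @property
    def percent(self) -> Optional[float]:
        return None if self.fraction is None else 100.0 * self.fraction


def percent_activated(events: EventTable, gates: GateSet) -> ActivationResult:
    """Fraction of transfected (iBlue+) cells with an active reporter.

    Gate order: cells -> singlets -> fluorescence thresholds. Returns a
    missing (None) fraction, not zero, when no iBlue+ events survive.
    """
    if gates.iblue_threshold is None or gates.ecfp_threshold is None:
        raise CytometryError("gates must be calibrated before quantification")
    mask = scatter_mask(events, gates)
    iblue_pos = events["iBlue"][mask] > gates.iblue_threshold
    ecfp_pos = events["ECFP"][mask] > gates.ecfp_threshold
    a = int((iblue_pos & ecfp_pos).sum())
    b = int((iblue_pos & ~ecfp_pos).sum())
    fraction = a / (a + b) if a + b > 0 else None
    return ActivationResult(
        fraction=fraction,
        n_double_positive=a,
        n_iblue_only=b,
        n_gated=int(mask.sum()),
    )


def fold_turn_on(on: float, off: float, off_floor: Optional[float] = None) -> float:
    """ON/OFF activation ratio.

    When ``off`` is zero the ratio is unbounded; pass ``off_floor`` to
    substitute a detection floor, otherwise +inf is returned.
    """
    if off < 0 or on < 0:
        raise CytometryError("fractions must be >= 0")
    if off == 0:
        if off_floor:
            return on / off_floor
        return math.inf
    return on / off


def replicate_summary(values: Sequence[float]) -> Dict[str, float]:
    """Mean / SD summary for replicate activation values (reporting only)."""
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
    }


def unpaired_ttest(a: Sequence[float], b: Sequence[float]) -> Dict[str, float]:
    """Unpaired two-sample t-test (thin wrapper; reporting only)."""
    from scipy import stats

    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return {"t": float(t), "p": float(p)}
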