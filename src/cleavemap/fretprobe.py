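"""Fluorometric verification: probe design and cleavage-curve classification.

A chimeric probe carries the candidate RNA cleavage sequence between two
5-base deoxyadenosine arms, with a 5' fluorophore (6-FAM) and a 3' quencher
(BHQ-1).  Cleaving the RNA insert separates fluorophore from quencher, so
fluorescence rises with pseudo-first-order kinetics

    F(t) = F0 + A * (1 - exp(-k t)),

which the simulator emits (plus Gaussian noise) and the classifier fits.
A probe is called cleaved when its baseline-subtracted endpoint rise exceeds
``fold_threshold`` times that of its no-enzyme control; the baseline is the
control's initial intensity, making the verdict invariant to affine
rescaling of the recorded intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import curve_fit

from .motifcall import Motif

logger = logging.getLogger("cleavemap")

_VARIANT_ORDER = "UACG"  # order in which substitution variants are enumerated


@dataclass(frozen=True)
class Probe:
    """A chimeric DNA/RNA fluorometric probe.

    ``full_sequence`` writes the deoxyadenosine arms as lowercase 'a' to
    distinguish DNA from the RNA insert.
    """

    name: str
    insert: str
    full_sequence: str
    label_5p: str = "6-FAM"
    label_3p: str = "BHQ-1"


@dataclass(frozen=True)
class FluorCurve:
    probe_name: str
    times: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # arbitrary units
    replicate: int = 1

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensity):
            raise ValueError("times and intensity must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class Verdict:
    probe_name: str
    cleaved: bool
    fold_change: float
    k_estimate: float | None  # per minute; None when the fit failed
    flagged: bool = False


def _make_probe(insert: str) -> Probe:
    return Probe(name=f"DR-{insert}", insert=insert, full_sequence="aaaaa" + insert + "aaaaa")


def design_probes(motif: Motif) -> list[Probe]:
    """The consensus probe plus, per low-consistency position, its three
    single-base substitution variants; duplicates are never emitted."""
    cons = motif.consensus
    bad = set(cons) - set("ACGU")
    if bad:
        raise ValueError(f"consensus contains non-RNA characters {sorted(bad)}")
    inserts = [cons]
    for pos in motif.low_consistency_positions:
        original = cons[pos - 1]
        for base in _VARIANT_ORDER:
            if base == original:
                continue
            variant = cons[: pos - 1] + base + cons[pos:]
            if variant not in inserts:
                inserts.append(variant)
    return [_make_probe(s) for s in inserts]


def simulate_fret(
    probe: Probe,
    cleavage_rate: float,
    t_end: float = 60.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    baseline: float = 1.0,
    amplitude: float = 9.0,
    seed: int = 0,
    replicate: int = 1,
) -> FluorCurve:
    """One fluorescence time course under first-order cleavage kinetics."""
    if cleavage_rate < 0:
        raise ValueError("cleavage_rate must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2, dt)
    mean = baseline + amplitude * (1.0 - np.exp(-cleavage_rate * t))
    noise = rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else 0.0
    return FluorCurve(probe.name, t, mean + noise, replicate=replicate)


def _group(curves: Iterable[FluorCurve]) -> dict[str, list[FluorCurve]]:
    by: dict[str, list[FluorCurve]] = {}
    for c in curves:
        by.setdefault(c.probe_name, []).append(c)
    return by


def _mean_curve(group: list[FluorCurve]) -> tuple[np.ndarray, np.ndarray]:
    t0 = group[0].times
    for c in group[1:]:
        if len(c.times) != len(t0) or np.any(c.times != t0):
            raise ValueError(f"replicates of {c.probe_name!r} are on different time grids")
    return t0, np.mean([c.intensity for c in group], axis=0)


def _fit_k(t: np.ndarray, y: np.ndarray) -> float | None:
    def model(t, f0, a, k):
        return f0 + a * (1.0 - np.exp(-k * t))

    span = max(float(y.max() - y.min()), 1e-12)
    try:
        popt, _ = curve_fit(
            model, t, y,
            p0=(float(y[0]), span, 0.1),
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return None
    return float(popt[2])


def classify_curves(
    curves: list[FluorCurve],
    control_curves: list[FluorCurve],
    fold_threshold: float = 2.0,
) -> list[Verdict]:
    """Per-probe cleaved / not-cleaved verdicts with estimated rate k.

    Replicates are averaged (triplicate-style), k is fit by least squares
    against the exponential model, and the verdict compares baseline-
    subtracted endpoint rises: cleaved iff
    (sample_end - baseline) >= fold_threshold * denom, where the baseline is
    the control's initial mean intensity and denom is the larger of the
    control's own endpoint rise and its estimated noise scale (so a flat but
    noisy control cannot produce a spuriously large fold change).  Both
    quantities scale with the recording gain and are offset-free, keeping the
    verdict invariant to affine rescaling applied to sample and control alike.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    samples = _group(curves)
    controls = _group(control_curves)
    verdicts: list[Verdict] = []
    for name, group in samples.items():
        if name not in controls:
            raise ValueError(f"no control (no-enzyme) curve for probe {name!r}")
        t, y = _mean_curve(group)
        tc, yc = _mean_curve(controls[name])
        base = float(yc[0])
        sample_rise = float(y[-1]) - base
        control_rise = float(yc[-1]) - base
        # noise scale from control first differences (trend-insensitive)
        sigma = float(np.std(np.diff(yc)) / np.sqrt(2.0)) if len(yc) > 1 else 0.0
        denom = max(control_rise, sigma)
        if denom > 0:
            fold = sample_rise / denom
        else:
            fold = np.inf if sample_rise > 0 else 0.0
        k = _fit_k(t, y)
        flagged = k is None
        if flagged:
            logger.warning("probe %s: kinetic fit failed; k not estimable", name)
        verdicts.append(
            Verdict(
                probe_name=name,
                cleaved=bool(fold >= fold_threshold),
                fold_change=float(fold),
                k_estimate=k,
                flagged=flagged,
            )
        )
    return verdicts
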