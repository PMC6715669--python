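"""Seeded simulators for intact spectra, MS/MS ladders, calibration series
and two-group cohorts.

A single global seed fans out to per-component substreams (stable spawn
keys), so adding a simulation stage never perturbs the draws of earlier
stages.  Every output is deterministic for a fixed seed.

Per-sample methylation fractions are drawn from Gaussians truncated to
[0, 1] — a bounded convenience distribution, not a claim about biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect_quant import predict_species
from .fragmentation import DEFAULT_SERIES, fragment_ladder
from .rna_mass import Oligo
from .spectra_io import Peak, PeakList

__all__ = [
    "SimulationConfig",
    "simulate_intact",
    "simulate_msms",
    "simulate_calibration_series",
    "simulate_cohort",
]

# stable substream ids — never renumber
_STREAM_INTACT = 1
_STREAM_MSMS = 2
_STREAM_CALIBRATION = 3
_STREAM_COHORT = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=key))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for spectrum simulation.

    ``fractions`` maps methyl count k to its molar fraction (must sum to 1).
    ``response_factor`` scales the ionization efficiency of methylated
    (k >= 1) species relative to the unmethylated form.
    """

    oligo: Oligo
    fractions: Dict[int, float] = field(default_factory=lambda: {0: 1.0})
    mass_error_ppm: float = 0.0
    intensity_cv: float = 0.0
    adduct_rates: Dict[str, float] = field(default_factory=dict)
    baseline_noise: float = 0.0
    coverage: float = 1.0
    response_factor: float = 1.0
    base_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(k < 0 or f < 0 for k, f in self.fractions.items()):
            raise ValueError("fractions require k >= 0 and values >= 0")
        for name, rate in self.adduct_rates.items():
            if name not in ("Na", "K") or not 0.0 <= rate <= 1.0:
                raise ValueError(f"invalid adduct rate {name}={rate}")
        if sum(self.adduct_rates.values()) > 1.0:
            raise ValueError("adduct rates must sum to <= 1")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.mass_error_ppm < 0 or self.intensity_cv < 0 or self.response_factor <= 0:
            raise ValueError("noise parameters must be non-negative; response factor positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _jitter_ppm(rng: np.random.Generator, mz: np.ndarray, ppm_sd: float) -> np.ndarray:
    if ppm_sd <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sd * 1e-6, size=mz.shape))


def simulate_intact(config: SimulationConfig) -> PeakList:
    """One peak per (methyl count, adduct) species, noise per the config."""
    rng = _rng(config.seed, _STREAM_INTACT)
    kmax = max(config.fractions)
    adducts = [a for a, r in sorted(config.adduct_rates.items()) if r > 0]
    preds = predict_species(config.oligo, kmax, adducts)
    base_rate = 1.0 - sum(config.adduct_rates.values())

    mzs, intensities = [], []
    for pred in preds:
        frac = config.fractions.get(pred.k, 0.0)
        if frac <= 0:
            continue
        rate = base_rate if pred.adduct == "none" else config.adduct_rates[pred.adduct]
        if rate <= 0:
            continue
        response = config.response_factor if pred.k >= 1 else 1.0
        mzs.append(pred.mz)
        intensities.append(config.base_intensity * frac * rate * response)
    mzs = np.asarray(mzs)
    intensities = np.asarray(intensities)
    intensities = intensities * _lognormal_factor(rng, config.intensity_cv, intensities.size)
    mzs = _jitter_ppm(rng, mzs, config.mass_error_ppm)

    snrs: List[Optional[float]] = [None] * len(mzs)
    if config.baseline_noise > 0:
        snrs = list(intensities / config.baseline_noise)
    order = np.argsort(mzs)
    peaks = tuple(
        Peak(float(mzs[i]), float(intensities[i]), snrs[i]) for i in order
    )
    return PeakList(peaks, provenance=f"simulate_intact(seed={config.seed})")


def simulate_msms(
    config: SimulationConfig, series: Sequence[str] = DEFAULT_SERIES
) -> PeakList:
    """Fragment ladder of the config's oligo with probabilistic coverage.

    At coverage 1 and zero noise the output peak set equals the theoretical
    ladder exactly.
    """
    rng = _rng(config.seed, _STREAM_MSMS)
    ions = fragment_ladder(config.oligo, series=series)
    keep = rng.random(len(ions)) < config.coverage if config.coverage < 1.0 else np.ones(
        len(ions), dtype=bool
    )
    mzs = np.array([ion.mz for ion in ions])[keep]
    if mzs.size == 0:
        return PeakList((), ms_level=2, provenance=f"simulate_msms(seed={config.seed})")
    intensities = config.base_intensity * _lognormal_factor(
        rng, config.intensity_cv, mzs.size
    )
    mzs = _jitter_ppm(rng, mzs, config.mass_error_ppm)
    order = np.argsort(mzs)
    mzs, intensities = mzs[order], intensities[order]
    # theoretical ions can coincide (e.g. symmetric sequences): merge
    out_mz: List[float] = []
    out_int: List[float] = []
    for m, i in zip(mzs, intensities):
        if out_mz and m - out_mz[-1] < 1e-9:
            out_int[-1] += i
        else:
            out_mz.append(float(m))
            out_int.append(float(i))
    return PeakList(
        tuple(Peak(m, i) for m, i in zip(out_mz, out_int)),
        ms_level=2,
        provenance=f"simulate_msms(seed={config.seed})",
    )


def simulate_calibration_series(
    fractions: Sequence[float],
    replicates: int,
    config: SimulationConfig,
) -> List[Tuple[float, int, PeakList]]:
    """Standard-mixture dilution series: one intact spectrum per
    (known fraction, replicate), the mixture holding fraction f of the
    singly methylated and 1-f of the unmethylated species."""
    if not fractions:
        raise ValueError("fraction list is empty")
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out = []
    for li, f in enumerate(fractions):
        for rep in range(replicates):
            sub = _rng(config.seed, _STREAM_CALIBRATION, li, rep)
            level_seed = int(sub.integers(0, 2**31 - 1))
            cfg = replace(config, fractions={0: 1.0 - f, 1: f}, seed=level_seed)
            out.append((float(f), rep, simulate_intact(cfg)))
    return out


def simulate_cohort(
    n_case: int,
    n_control: int,
    case_fraction_mean: float,
    control_fraction_mean: float,
    sd: float,
    paired: bool = False,
    seed: int = 0,
    pair_correlation: float = 0.5,
    include_markers: bool = False,
    marker_log_effect: float = 1.0,
) -> pd.DataFrame:
    """Two-group cohort of per-sample methylation fractions.

    Fractions are Gaussian truncated to [0, 1].  In paired mode
    (``n_case == n_control`` required) case/control pairs share a latent
    Gaussian factor with correlation ``pair_correlation``.  Optional
    CA19-9 / CEA marker columns are lognormal with a group difference of
    ``marker_log_effect`` on the log scale.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("both groups must be non-empty")
    if paired and n_case != n_control:
        raise ValueError("paired mode requires equal group sizes")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = _rng(seed, _STREAM_COHORT)

    def truncated(mean: float, noise: np.ndarray) -> np.ndarray:
        return np.clip(mean + sd * noise, 0.0, 1.0)

    rows: List[dict] = []
    if paired:
        latent = rng.normal(size=n_case)
        e_case = rng.normal(size=n_case)
        e_ctrl = rng.normal(size=n_case)
        rho = pair_correlation
        mix = np.sqrt(max(1.0 - rho * rho, 0.0))
        case_f = truncated(case_fraction_mean, rho * latent + mix * e_case)
        ctrl_f = truncated(control_fraction_mean, rho * latent + mix * e_ctrl)
        for i in range(n_case):
            rows.append(
                {"sample_id": f"case_{i+1}", "group": "case",
                 "pair_id": f"pair_{i+1}", "fraction": case_f[i]}
            )
            rows.append(
                {"sample_id": f"control_{i+1}", "group": "control",
                 "pair_id": f"pair_{i+1}", "fraction": ctrl_f[i]}
            )
    else:
        case_f = truncated(case_fraction_mean, rng.normal(size=n_case))
        ctrl_f = truncated(control_fraction_mean, rng.normal(size=n_control))
        for i in range(n_case):
            rows.append({"sample_id": f"case_{i+1}", "group": "case",
                         "pair_id": "", "fraction": case_f[i]})
        for i in range(n_control):
            rows.append({"sample_id": f"control_{i+1}", "group": "control",
                         "pair_id": "", "fraction": ctrl_f[i]})

    table = pd.DataFrame(rows)
    if include_markers:
        n = len(table)
        is_case = (table["group"] == "case").to_numpy()
        for marker, base_mu in (("ca19_9", 3.0), ("cea", 1.0)):
            mu = base_mu + marker_log_effect * is_case
            table[marker] = np.exp(rng.normal(mu, 1.0, size=n))
    return table
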