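"""Synthetic-data generators for every pipeline input, with ground truth.

The flux generator emulates the three-phase kinetic structure of the
tamoxifen-inducible reconstitution assay: a baseline window, addition of
4-OHT releasing the SLP65 signal transducer (any BCR with autonomous
activity now fluxes calcium), and finally anti-Ig crosslinking driving the
maximal response.  Cells are a mixture of transduced / untransduced and, among
transduced cells, autonomous responders, crosslink-only responders and a
small totally-unresponsive remainder.  Each acquired event is one cell
sampled at a uniform random time (constant flow rate); channel intensities
carry independent multiplicative lognormal noise.

The autonomous response is modeled as a sustained step: after 4-OHT plus a
fixed lag, a responder's true 405/485 ratio (SIR) jumps from the baseline
``mu0`` to ``a_aut * mu0``, and after crosslinking every non-unresponsive
transduced cell jumps to ``a_max * mu0``.  Transient decay kinetics are not
modeled.  Untransduced (GFP-negative) cells carry no BCR and never respond.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FluxProtocol, FluxSeries, PhosphoSample

__all__ = [
    "FluxSimParams",
    "GroundTruth",
    "CaseSpec",
    "GrowthSeries",
    "simulate_flux_experiment",
    "simulate_cohort",
    "simulate_phospho",
    "simulate_dose_response",
    "simulate_growth",
    "simulate_aberrations",
    "DEFAULT_CONCENTRATIONS_UM",
]

# intensity scales (arbitrary fluorescence units)
_CH485_BASE = 1000.0
_GFP_POS_MEDIAN = 5000.0
_GFP_NEG_MEDIAN = 50.0
_DTOMATO_MEDIAN = 2000.0
_VIABILITY_LIVE = 100.0
_VIABILITY_DEAD = 10000.0
_MARKER_CV = 0.5


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _lognormal_median(rng: np.random.Generator, median: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, median)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


@dataclass(frozen=True)
class FluxSimParams:
    """Generator settings for one flux acquisition.

    Defaults state the emulated world once: 5,000 acquired cells per sample
    (acquisition rates are instrument-dependent and not published for this
    assay), 60% transduction efficiency, a modest 10% channel noise CV for a
    ratiometric dye, baseline SIR 1.0, a 3-fold maximal crosslink response,
    a 2-fold autonomous response, 5% of transduced cells totally
    unresponsive, and a 10-s response lag after stimulus addition.
    """

    n_cells: int = 5000
    event_rate: float | None = None  # events/s; derived from n_cells if None
    transduced_fraction: float = 0.6
    p_aut: float = 0.5  # autonomous responders, among transduced cells
    u_true: float = 0.05  # totally unresponsive, among transduced cells
    mu0: float = 1.0  # baseline SIR
    a_aut: float = 2.0  # autonomous fold-change over baseline
    a_max: float = 3.0  # crosslink fold-change over baseline
    noise_cv: float = 0.1
    response_lag_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be a positive count, got {self.n_cells}")
        if self.event_rate is not None and self.event_rate <= 0:
            raise ValueError(f"event_rate must be > 0 events/s, got {self.event_rate}")
        for name in ("transduced_fraction", "p_aut", "u_true"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_aut + self.u_true > 1 + 1e-12:
            raise ValueError(
                f"p_aut + u_true must be <= 1 (a cell cannot both respond autonomously "
                f"and be totally unresponsive), got {self.p_aut} + {self.u_true}"
            )
        if self.mu0 <= 0:
            raise ValueError(f"mu0 must be a positive ratio, got {self.mu0}")
        for name in ("a_aut", "a_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a fold-change >= 1, got {getattr(self, name)}")
        if self.a_max < self.a_aut:
            raise ValueError(
                f"a_max must be >= a_aut (autonomous response weaker than maximal), "
                f"got a_max={self.a_max} < a_aut={self.a_aut}"
            )
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.response_lag_s < 0:
            raise ValueError(f"response_lag_s must be >= 0 s, got {self.response_lag_s}")


@dataclass
class GroundTruth:
    """Per-cell and per-case truth labels accompanying a simulated sample."""

    cells: pd.DataFrame  # columns: transduced, autonomous_responder, crosslink_responder
    signaling: bool | None = None  # per-case label, set by simulate_cohort
    isotype: str | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def simulate_flux_experiment(
    params: FluxSimParams, protocol: FluxProtocol | None = None
) -> tuple[FluxSeries, GroundTruth]:
    """Simulate one flux acquisition; identical (params, protocol) reproduce bytes."""
    protocol = protocol or FluxProtocol()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_cells

    time_s = np.sort(rng.uniform(0.0, protocol.crosslink_end_s, size=n))
    transduced = rng.random(n) < params.transduced_fraction
    u = rng.random(n)
    autonomous = transduced & (u < params.p_aut)
    unresponsive = transduced & (u >= params.p_aut) & (u < params.p_aut + params.u_true)
    crosslink_resp = transduced & ~unresponsive

    sir_true = np.full(n, params.mu0)
    t_aut_on = protocol.t_4oht_s + params.response_lag_s
    t_xl_on = protocol.autonomous_end_s + params.response_lag_s
    sir_true[autonomous & (time_s >= t_aut_on)] = params.mu0 * params.a_aut
    sir_true[crosslink_resp & (time_s >= t_xl_on)] = params.mu0 * params.a_max

    ch485 = _CH485_BASE * _lognormal_factor(rng, params.noise_cv, n)
    ch405 = sir_true * _CH485_BASE * _lognormal_factor(rng, params.noise_cv, n)
    gfp = np.where(
        transduced,
        _lognormal_median(rng, _GFP_POS_MEDIAN, _MARKER_CV, n),
        _lognormal_median(rng, _GFP_NEG_MEDIAN, _MARKER_CV, n),
    )
    dtomato = _lognormal_median(rng, _DTOMATO_MEDIAN, _MARKER_CV, n)
    viability = _lognormal_median(rng, _VIABILITY_LIVE, _MARKER_CV, n)

    events = pd.DataFrame(
        {
            "time_s": time_s,
            "ch405": ch405,
            "ch485": ch485,
            "gfp": gfp,
            "dtomato": dtomato,
            "viability": viability,
        }
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "transduced": transduced,
                "autonomous_responder": autonomous,
                "crosslink_responder": crosslink_resp,
            }
        )
    )
    return FluxSeries(events=events, sample_id=f"sim-{params.seed}"), truth


@dataclass(frozen=True)
class CaseSpec:
    """One cohort member: identity, isotype, truth label, generator settings."""

    case_id: str
    isotype: str
    signaling: bool
    params: FluxSimParams


def _substream_seed(seed: int, case_index: int, replicate: int) -> int:
    """Mix the case index and replicate into the global seed, deterministically."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(case_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    case_specs: Sequence[CaseSpec],
    protocol: FluxProtocol | None = None,
    seed: int = 0,
    n_replicates: int = 2,
) -> list[tuple[list[FluxSeries], GroundTruth]]:
    """Simulate a cohort; each case yields ``n_replicates`` series with
    independent noise (derived per-case substreams of the global seed) and a
    shared per-case ground truth (labels of the first replicate)."""
    if not case_specs:
        raise ValueError("case_specs must contain at least one case")
    ids = [c.case_id for c in case_specs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate case_id(s): {sorted(dupes)}")
    protocol = protocol or FluxProtocol()
    out = []
    for i, spec in enumerate(case_specs):
        reps = []
        truth: GroundTruth | None = None
        for r in range(n_replicates):
            p = dataclasses.replace(spec.params, seed=_substream_seed(seed, i, r))
            series, t = simulate_flux_experiment(p, protocol)
            series.sample_id = spec.case_id
            series.replicate_index = r
            reps.append(series)
            if truth is None:
                truth = t
        assert truth is not None
        truth.signaling = spec.signaling
        truth.isotype = spec.isotype
        out.append((reps, truth))
    return out


# ---------------------------------------------------------------------------
# Phospho-flow
# ---------------------------------------------------------------------------


def simulate_phospho(
    n_cells: int,
    mfi_unstim: float,
    mfi_stim: float,
    noise_cv: float = 0.3,
    live_fraction: float = 0.95,
    seed: int = 0,
    target: str = "pBLNK",
) -> tuple[PhosphoSample, PhosphoSample]:
    """Paired unstimulated/crosslinked samples, lognormal around target MFIs.

    The lognormal is parameterized so its *arithmetic* mean equals the target
    (MFI is an arithmetic mean); dead cells are flagged in the viability
    channel for exclusion at gating.
    """
    if mfi_unstim <= 0 or mfi_stim <= 0:
        raise ValueError(f"target MFIs must be > 0, got ({mfi_unstim}, {mfi_stim})")
    if not (0 < live_fraction <= 1):
        raise ValueError(f"live_fraction must be in (0, 1], got {live_fraction}")
    if n_cells <= 0:
        raise ValueError(f"n_cells must be positive, got {n_cells}")
    rng = np.random.default_rng(seed)

    def one(mfi: float, condition: str) -> PhosphoSample:
        intensity = mfi * _lognormal_factor(rng, noise_cv, n_cells)
        dead = rng.random(n_cells) >= live_fraction
        cells = pd.DataFrame(
            {
                "intensity": intensity,
                "gfp": _lognormal_median(rng, _GFP_POS_MEDIAN, _MARKER_CV, n_cells),
                "dtomato": _lognormal_median(rng, _DTOMATO_MEDIAN, _MARKER_CV, n_cells),
                "viability": np.where(
                    dead,
                    _lognormal_median(rng, _VIABILITY_DEAD, _MARKER_CV, n_cells),
                    _lognormal_median(rng, _VIABILITY_LIVE, _MARKER_CV, n_cells),
                ),
            }
        )
        return PhosphoSample(cells=cells, condition=condition, target=target)

    return one(mfi_unstim, "unstimulated"), one(mfi_stim, "crosslinked")


# ---------------------------------------------------------------------------
# Dose-response plates
# ---------------------------------------------------------------------------

#: Twofold dilution series, 96 uM down to 0.1875 uM (10 concentrations).
DEFAULT_CONCENTRATIONS_UM: tuple[float, ...] = tuple(96.0 / 2**k for k in range(10))


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.05,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicate_wells: int = 2,
    n_control_wells: int = 4,
    control_od: float = 1.5,
) -> pd.DataFrame:
    """Simulate a viability plate: duplicate wells per concentration plus
    medium-control wells, OD values from a four-parameter logistic plus
    Gaussian noise.  Returns columns concentration_um, od490,
    is_medium_control."""
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0 uM, got {ic50}")
    conc = np.asarray(
        DEFAULT_CONCENTRATIONS_UM if concentrations is None else concentrations, dtype=float
    )
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        viability = bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
        for _ in range(n_replicate_wells):
            od = viability * control_od + rng.normal(0.0, noise_sd) * control_od
            rows.append((c, od, False))
    for _ in range(n_control_wells):
        rows.append((np.nan, control_od + rng.normal(0.0, noise_sd) * control_od, True))
    return pd.DataFrame(rows, columns=["concentration_um", "od490", "is_medium_control"])


# ---------------------------------------------------------------------------
# Growth with bead calibration
# ---------------------------------------------------------------------------


@dataclass
class GrowthSeries:
    """Bead-calibrated cell-count time series.

    ``bead_expected`` is the nominal bead spike per acquisition; observed
    bead counts fluctuate with acquisition volume, and cell counts are
    rescaled by expected/observed beads before fitting.
    """

    data: pd.DataFrame  # columns: time_h, cell_count, bead_count
    bead_expected: float

    def normalized_counts(self) -> np.ndarray:
        d = self.data
        return (d["cell_count"] * (self.bead_expected / d["bead_count"])).to_numpy()


def simulate_growth(
    doubling_time_h: float,
    n_timepoints: int = 5,
    interval_h: float = 24.0,
    bead_count: float = 5000.0,
    noise_cv: float = 0.1,
    seed: int = 0,
    initial_cells: float = 1e4,
) -> GrowthSeries:
    """Exponential growth sampled with bead normalization; counts follow
    ``initial_cells * 2**(t / doubling_time_h)`` with lognormal noise."""
    if doubling_time_h <= 0:
        raise ValueError(f"doubling_time_h must be > 0, got {doubling_time_h}")
    if n_timepoints < 2:
        raise ValueError(f"n_timepoints must be >= 2, got {n_timepoints}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * interval_h
    cells = initial_cells * 2.0 ** (t / doubling_time_h)
    cells = cells * _lognormal_factor(rng, noise_cv, n_timepoints)
    beads = bead_count * _lognormal_factor(rng, noise_cv, n_timepoints)
    return GrowthSeries(
        data=pd.DataFrame({"time_h": t, "cell_count": cells, "bead_count": beads}),
        bead_expected=bead_count,
    )


# ---------------------------------------------------------------------------
# Genomic aberration matrices
# ---------------------------------------------------------------------------


def simulate_aberrations(
    model, n_cases_per_cluster: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw binary aberration states from each cluster's conditional
    frequencies (the model's raw, unsmoothed frequencies).

    Returns (matrix, labels): matrix is cases x loci of 0/1; labels holds the
    true generating cluster per case.
    """
    from .genomics import ClusterModel  # local import avoids a cycle

    if not isinstance(model, ClusterModel):
        raise TypeError("model must be a ClusterModel")
    if n_cases_per_cluster <= 0:
        raise ValueError(f"n_cases_per_cluster must be > 0, got {n_cases_per_cluster}")
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for ci, cluster in enumerate(model.clusters):
        freqs = model.frequencies[:, ci]
        for j in range(n_cases_per_cluster):
            rows.append((rng.random(len(model.loci)) < freqs).astype(int))
            labels.append(cluster)
            index.append(f"{cluster}-{j:03d}")
    matrix = pd.DataFrame(rows, columns=list(model.loci), index=index)
    return matrix, pd.Series(labels, index=index, name="true_cluster")
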