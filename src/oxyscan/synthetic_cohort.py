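"""Calibrated synthetic sickle-cell cohorts with simulated oxygenscan traces.

No raw patient data accompany the published cohort this generator emulates,
so the pipeline is exercised on synthetic patients built to reproduce the
cohort's *observable* structure:

* marginal biomarker distributions (truncated normals for %HbF, Hb and RBC
  count; %F-cells linked to log %HbF through a logistic curve, reflecting the
  established log-linear HbF/F-cell relationship; %DRBCs decaying with %HbF);
* curve morphology: each patient's red-cell population is a three-class
  mixture (protected F-cells, non-F sickle cells, dense cells), each class an
  EI-vs-pO2 sigmoid; the population EI is the weight-averaged class EI;
* reoxygenation behaviour: an irreversibly sickled fraction of each class
  stays at its deoxygenated EI, and a lysed fraction is removed with weight
  renormalisation — lysis concentrated in poorly deformable classes is what
  lets Recovery exceed 100%;
* the published 3x3 correlation matrix between extracted curve parameters
  (EI_min, EI_max, PoS) and biomarkers (%HbF, %F-cells, %DRBCs): the shipped
  default configuration is the frozen output of :func:`calibrate_generator`
  against those nine coefficients.

The measured %DRBC (cells with MCHC > 41 g/dl) is the extreme tail of a
shifted density distribution, so the poorly deformable subpopulation it
proxies is larger than the count itself; the dense-class mixture weight is
therefore ``dense_amplification x drbc_pct/100`` rather than the raw
fraction.

Reproducibility: one master seed; patient ``i`` draws from an independent
substream seeded by ``(seed, i)``, so cohorts are bit-identical regardless
of generation order.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from . import trace_io
from .curve_params import (
    DEFAULT_CONFIG,
    CurveParameters,
    ExtractionConfig,
    extract_parameters,
)
from .trace_io import BiomarkerTable, OxygenscanTrace, TraceMetadata

CLASS_NAMES = ("f_cell", "non_f_sickle", "dense")

#: Published cohort marginals the generator is calibrated to
#: (mean, sd, low, high), percentages on the 0-100 scale.
REFERENCE_MARGINALS = {
    "hbf_pct": (23.0, 11.5, 5.6, 50.6),
    "fcells_pct": (67.7, 23.1, 24.0, 99.2),
    "drbc_pct": (1.2, 1.5, 0.0, 4.8),
    "hb_g_dl": (9.0, 1.2, 6.9, 11.4),
    "rbc_count_1e6_ul": (3.2, 0.7, 1.7, 4.5),
}

#: Published correlation matrix (biomarker rows x curve-parameter columns)
#: the default configuration is calibrated to reproduce end-to-end.
REFERENCE_CORRELATIONS = pd.DataFrame(
    {
        "ei_min": [0.6310, 0.5855, -0.6988],
        "ei_max": [0.6675, 0.6496, -0.8152],
        "pos_mmHg": [-0.5596, -0.5309, 0.7029],
    },
    index=["hbf_pct", "fcells_pct", "drbc_pct"],
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class CalibrationError(RuntimeError):
    """Calibration could not reach the target correlations.

    Carries the best configuration found (``config``) and its observed
    correlation matrix (``observed``) for diagnosis.
    """

    def __init__(self, message: str, config=None, observed=None):
        super().__init__(message)
        self.config = config
        self.observed = observed


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal marginal.  ``loc``/``sd`` parameterise the parent
    normal; draws are restricted to [low, high], so the *truncated* mean
    differs slightly from ``loc`` (see :func:`recenter_truncnorm`)."""

    loc: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigError("marginal requires low < high")
        if not self.sd > 0:
            raise ConfigError("marginal requires sd > 0")

    def _cdf_bounds(self) -> tuple[float, float]:
        a = (self.low - self.loc) / self.sd
        b = (self.high - self.loc) / self.sd
        return float(ndtr(a)), float(ndtr(b))

    def ppf(self, u):
        """Inverse CDF: maps uniform(0,1) draws to truncated-normal draws."""
        fa, fb = self._cdf_bounds()
        return self.loc + self.sd * ndtri(fa + np.asarray(u) * (fb - fa))

    def mean(self) -> float:
        a = (self.low - self.loc) / self.sd
        b = (self.high - self.loc) / self.sd
        z = ndtr(b) - ndtr(a)
        phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
        return self.loc + self.sd * (phi(a) - phi(b)) / z


def recenter_truncnorm(marginal: TruncNormal, target_mean: float) -> TruncNormal:
    """Solve for the parent ``loc`` so the truncated mean equals ``target_mean``."""
    f = lambda loc: replace(marginal, loc=loc).mean() - target_mean
    lo, hi = marginal.low - 5 * marginal.sd, marginal.high + 5 * marginal.sd
    return replace(marginal, loc=float(brentq(f, lo, hi, xtol=1e-10)))


@dataclass(frozen=True)
class FCellLink:
    """%F-cells as a logistic function of log(%HbF) plus Gaussian noise,
    clipped to the observed cohort range."""

    log_mid: float
    log_scale: float
    noise_sd: float
    low: float = 24.0
    high: float = 99.2

    def mean_curve(self, hbf):
        return 100.0 * expit((np.log(hbf) - self.log_mid) / self.log_scale)


@dataclass(frozen=True)
class DrbcLink:
    """%DRBCs decaying exponentially with %HbF plus Gaussian noise, clipped
    to the observed cohort range (a point mass at 0 mirrors the real
    zero-DRBC samples)."""

    amplitude: float
    tau: float
    noise_sd: float
    low: float = 0.0
    high: float = 4.8

    def mean_curve(self, hbf):
        return self.amplitude * np.exp(-np.asarray(hbf) / self.tau)


@dataclass(frozen=True)
class CellClassModel:
    """One red-cell class: an EI-vs-pO2 sigmoid with reoxygenation behaviour.

    ``ei_oxy``/``ei_deoxy`` are the EI ceiling and floor, ``p50_mmHg`` the
    sickling-transition midpoint, ``slope_mmHg`` its width.  On
    reoxygenation, ``irreversible_fraction`` of the class stays at the floor
    and ``lysis_fraction`` is removed from the population entirely.
    """

    class_name: str
    ei_oxy: float
    ei_deoxy: float
    p50_mmHg: float
    slope_mmHg: float
    irreversible_fraction: float = 0.0
    lysis_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.ei_deoxy <= self.ei_oxy < 1:
            raise ConfigError(
                f"{self.class_name}: need 0 <= ei_deoxy <= ei_oxy < 1"
            )
        if not 0 < self.p50_mmHg < 150:
            raise ConfigError(f"{self.class_name}: p50_mmHg must be in (0, 150)")
        if not self.slope_mmHg > 0:
            raise ConfigError(f"{self.class_name}: slope_mmHg must be > 0")
        for name in ("irreversible_fraction", "lysis_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{self.class_name}: {name} must be in [0, 1]")

    def ei(self, po2):
        """Deoxygenation-path EI at the given pO2 (sigmoid in pO2)."""
        return self.ei_deoxy + (self.ei_oxy - self.ei_deoxy) * expit(
            (np.asarray(po2, dtype=float) - self.p50_mmHg) / self.slope_mmHg
        )

    def ei_reox(self, po2):
        """Reoxygenation-path EI: the irreversibly sickled fraction stays at
        the deoxygenated floor."""
        irr = self.irreversible_fraction
        return (1.0 - irr) * self.ei(po2) + irr * self.ei_deoxy


@dataclass(frozen=True)
class Protection:
    """Fraction of F-cells that are effectively protected from sickling, as
    a logistic function of %HbF (more HbF per F-cell at higher total HbF)."""

    mid: float
    scale: float

    def __call__(self, hbf):
        return expit((np.asarray(hbf, dtype=float) - self.mid) / self.scale)


@dataclass(frozen=True)
class ClassJitter:
    """Per-patient Gaussian jitter of class sigmoid parameters — biological
    variability not captured by the three measured biomarkers."""

    ei_oxy_sd: float = 0.0
    ei_deoxy_sd: float = 0.0
    p50_sd: float = 0.0


@dataclass(frozen=True)
class Sampling:
    """Measurement cycle timing and pO2 profile: an oxygenated plateau, a
    1,300 s nitrogen-driven decline and a 280 s reoxygenation, sampled at a
    fixed rate."""

    plateau_s: float = 100.0
    deox_s: float = 1300.0
    reox_s: float = 280.0
    hz: float = 1.0
    po2_high_mmHg: float = 150.0
    po2_low_mmHg: float = 5.0

    def __post_init__(self) -> None:
        if min(self.plateau_s, self.deox_s, self.reox_s, self.hz) <= 0:
            raise ConfigError("sampling durations and rate must be positive")

    def time_grid(self) -> np.ndarray:
        total = self.plateau_s + self.deox_s + self.reox_s
        n = int(round(total * self.hz)) + 1
        return np.arange(n) / self.hz

    def po2_profile(self) -> np.ndarray:
        t = self.time_grid()
        t1 = self.plateau_s
        t2 = self.plateau_s + self.deox_s
        po2 = np.empty_like(t)
        po2[t <= t1] = self.po2_high_mmHg
        deox = (t > t1) & (t <= t2)
        po2[deox] = self.po2_high_mmHg + (t[deox] - t1) / self.deox_s * (
            self.po2_low_mmHg - self.po2_high_mmHg
        )
        reox = t > t2
        po2[reox] = self.po2_low_mmHg + (t[reox] - t2) / self.reox_s * (
            self.po2_high_mmHg - self.po2_low_mmHg
        )
        return po2


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_patients: int = 38
    seed: int = 0
    hbf_marginal: TruncNormal = field(
        default_factory=lambda: TruncNormal(23.0, 11.5, 5.6, 50.6)
    )
    fcell_link: FCellLink = field(
        default_factory=lambda: FCellLink(2.58, 0.75, 8.0)
    )
    drbc_link: DrbcLink = field(default_factory=lambda: DrbcLink(6.0, 15.0, 0.8))
    hb_marginal: TruncNormal = field(
        default_factory=lambda: TruncNormal(9.0, 1.2, 6.9, 11.4)
    )
    rbc_marginal: TruncNormal = field(
        default_factory=lambda: TruncNormal(3.2, 0.7, 1.7, 4.5)
    )
    protection: Protection = field(default_factory=lambda: Protection(10.0, 5.0))
    #: Linear rise of the F-cell deoxygenated EI floor with %HbF (per %),
    #: centred on the cohort mean: at higher total HbF each F-cell carries
    #: more HbF and keeps a higher EI under hypoxia.
    fcell_floor_hbf_slope: float = 0.0
    dense_amplification: float = 8.0
    dense_weight_cap: float = 0.5
    class_models: tuple[CellClassModel, ...] = field(
        default_factory=lambda: (
            CellClassModel("f_cell", 0.60, 0.57, 10.0, 5.0, 0.0, 0.0),
            CellClassModel("non_f_sickle", 0.48, 0.14, 20.0, 6.0, 0.25, 0.05),
            CellClassModel("dense", 0.30, 0.03, 70.0, 8.0, 0.85, 0.35),
        )
    )
    jitter: ClassJitter = field(default_factory=ClassJitter)
    measurement_noise_sd: float = 0.003
    po2_noise_sd: float = 0.3
    sampling: Sampling = field(default_factory=Sampling)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.measurement_noise_sd < 0 or self.po2_noise_sd < 0:
            raise ConfigError("noise sds must be >= 0")
        names = tuple(m.class_name for m in self.class_models)
        if names != CLASS_NAMES:
            raise ConfigError(f"class_models must be named {CLASS_NAMES} in order")
        if not 0 < self.dense_weight_cap <= 1:
            raise ConfigError("dense_weight_cap must be in (0, 1]")

    def class_model(self, name: str) -> CellClassModel:
        return self.class_models[CLASS_NAMES.index(name)]


# --- YAML (de)serialisation -------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(payload: dict) -> SimulationConfig:
    payload = dict(payload)
    builders: dict[str, Callable] = {
        "hbf_marginal": lambda d: TruncNormal(**d),
        "hb_marginal": lambda d: TruncNormal(**d),
        "rbc_marginal": lambda d: TruncNormal(**d),
        "fcell_link": lambda d: FCellLink(**d),
        "drbc_link": lambda d: DrbcLink(**d),
        "protection": lambda d: Protection(**d),
        "jitter": lambda d: ClassJitter(**d),
        "sampling": lambda d: Sampling(**d),
        "class_models": lambda ms: tuple(CellClassModel(**m) for m in ms),
    }
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    for key, build in builders.items():
        if key in payload:
            try:
                payload[key] = build(payload[key])
            except TypeError as exc:
                raise ConfigError(f"invalid {key!r} section: {exc}") from exc
    try:
        return SimulationConfig(**payload)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True), encoding="utf-8"
    )


def load_config(path: str | Path) -> SimulationConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(payload)


def config_hash(config: SimulationConfig) -> str:
    """Stable content hash of the canonical YAML serialisation."""
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


_DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_calibrated.yaml"


def default_config() -> SimulationConfig:
    """The shipped default configuration: the frozen output of
    :func:`calibrate_generator` against the reference correlation matrix."""
    return load_config(_DEFAULT_CONFIG_PATH)


# ---------------------------------------------------------------------------
# Patient sampling
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One synthetic patient: biomarkers, optionally the simulated trace and
    (filled by the analysis pipeline, not the generator) extracted curve
    parameters."""

    sample_id: str
    hbf_pct: float
    fcells_pct: float
    drbc_pct: float
    hb_g_dl: float
    rbc_count_1e6_ul: float
    curve: OxygenscanTrace | None = None
    params: CurveParameters | None = None


def patient_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, order-stable substream for patient ``index``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def sample_patient(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "patient",
) -> PatientRecord:
    """Draw one patient's biomarkers (no trace).

    Draw order from ``rng`` is fixed (three uniforms, two normals) so that a
    given substream always yields the same patient.
    """
    u = rng.uniform(size=3)
    z = rng.standard_normal(size=2)
    hbf = float(config.hbf_marginal.ppf(u[0]))
    link = config.fcell_link
    fcells = float(
        np.clip(link.mean_curve(hbf) + z[0] * link.noise_sd, link.low, link.high)
    )
    dlink = config.drbc_link
    drbc = float(
        np.clip(dlink.mean_curve(hbf) + z[1] * dlink.noise_sd, dlink.low, dlink.high)
    )
    hb = float(config.hb_marginal.ppf(u[1]))
    rbc = float(config.rbc_marginal.ppf(u[2]))
    return PatientRecord(
        sample_id=sample_id,
        hbf_pct=hbf,
        fcells_pct=fcells,
        drbc_pct=drbc,
        hb_g_dl=hb,
        rbc_count_1e6_ul=rbc,
    )


# ---------------------------------------------------------------------------
# Per-patient mixture and analytic curve parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientMixture:
    """Class weights plus (jittered) class models for one patient, in the
    fixed order (f_cell, non_f_sickle, dense)."""

    weights: tuple[float, float, float]
    models: tuple[CellClassModel, CellClassModel, CellClassModel]

    def ei(self, po2):
        """Population EI on the deoxygenation path: weighted arithmetic mean
        of the class sigmoids."""
        po2 = np.asarray(po2, dtype=float)
        return sum(w * m.ei(po2) for w, m in zip(self.weights, self.models))

    def reox_weights(self) -> tuple[float, ...]:
        surv = [w * (1.0 - m.lysis_fraction) for w, m in zip(self.weights, self.models)]
        total = sum(surv)
        if total <= 0:
            raise ConfigError("all cells lysed; reoxygenation weights undefined")
        return tuple(s / total for s in surv)

    def ei_reox(self, po2):
        """Population EI on the reoxygenation path: lysed fractions removed
        (weights renormalised), irreversibly sickled fractions held at their
        deoxygenated floor."""
        po2 = np.asarray(po2, dtype=float)
        w = self.reox_weights()
        return sum(wi * m.ei_reox(po2) for wi, m in zip(w, self.models))


def class_weights(
    patient: PatientRecord, config: SimulationConfig
) -> tuple[float, float, float]:
    """Mixture weights from the biomarkers.

    Dense weight: ``dense_amplification x drbc/100`` (capped); F-cell weight:
    the F-cell fraction times the HbF-dependent protection, applied to the
    non-dense remainder; the rest are non-F sickle cells.
    """
    w_d = min(config.dense_amplification * patient.drbc_pct / 100.0,
              config.dense_weight_cap)
    prot = float(config.protection(patient.hbf_pct))
    w_f = (patient.fcells_pct / 100.0) * prot * (1.0 - w_d)
    w_n = 1.0 - w_d - w_f
    if w_f + w_d + w_n <= 0 or w_n < -1e-12:
        raise ConfigError("class weights must be non-negative and sum to 1")
    return (w_f, max(w_n, 0.0), w_d)


def draw_mixture(
    patient: PatientRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PatientMixture:
    """Class weights plus per-patient jittered class models.

    Draws exactly nine normals (three per class, in class order), so the
    stream position after this call is deterministic.
    """
    jz = rng.standard_normal(size=(3, 3))
    jit = config.jitter
    models = []
    for row, base in zip(jz, config.class_models):
        floor = base.ei_deoxy
        if base.class_name == "f_cell":
            floor = floor + config.fcell_floor_hbf_slope * (
                patient.hbf_pct - REFERENCE_MARGINALS["hbf_pct"][0]
            )
        u = float(np.clip(base.ei_oxy + row[0] * jit.ei_oxy_sd, 0.01, 0.98))
        low = float(np.clip(floor + row[1] * jit.ei_deoxy_sd, 0.0, u))
        p50 = float(np.clip(base.p50_mmHg + row[2] * jit.p50_sd, 1.0, 149.0))
        models.append(replace(base, ei_oxy=u, ei_deoxy=low, p50_mmHg=p50))
    return PatientMixture(weights=class_weights(patient, config),
                          models=tuple(models))


def analytic_parameters(
    mix: PatientMixture, config: SimulationConfig
) -> tuple[float, float, float, float]:
    """Noise-free curve parameters implied by a patient's mixture:
    (ei_max, ei_min, pos_mmHg, recovery_pct); pos is NaN when the curve
    never drops 5% below EI_max within the measured pO2 range."""
    p_hi = config.sampling.po2_high_mmHg
    p_lo = config.sampling.po2_low_mmHg
    ei_max = float(mix.ei(p_hi))
    ei_min = float(mix.ei(p_lo))
    threshold = 0.95 * ei_max
    if ei_min > threshold:
        pos = float("nan")
    else:
        lo, hi = p_lo, p_hi
        for _ in range(80):  # bisection: mix.ei is monotone increasing in pO2
            mid = 0.5 * (lo + hi)
            if mix.ei(mid) > threshold:
                hi = mid
            else:
                lo = mid
        pos = 0.5 * (lo + hi)
    recovery = 100.0 * float(mix.ei_reox(p_hi)) / ei_max
    return ei_max, ei_min, pos, recovery


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def simulate_trace_from_mixture(
    mix: PatientMixture,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "patient",
) -> OxygenscanTrace:
    """Sample the mixture EI along the pO2 cycle and add measurement noise."""
    s = config.sampling
    t = s.time_grid()
    po2_clean = s.po2_profile()
    deox_end = s.plateau_s + s.deox_s
    ei = np.where(
        t <= deox_end, mix.ei(po2_clean), mix.ei_reox(po2_clean)
    )
    if config.measurement_noise_sd > 0:
        ei = ei + rng.standard_normal(len(t)) * config.measurement_noise_sd
    if config.po2_noise_sd > 0:
        po2 = po2_clean + rng.standard_normal(len(t)) * config.po2_noise_sd
    else:
        po2 = po2_clean.copy()
    ei = np.clip(ei, 0.0, 0.9999)
    po2 = np.clip(po2, 0.0, 200.0)
    meta = TraceMetadata(
        sample_id=sample_id,
        deox_duration_s=s.deox_s,
        reox_duration_s=s.reox_s,
    )
    return OxygenscanTrace(time_s=t, pO2_mmHg=po2, ei=ei, metadata=meta)


def simulate_curve(
    patient: PatientRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> OxygenscanTrace:
    """Simulate one patient's oxygenscan trace (jitter + noise from ``rng``)."""
    mix = draw_mixture(patient, config, rng)
    return simulate_trace_from_mixture(mix, config, rng, patient.sample_id)


def simulate_cohort(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    keep_traces: bool = True,
) -> list[PatientRecord]:
    """Generate the full cohort (biomarkers + traces).

    With ``outdir`` set, writes ``biomarkers.csv`` plus one trace CSV (and
    metadata sidecar) per patient via :mod:`oxyscan.trace_io`.
    """
    records = []
    for i in range(config.n_patients):
        rng = patient_rng(config.seed, i)
        sid = f"SYN{i:04d}"
        rec = sample_patient(config, rng, sample_id=sid)
        trace = simulate_curve(rec, config, rng)
        if keep_traces or outdir is not None:
            rec.curve = trace
        records.append(rec)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table = BiomarkerTable(biomarker_frame(records))
        trace_io.write_biomarkers(table, outdir / "biomarkers.csv")
        for rec in records:
            trace_io.write_trace(rec.curve, outdir / f"{rec.sample_id}.csv")
            if not keep_traces:
                rec.curve = None
    return records


def biomarker_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "hbf_pct": [r.hbf_pct for r in records],
            "fcells_pct": [r.fcells_pct for r in records],
            "drbc_pct": [r.drbc_pct for r in records],
            "hb_g_dl": [r.hb_g_dl for r in records],
            "rbc_count_1e6_ul": [r.rbc_count_1e6_ul for r in records],
        }
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline and fast analytic forward map
# ---------------------------------------------------------------------------

def run_pipeline(
    config: SimulationConfig,
    n: int | None = None,
    seed: int | None = None,
    extraction: ExtractionConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Simulate -> extract for every patient, streaming (traces discarded).

    Returns one row per patient: biomarkers plus extracted ``ei_max``,
    ``ei_min``, ``pos_mmHg``, ``recovery_pct`` and flags.
    """
    if n is not None:
        config = replace(config, n_patients=n)
    if seed is not None:
        config = replace(config, seed=seed)
    rows = []
    for i in range(config.n_patients):
        rng = patient_rng(config.seed, i)
        rec = sample_patient(config, rng, sample_id=f"SYN{i:04d}")
        trace = simulate_curve(rec, config, rng)
        p = extract_parameters(trace, extraction)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "hbf_pct": rec.hbf_pct,
                "fcells_pct": rec.fcells_pct,
                "drbc_pct": rec.drbc_pct,
                "hb_g_dl": rec.hb_g_dl,
                "rbc_count_1e6_ul": rec.rbc_count_1e6_ul,
                "ei_max": p.ei_max,
                "ei_min": p.ei_min,
                "pos_mmHg": p.pos_mmHg,
                "recovery_pct": p.recovery_pct,
                "flags": ";".join(sorted(p.flags)),
            }
        )
    return pd.DataFrame(rows)


def cohort_analytic_frame(
    config: SimulationConfig, n: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Biomarkers plus *noise-free analytic* curve parameters per patient.

    Uses the same per-patient substreams (biomarkers and class jitter are
    identical to :func:`run_pipeline`'s) but skips trace synthesis and
    extraction — the fast forward map used during calibration.  The
    transformations are applied as whole-cohort array operations; only the
    raw random draws come from the per-patient substreams.
    """
    if n is not None:
        config = replace(config, n_patients=n)
    if seed is not None:
        config = replace(config, seed=seed)
    m = config.n_patients
    u = np.empty((m, 3))
    z = np.empty((m, 2))
    jz = np.empty((m, 3, 3))
    for i in range(m):
        rng = patient_rng(config.seed, i)
        u[i] = rng.uniform(size=3)
        z[i] = rng.standard_normal(size=2)
        jz[i] = rng.standard_normal(size=(3, 3))
    hbf = config.hbf_marginal.ppf(u[:, 0])
    link = config.fcell_link
    fcells = np.clip(link.mean_curve(hbf) + z[:, 0] * link.noise_sd,
                     link.low, link.high)
    dlink = config.drbc_link
    drbc = np.clip(dlink.mean_curve(hbf) + z[:, 1] * dlink.noise_sd,
                   dlink.low, dlink.high)
    hb = config.hb_marginal.ppf(u[:, 1])
    rbc = config.rbc_marginal.ppf(u[:, 2])

    # jittered class parameters, (m, 3) in class order — mirrors draw_mixture
    jit = config.jitter
    base_u = np.array([c.ei_oxy for c in config.class_models])
    base_l = np.array([c.ei_deoxy for c in config.class_models])
    base_p = np.array([c.p50_mmHg for c in config.class_models])
    slope = np.array([c.slope_mmHg for c in config.class_models])
    irr = np.array([c.irreversible_fraction for c in config.class_models])
    lys = np.array([c.lysis_fraction for c in config.class_models])
    floors = np.broadcast_to(base_l, (m, 3)).copy()
    floors[:, 0] += config.fcell_floor_hbf_slope * (
        hbf - REFERENCE_MARGINALS["hbf_pct"][0]
    )
    u_c = np.clip(base_u + jz[:, :, 0] * jit.ei_oxy_sd, 0.01, 0.98)
    l_c = np.clip(floors + jz[:, :, 1] * jit.ei_deoxy_sd, 0.0, u_c)
    p50 = np.clip(base_p + jz[:, :, 2] * jit.p50_sd, 1.0, 149.0)

    w_d = np.minimum(config.dense_amplification * drbc / 100.0,
                     config.dense_weight_cap)
    prot = config.protection(hbf)
    w_f = (fcells / 100.0) * prot * (1.0 - w_d)
    w_n = np.maximum(1.0 - w_d - w_f, 0.0)
    w = np.stack([w_f, w_n, w_d], axis=1)

    def mix_ei(p):  # p: (m,) or scalar -> (m,)
        p = np.asarray(p, dtype=float)[..., None]
        return (w * (l_c + (u_c - l_c) * expit((p - p50) / slope))).sum(axis=-1)

    p_hi, p_lo = config.sampling.po2_high_mmHg, config.sampling.po2_low_mmHg
    ei_max = mix_ei(np.full(m, p_hi))
    ei_min = mix_ei(np.full(m, p_lo))
    threshold = 0.95 * ei_max
    lo = np.full(m, p_lo)
    hi = np.full(m, p_hi)
    for _ in range(60):  # monotone in pO2 -> bisection
        mid = 0.5 * (lo + hi)
        above = mix_ei(mid) > threshold
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    pos = np.where(ei_min > threshold, np.nan, 0.5 * (lo + hi))
    surv = w * (1.0 - lys)
    w_reox = surv / surv.sum(axis=1, keepdims=True)
    ei_reox_hi = (
        w_reox
        * ((1 - irr) * (l_c + (u_c - l_c) * expit((p_hi - p50) / slope))
           + irr * l_c)
    ).sum(axis=1)
    recovery = 100.0 * ei_reox_hi / ei_max
    return pd.DataFrame(
        {
            "sample_id": [f"SYN{i:04d}" for i in range(m)],
            "hbf_pct": hbf,
            "fcells_pct": fcells,
            "drbc_pct": drbc,
            "hb_g_dl": hb,
            "rbc_count_1e6_ul": rbc,
            "ei_max": ei_max,
            "ei_min": ei_min,
            "pos_mmHg": pos,
            "recovery_pct": recovery,
        }
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _observed_correlations(frame: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations, biomarker rows x parameter
    columns, matching the shape of :data:`REFERENCE_CORRELATIONS`."""
    out = {}
    for param in REFERENCE_CORRELATIONS.columns:
        col = []
        for bio in REFERENCE_CORRELATIONS.index:
            pair = frame[[bio, param]].dropna()
            col.append(float(np.corrcoef(pair[bio], pair[param])[0, 1]))
        out[param] = col
    return pd.DataFrame(out, index=REFERENCE_CORRELATIONS.index)


def _with_updates(config: SimulationConfig, updates: dict[str, float]) -> SimulationConfig:
    """Return a config with dotted-path fields replaced, e.g.
    ``{"fcell_link.noise_sd": 6.0, "class.non_f_sickle.p50_mmHg": 22.0}``."""
    payload = config_to_dict(config)
    for path, value in updates.items():
        parts = path.split(".")
        if parts[0] == "class":
            idx = CLASS_NAMES.index(parts[1])
            payload["class_models"][idx][parts[2]] = float(value)
        else:
            node = payload
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = float(value)
    return config_from_dict(payload)


#: Knobs explored by the calibration coordinate search: dotted path, initial
#: step, lower bound, upper bound.
CALIBRATION_KNOBS: tuple[tuple[str, float, float, float], ...] = (
    ("fcell_link.noise_sd", 2.0, 0.5, 25.0),
    ("drbc_link.noise_sd", 0.3, 0.05, 4.0),
    ("drbc_link.tau", 3.0, 4.0, 60.0),
    ("drbc_link.amplitude", 1.0, 0.5, 20.0),
    ("protection.mid", 3.0, 0.0, 40.0),
    ("protection.scale", 2.0, 1.0, 25.0),
    ("dense_amplification", 1.0, 0.5, 10.0),
    ("class.f_cell.ei_deoxy", 0.01, 0.30, 0.595),
    ("fcell_floor_hbf_slope", 0.0005, 0.0, 0.008),
    ("class.non_f_sickle.ei_oxy", 0.02, 0.32, 0.59),
    ("class.non_f_sickle.ei_deoxy", 0.02, 0.02, 0.42),
    ("class.non_f_sickle.p50_mmHg", 3.0, 8.0, 45.0),
    ("class.dense.p50_mmHg", 4.0, 30.0, 110.0),
    ("fcell_link.log_scale", 0.08, 0.35, 1.3),
    ("class.dense.ei_oxy", 0.03, 0.08, 0.45),
    ("jitter.ei_oxy_sd", 0.003, 0.0, 0.08),
    ("jitter.ei_deoxy_sd", 0.005, 0.0, 0.15),
    ("jitter.p50_sd", 1.0, 0.0, 25.0),
)


def _calibration_objective(
    config: SimulationConfig,
    targets: pd.DataFrame,
    n_calib: int,
    seed: int,
) -> tuple[float, pd.DataFrame]:
    """Search objective: RMS deviation of the nine correlations from their
    targets (smooth enough for coordinate descent) plus a soft penalty for
    drifting marginal means."""
    frame = cohort_analytic_frame(config, n=n_calib, seed=seed)
    obs = _observed_correlations(frame)
    dev = (obs - targets).to_numpy()
    mean_pen = 0.0
    for col, target in (("hbf_pct", 23.0), ("fcells_pct", 67.7)):
        miss = abs(frame[col].mean() - target)
        mean_pen += max(0.0, miss - 0.25)
    rms = float(np.sqrt(np.mean(dev**2)))
    return rms + 0.5 * mean_pen, obs


def calibrate_marginals(config: SimulationConfig, n_probe: int = 8000,
                        seed: int = 0) -> SimulationConfig:
    """Stage-1 calibration: recenter the truncated-normal locations so the
    truncated means hit the reference means, and solve the F-cell link
    midpoint so the simulated %F-cells mean (clipping included) matches."""
    cfg = replace(
        config,
        hbf_marginal=recenter_truncnorm(config.hbf_marginal,
                                        REFERENCE_MARGINALS["hbf_pct"][0]),
        hb_marginal=recenter_truncnorm(config.hb_marginal,
                                       REFERENCE_MARGINALS["hb_g_dl"][0]),
        rbc_marginal=recenter_truncnorm(config.rbc_marginal,
                                        REFERENCE_MARGINALS["rbc_count_1e6_ul"][0]),
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 987]))
    hbf = cfg.hbf_marginal.ppf(rng.uniform(size=n_probe))
    z = rng.standard_normal(size=n_probe)
    link = cfg.fcell_link

    def fcell_mean_gap(log_mid: float) -> float:
        raw = 100.0 * expit((np.log(hbf) - log_mid) / link.log_scale)
        sim = np.clip(raw + z * link.noise_sd, link.low, link.high)
        return float(sim.mean()) - REFERENCE_MARGINALS["fcells_pct"][0]

    log_mid = float(brentq(fcell_mean_gap, 1.0, 4.5, xtol=1e-6))
    return replace(cfg, fcell_link=replace(link, log_mid=log_mid))


def calibrate_generator(
    base_config: SimulationConfig,
    target_matrix: pd.DataFrame | None = None,
    n_calib: int = 4000,
    seed: int = 0,
    max_rounds: int = 30,
    tolerance: float = 0.05,
) -> SimulationConfig:
    """Tune the generator so end-to-end observable correlations match the
    target matrix.

    Coordinate search over link-noise sds and class-model spreads
    (:data:`CALIBRATION_KNOBS`) against the noise-free analytic forward map
    (the full extractors add only per-sample measurement noise, which is
    negligible at the smoothing defaults); the marginal means are re-solved
    first.  Raises :class:`CalibrationError`, listing the worst entries, if
    the targets cannot be reached within ``tolerance``.
    """
    targets = REFERENCE_CORRELATIONS if target_matrix is None else target_matrix
    targets = targets.loc[REFERENCE_CORRELATIONS.index, REFERENCE_CORRELATIONS.columns]
    config = calibrate_marginals(base_config, seed=seed)
    best, _ = _calibration_objective(config, targets, n_calib, seed)
    steps = {path: step for path, step, _, _ in CALIBRATION_KNOBS}
    bounds = {path: (lo, hi) for path, _, lo, hi in CALIBRATION_KNOBS}
    for _ in range(max_rounds):
        improved = False
        for path, _, _, _ in CALIBRATION_KNOBS:
            payload = config_to_dict(config)
            parts = path.split(".")
            if parts[0] == "class":
                cur = payload["class_models"][CLASS_NAMES.index(parts[1])][parts[2]]
            else:
                node = payload
                for p in parts[:-1]:
                    node = node[p]
                cur = node[parts[-1]]
            lo, hi = bounds[path]
            for cand in (cur + steps[path], cur - steps[path]):
                cand = min(max(cand, lo), hi)
                if cand == cur:
                    continue
                try:
                    trial = _with_updates(config, {path: cand})
                    trial = calibrate_marginals(trial, seed=seed)
                except ConfigError:
                    continue
                val, _ = _calibration_objective(trial, targets, n_calib, seed)
                if val < best - 1e-4:
                    config, best, improved = trial, val, True
                    break
        if not improved:
            shrunk = {p: s * 0.5 for p, s in steps.items()}
            if max(shrunk.values()) < 1e-3:
                break
            steps = shrunk
        if best <= tolerance * 0.3:
            break
    _, obs = _calibration_objective(config, targets, n_calib, seed)
    if float((obs - targets).abs().to_numpy().max()) > tolerance:
        dev = (obs - targets).abs()
        worst = dev.stack().sort_values(ascending=False).head(3)
        raise CalibrationError(
            "targets unreachable within search budget; worst entries: "
            + ", ".join(f"{idx}: |dev|={v:.3f}" for idx, v in worst.items()),
            config=config,
            observed=obs,
        )
    return config
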