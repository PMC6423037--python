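"""Synthetic longitudinal rbST studies: expression, amplification curves, milk yield.

The generator emulates the statistical structure of the reference
experiment so that every downstream stage of the pipeline can be verified
against known ground truth:

* per-gene log-normal relative abundance with between-animal random
  effects and a per-sample RNA-loading effect common to all genes (which
  reference-gene normalization must cancel);
* dose-locked multiplicative up-regulation of responsive genes, pulsed
  after each injection (configurable onset, peak, washout; no
  accumulation across doses — the most recent dose dominates);
* genes that are never detected, detected per animal, or subject to
  per-sample dropout;
* stable reference genes;
* raw amplification fluorescence curves (logistic amplification with
  per-gene efficiency, plateau, baseline, multiplicative session factors
  and additive noise);
* daily milk yields following Wood's lactation curve with a sustained
  treatment boost.

All randomness derives from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign, DoseSchedule, build_dose_schedule, days_since_last_dose

__all__ = [
    "GeneProfile",
    "YieldModel",
    "CurveParams",
    "SimulationConfig",
    "default_profiles",
    "response_kernel",
    "simulate_expression",
    "simulate_yield",
    "simulate_curves",
    "simulate_study",
]

Detection = Literal["always", "never", "per_animal", "dropout"]


@dataclass(frozen=True)
class GeneProfile:
    """Generative model for one gene's relative abundance.

    ``baseline_log10_mean``/``baseline_log10_sd`` set the log-normal
    baseline; ``animal_sd`` is a between-animal random effect (log10).
    Responsive genes receive a multiplicative dose-locked pulse of
    maximal fold-change ``1 + amplitude`` (see :func:`response_kernel`).
    ``detection`` selects how missingness arises: ``always``, ``never``,
    ``per_animal`` (each animal expresses the gene with probability
    ``p_detect``) or ``dropout`` (each sample independently missing with
    probability ``p_dropout``).
    """

    gene: str
    baseline_log10_mean: float = 0.0
    baseline_log10_sd: float = 0.16
    animal_sd: float = 0.12
    responsive: bool = False
    onset_days: float = 1.0
    peak_day: float = 8.0
    washout_tau: float = 6.0
    amplitude: float = 0.0
    rise_tau_days: float | None = None
    #: probability that a given dose elicits the pulse in a given animal
    #: (1.0 = responds to every dose; <1 models erratic responders)
    response_prob: float = 1.0
    detection: Detection = "always"
    p_detect: float = 1.0
    p_dropout: float = 0.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.washout_tau <= 0:
            raise ValueError("washout_tau must be > 0")
        if not (self.peak_day >= self.onset_days >= 0):
            raise ValueError("need peak_day >= onset_days >= 0")
        for p in (self.p_detect, self.p_dropout, self.response_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.is_reference and self.responsive:
            raise ValueError("reference genes must be non-responsive")


@dataclass(frozen=True)
class YieldModel:
    """Wood lactation curve with treatment boost.

    Daily yield for animal ``a`` at ``t`` days in milk:

        kg(t) = s_a * scale_g * a*t^b*exp(-c*t) * (1 + boost*r(t)) + noise

    where ``s_a`` is a per-animal log-normal scale, ``scale_g`` is
    ``treated_scale`` for treated animals (baseline herd imbalance) and 1
    for controls, and ``r(t)`` ramps up over ``boost_rise_days`` after the
    first dose, tracks dose coverage (decaying when >1 interval elapses
    since the last dose) and decays after the last dose.

    Defaults put the lactation peak near 38 kg at ~55 days in milk.
    """

    wood_a: float = 16.0
    wood_b: float = 0.22
    wood_c: float = 0.004
    animal_scale_sd: float = 0.12
    treatment_boost: float = 0.28
    boost_rise_days: float = 14.0
    boost_decay_tau: float = 10.0
    treated_scale: float = 1.13
    noise_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.wood_a <= 0 or self.wood_c <= 0:
            raise ValueError("wood_a and wood_c must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CurveParams:
    """Amplification-curve generator settings.

    ``efficiency`` maps gene -> per-cycle fold amplification in (1, 2];
    genes absent from the map get ``default_efficiency``.  Fluorescence
    follows a logistic amplification with plateau ``plateau_k`` above a
    constant baseline, scaled by a multiplicative session factor.
    """

    default_efficiency: float = 1.9
    efficiency: dict[str, float] = field(default_factory=dict)
    plateau_k: float = 3000.0
    baseline: float = 100.0
    baseline_jitter_sd: float = 2.0
    noise_sd: float = 1.0
    n_cycles: int = 40
    x0_scale: float = 1e-4
    n_replicates: int = 3

    def gene_efficiency(self, gene: str) -> float:
        return self.efficiency.get(gene, self.default_efficiency)


# --- default gene roster ----------------------------------------------

def default_profiles() -> list[GeneProfile]:
    """The 15 target + 3 reference genes of the panel, with default roles.

    Strong responders CCND1, IGF1R, TNF and IL1B; weak responders SIRT2,
    TPD52L2 and EEF1G; noisy non-responders LTF, MFGE8 and CTNNAL1
    (CTNNAL1 with per-sample dropout, so the 0%-missing filter excludes
    it); IGFBP3/IGFBP5/COL3A1/ESR2 never detected; IGF1 detected per
    animal with low probability; references UXT, RPS9, GPAM stable.

    Baselines and effect sizes are calibrated so the day-1 IGF1R
    treated/control group-mean ratio is ~3.9 (0.348 vs 0.0898), the
    day-23 SIRT2 ratio ~3.0 (1.517 vs 0.506), and washed-out days show no
    group difference (0.433 vs 0.430 at day 219).
    """
    strong = dict(responsive=True, washout_tau=6.0, amplitude=3.0)
    return [
        # strong responders
        GeneProfile("IGF1R", baseline_log10_mean=-1.047, baseline_log10_sd=0.16,
                    animal_sd=0.05, onset_days=0.0, peak_day=7.0,
                    rise_tau_days=0.35, **strong),
        GeneProfile("CCND1", baseline_log10_mean=-0.30, baseline_log10_sd=0.16,
                    animal_sd=0.05, onset_days=1.0, peak_day=8.0, **strong),
        GeneProfile("TNF", baseline_log10_mean=-0.70, baseline_log10_sd=0.18,
                    animal_sd=0.05, responsive=True, onset_days=2.0,
                    peak_day=10.0, washout_tau=6.0, amplitude=3.5),
        GeneProfile("IL1B", baseline_log10_mean=-0.85, baseline_log10_sd=0.18,
                    animal_sd=0.05, responsive=True, onset_days=2.0,
                    peak_day=10.0, washout_tau=6.0, amplitude=3.5),
        # weak / erratic responders
        GeneProfile("SIRT2", baseline_log10_mean=-0.33, baseline_log10_sd=0.18,
                    animal_sd=0.05, responsive=True, onset_days=2.0,
                    peak_day=9.0, washout_tau=6.0, amplitude=1.2,
                    response_prob=0.15),
        GeneProfile("TPD52L2", baseline_log10_mean=-0.15, baseline_log10_sd=0.16,
                    animal_sd=0.05, responsive=True, onset_days=0.5,
                    peak_day=4.0, washout_tau=5.0, amplitude=0.4,
                    response_prob=0.25),
        GeneProfile("EEF1G", baseline_log10_mean=0.10, baseline_log10_sd=0.16,
                    animal_sd=0.05, responsive=True, onset_days=2.0,
                    peak_day=9.0, washout_tau=6.0, amplitude=0.3,
                    response_prob=0.25),
        # noisy non-responders (noise is within-animal; large between-animal
        # effects would alias into class signal with only 3 control animals)
        GeneProfile("LTF", baseline_log10_mean=0.50, baseline_log10_sd=0.35,
                    animal_sd=0.05),
        GeneProfile("MFGE8", baseline_log10_mean=0.20, baseline_log10_sd=0.30,
                    animal_sd=0.05),
        GeneProfile("CTNNAL1", baseline_log10_mean=-0.60, baseline_log10_sd=0.25,
                    animal_sd=0.05, detection="dropout", p_dropout=0.25),
        # undetected / sporadic
        GeneProfile("IGF1", baseline_log10_mean=-1.5, detection="per_animal",
                    p_detect=1.0 / 6.0),
        GeneProfile("IGFBP3", detection="never"),
        GeneProfile("IGFBP5", detection="never"),
        GeneProfile("COL3A1", detection="never"),
        GeneProfile("ESR2", detection="never"),
        # references
        GeneProfile("UXT", baseline_log10_mean=0.0, baseline_log10_sd=0.08,
                    animal_sd=0.06, is_reference=True),
        GeneProfile("RPS9", baseline_log10_mean=0.3, baseline_log10_sd=0.08,
                    animal_sd=0.06, is_reference=True),
        GeneProfile("GPAM", baseline_log10_mean=-0.2, baseline_log10_sd=0.08,
                    animal_sd=0.06, is_reference=True),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic study."""

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    profiles: tuple[GeneProfile, ...] = field(
        default_factory=lambda: tuple(default_profiles()))
    yield_model: YieldModel = field(default_factory=YieldModel)
    curve_params: CurveParams = field(default_factory=CurveParams)
    #: per-sample RNA-loading effect, log10 sd; common to all genes of a
    #: sample, cancelled by reference normalization
    loading_sd: float = 0.25
    #: mapping sampling day -> session id; default: consecutive sampling
    #: days grouped into sessions of ``samples_per_session`` days
    session_days_per_session: int = 6
    session_factor_sd: float = 0.35
    #: days in milk at first dose (treated, control)
    dim_at_first_dose: tuple[float, float] = (67.0, 75.0)
    exclude_genes: tuple[str, ...] = ()

    @property
    def schedule(self) -> DoseSchedule:
        return build_dose_schedule(self.design)

    def profile(self, gene: str) -> GeneProfile:
        for p in self.profiles:
            if p.gene == gene:
                return p
        raise KeyError(gene)


# --- response kernel ---------------------------------------------------

def response_kernel(tau: float | np.ndarray | None, profile: GeneProfile
                    ) -> float | np.ndarray:
    """Multiplicative dose effect at ``tau`` days after the latest dose.

    effect(tau) = 1 + amplitude * g(tau), with a unimodal pulse g: zero
    before ``onset_days``, a saturating-exponential rise to 1 at
    ``peak_day`` (time constant ``rise_tau_days``), then exponential
    decay with time constant ``washout_tau``.  ``tau=None`` (pre-dose)
    and non-responsive profiles give 1.
    """
    if tau is None or not profile.responsive or profile.amplitude == 0:
        if isinstance(tau, np.ndarray):
            return np.ones_like(tau, dtype=float)
        return 1.0
    t = np.asarray(tau, dtype=float)
    g = np.zeros_like(t)
    onset, peak = profile.onset_days, profile.peak_day
    rise_tau = profile.rise_tau_days
    if rise_tau is None:
        rise_tau = max((peak - onset) / 3.0, 1e-9)
    rising = (t >= onset) & (t <= peak)
    if peak > onset:
        norm = 1.0 - np.exp(-(peak - onset) / rise_tau)
        g[rising] = (1.0 - np.exp(-(t[rising] - onset) / rise_tau)) / norm
    else:
        g[rising] = 1.0
    decaying = t > peak
    g[decaying] = np.exp(-(t[decaying] - peak) / profile.washout_tau)
    out = 1.0 + profile.amplitude * g
    if np.isscalar(tau):
        return float(out)
    return out


# --- expression --------------------------------------------------------

def _animal_table(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for i in range(design.n_control):
        rows.append({"animal": f"C{i + 1}", "group": "control"})
    for i in range(design.n_treated):
        rows.append({"animal": f"T{i + 1}", "group": "rbst"})
    return pd.DataFrame(rows)


def _session_of_day(config: SimulationConfig) -> dict[int, str]:
    days = list(config.design.sampling_days)
    k = config.session_days_per_session
    return {d: f"S{i // k + 1}" for i, d in enumerate(days)}


def session_factors_truth(config: SimulationConfig) -> dict[str, float]:
    """The multiplicative session factors injected into simulated curves."""
    mapping = _session_of_day(config)
    sessions = sorted(set(mapping.values()), key=lambda s: int(s[1:]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    logf = rng.normal(0.0, config.session_factor_sd, size=len(sessions))
    logf -= logf.mean()  # geometric mean 1
    return {s: float(np.exp(l)) for s, l in zip(sessions, logf)}


def simulate_expression(config: SimulationConfig) -> pd.DataFrame:
    """Simulate true relative abundances for every animal/day/gene.

    Returns a long table with columns ``sample, animal, group, day,
    days_since_dose, session, gene, abundance, detected``.  Control
    animals and pre-dose days never carry dose effects.  Abundance is NaN
    where undetected.  Deterministic under ``config.seed``.
    """
    design = config.design
    schedule = config.schedule
    animals = _animal_table(design)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    session_of = _session_of_day(config)

    genes = [p for p in config.profiles if p.gene not in config.exclude_genes]
    # per-animal random effects and loadings
    animal_eff = {
        (a, p.gene): rng.normal(0.0, p.animal_sd)
        for a in animals["animal"] for p in genes
    }
    detect_animal = {
        (a, p.gene): (rng.random() < p.p_detect) if p.detection == "per_animal" else True
        for a in animals["animal"] for p in genes
    }
    # erratic responders: per animal x gene x dose, does this dose elicit a pulse?
    dose_responds = {
        (a, p.gene, k): (p.response_prob >= 1.0 or rng.random() < p.response_prob)
        for a in animals["animal"] for p in genes
        for k in range(len(schedule.dose_days))
    }

    def _last_dose_index(day: float) -> int | None:
        past = [i for i, d in enumerate(schedule.dose_days) if d <= day]
        return past[-1] if past else None
    rows = []
    for _, arow in animals.iterrows():
        a, grp = arow["animal"], arow["group"]
        for day in design.sampling_days:
            loading = rng.normal(0.0, config.loading_sd)
            tau = days_since_last_dose(schedule, day) if grp == "rbst" else None
            sample = f"{a}_d{day}"
            for p in genes:
                if p.detection == "never":
                    rows.append((sample, a, grp, day, tau, session_of[day],
                                 p.gene, np.nan, False))
                    continue
                if p.detection == "per_animal" and not detect_animal[(a, p.gene)]:
                    rows.append((sample, a, grp, day, tau, session_of[day],
                                 p.gene, np.nan, False))
                    continue
                dropped = (p.detection == "dropout"
                           and rng.random() < p.p_dropout)
                dose_idx = _last_dose_index(day) if grp == "rbst" else None
                if (dose_idx is not None
                        and not dose_responds[(a, p.gene, dose_idx)]):
                    eff = 1.0
                else:
                    eff = response_kernel(tau, p)
                log10x = (p.baseline_log10_mean + animal_eff[(a, p.gene)]
                          + loading + np.log10(eff)
                          + rng.normal(0.0, p.baseline_log10_sd))
                if dropped:
                    rows.append((sample, a, grp, day, tau, session_of[day],
                                 p.gene, np.nan, False))
                else:
                    rows.append((sample, a, grp, day, tau, session_of[day],
                                 p.gene, 10.0 ** log10x, True))
    return pd.DataFrame(rows, columns=[
        "sample", "animal", "group", "day", "days_since_dose", "session",
        "gene", "abundance", "detected"])


# --- milk yield --------------------------------------------------------

def _boost_profile(days: np.ndarray, schedule: DoseSchedule,
                   ym: YieldModel) -> np.ndarray:
    """r(t): 0 pre-dose, ramping to 1 over boost_rise_days, tracking dose
    coverage (decays when more than one interval passes without a dose)."""
    first, last = schedule.dose_days[0], schedule.dose_days[-1]
    r = np.zeros_like(days, dtype=float)
    for i, d in enumerate(days):
        if d < first:
            continue
        ramp = min((d - first) / ym.boost_rise_days, 1.0)
        tau = d - max(dd for dd in schedule.dose_days if dd <= d)
        # full effect while within a normal inter-dose interval;
        # exponential decay beyond it (gap weeks, post-treatment)
        overshoot = max(tau - 14.0, 0.0)
        r[i] = ramp * np.exp(-overshoot / ym.boost_decay_tau)
    return r


def simulate_yield(config: SimulationConfig) -> pd.DataFrame:
    """Daily milk yields (kg) per animal over the recording window."""
    design, ym = config.design, config.yield_model
    schedule = config.schedule
    animals = _animal_table(design)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    days = np.arange(-design.conditioning_days,
                     schedule.dose_days[-1] + design.followup_days + 1)
    boost = _boost_profile(days, schedule, ym)
    dim_treated, dim_control = config.dim_at_first_dose
    rows = []
    for _, arow in animals.iterrows():
        a, grp = arow["animal"], arow["group"]
        s_a = float(np.exp(rng.normal(0.0, ym.animal_scale_sd)))
        scale_g = ym.treated_scale if grp == "rbst" else 1.0
        dim0 = dim_treated if grp == "rbst" else dim_control
        t = days + dim0  # days in milk
        wood = ym.wood_a * np.power(t, ym.wood_b) * np.exp(-ym.wood_c * t)
        eff = 1.0 + (ym.treatment_boost * boost if grp == "rbst" else 0.0)
        kg = s_a * scale_g * wood * eff + rng.normal(0.0, ym.noise_sd, size=len(days))
        for d, y in zip(days, kg):
            rows.append((a, grp, int(d), float(max(y, 0.0))))
    return pd.DataFrame(rows, columns=["animal", "group", "day", "kg"])


# --- amplification curves ---------------------------------------------

def simulate_curves(expression: pd.DataFrame, config: SimulationConfig
                    ) -> pd.DataFrame:
    """Generate raw fluorescence curves for every expression record.

    Per replicate: logistic amplification
    ``X(c) = X0*E^c / (1 + X0*(E^c - 1)/K)`` with ``X0`` proportional to
    true abundance, fluorescence ``F(c) = f_s * (B + X(c)) + noise`` with
    the sample's session factor ``f_s``.  Undetected records give flat
    baseline-only curves.  Returns a long table (well, sample, animal,
    group, day, session, gene, replicate, cycle, fluorescence).
    """
    cp = config.curve_params
    factors = session_factors_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    cycles = np.arange(1, cp.n_cycles + 1)
    frames = []
    for idx, rec in enumerate(expression.itertuples(index=False)):
        E = cp.gene_efficiency(rec.gene)
        fs = factors.get(rec.session, 1.0)
        for rep in range(1, cp.n_replicates + 1):
            if rec.detected and np.isfinite(rec.abundance):
                x0 = cp.x0_scale * rec.abundance
                ec = np.power(E, cycles.astype(float))
                x = x0 * ec / (1.0 + x0 * (ec - 1.0) / cp.plateau_k)
            else:
                x = np.zeros_like(cycles, dtype=float)
            b = cp.baseline + rng.normal(0.0, cp.baseline_jitter_sd)
            f = fs * (b + x) + rng.normal(0.0, cp.noise_sd, size=len(cycles))
            frames.append(pd.DataFrame({
                "well": f"w{idx}_{rep}",
                "sample": rec.sample,
                "animal": rec.animal,
                "group": rec.group,
                "day": rec.day,
                "session": rec.session,
                "gene": rec.gene,
                "replicate": rep,
                "cycle": cycles,
                "fluorescence": f,
            }))
    return pd.concat(frames, ignore_index=True)


# --- convenience -------------------------------------------------------

def simulate_study(config: SimulationConfig, outdir: str | Path | None = None,
                   with_curves: bool = False) -> dict:
    """Run the full generator; optionally write CSVs plus ground truth JSON."""
    expression = simulate_expression(config)
    yields = simulate_yield(config)
    out = {"expression": expression, "yields": yields,
           "session_factors": session_factors_truth(config)}
    if with_curves:
        out["curves"] = simulate_curves(expression, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        expression.to_csv(outdir / "expression.csv", index=False)
        yields.to_csv(outdir / "yields.csv", index=False)
        if with_curves:
            out["curves"].to_csv(outdir / "curves.csv", index=False)
        truth = {
            "session_factors": out["session_factors"],
            "responsive_genes": [p.gene for p in config.profiles
                                 if p.responsive],
            "reference_genes": [p.gene for p in config.profiles
                                if p.is_reference],
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out
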