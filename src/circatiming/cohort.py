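"""Synthetic constant-routine cohorts: timing trials and melatonin series.

Emulates the study geometry — 18 subjects, two 38.67-h constant routines
(CR1 entrained, CR2 after a week of 28-h forced desynchrony), interval
timing sampled every 2 h (20 occasions per routine), each occasion crossing
{estimation, production} x {10 s, 40 s} with 3 trials per cell, and hourly
melatonin sampling with a known DLMO per subject-epoch.

Two generative backends:

* :func:`simulate_mechanistic` drives trial responses through the
  pacemaker-accumulator model (:mod:`circatiming.clock`) with
  subject-varying modulation parameters and multiplicative trial noise;
* :func:`simulate_from_lmm` draws occasion-level ratios directly from the
  random-coefficient trajectory model with chosen fixed effects (e.g., the
  published coefficients), for parameter-recovery experiments.

Both return a truth record holding every generating quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clock
from .dlmo import ASSAY_FLOOR_PGML
from .lmm import FIXED_TERMS, ModelSpec, build_design

__all__ = [
    "ProtocolConfig",
    "SubjectEffects",
    "REFERENCE_BETA",
    "DEFAULT_RE_SD",
    "DEFAULT_SIGMA_CELLS",
    "occasion_grid",
    "simulate_melatonin",
    "simulate_from_lmm",
    "simulate_mechanistic",
]

#: Fixed-effect coefficients (ratio units, % of target) reported for this
#: protocol's full trajectory model, used as the default generating truth
#: in recovery simulations.  Coding: TASK production=0/estimation=1,
#: STIM 10s=0/40s=1, CR CR1=0/CR2=1.
REFERENCE_BETA = {
    "Intercept": 102.13,
    "TASK": -2.38,
    "STIM": -4.72,
    "CR": 0.19,
    "exp": 2.24,
    "sin": 2.64,
    "cos": -0.92,
    "TASK:STIM": -2.84,
    "TASK:CR": 2.66,
    "TASK:exp": -17.19,
    "TASK:sin": -3.28,
    "TASK:cos": -0.63,
    "STIM:exp": 13.29,
    "STIM:sin": -2.05,
    "STIM:cos": 2.20,
}

#: Between-subject SDs for (intercept, task slope, stimulus slope), ratio units.
DEFAULT_RE_SD = (10.0, 5.0, 5.0)

#: Residual SD (ratio units) per task x stimulus cell; longer stimuli and
#: the estimation task are noisier.
DEFAULT_SIGMA_CELLS = {
    ("production", 10.0): 8.0,
    ("production", 40.0): 10.0,
    ("estimation", 10.0): 12.0,
    ("estimation", 40.0): 15.0,
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Geometry of the constant-routine protocol."""

    n_subjects: int = 18
    n_crs: int = 2
    cr_length_h: float = 38.67
    sampling_interval_h: float = 2.0
    melatonin_interval_h: float = 1.0
    tasks: tuple[str, ...] = ("estimation", "production")
    stimuli_s: tuple[float, ...] = (10.0, 40.0)
    trials_per_cell: int = 3
    dlmo_mean_h: float = 14.0  # hours from CR start (~22:00 for an 08:00 start)
    dlmo_sd_h: float = 1.0

    def __post_init__(self):
        if min(self.n_subjects, self.n_crs, self.trials_per_cell) < 1:
            raise ValueError("counts must be >= 1")
        if not (self.cr_length_h > self.sampling_interval_h > 0):
            raise ValueError("need cr_length_h > sampling_interval_h > 0")


@dataclass(frozen=True)
class SubjectEffects:
    """Subject-level random effects and true DLMO times (hours from CR start)."""

    b0: float
    b1: float
    b2: float
    dlmo_cr1: float
    dlmo_cr2: float

    def dlmo(self, cr: str) -> float:
        return self.dlmo_cr1 if cr == "CR1" else self.dlmo_cr2


@dataclass
class TruthRecord:
    """Every generating quantity of a simulated cohort."""

    backend: str
    beta: dict = field(default_factory=dict)
    re_sd: tuple = ()
    re_corr: np.ndarray | None = None
    sigma_cells: dict = field(default_factory=dict)
    subjects: dict[str, SubjectEffects] = field(default_factory=dict)
    pacemaker: dict = field(default_factory=dict)
    redraws: int = 0

    def dlmo_table(self) -> pd.DataFrame:
        rows = []
        for sid, eff in self.subjects.items():
            for cr in ("CR1", "CR2"):
                rows.append({"subject_id": sid, "cr": cr, "dlmo_h": eff.dlmo(cr)})
        return pd.DataFrame(rows)

    def flat(self) -> dict:
        """Key-value view for the flat truth file."""
        out = {"backend": self.backend, "redraws": self.redraws}
        for k, v in self.beta.items():
            out[f"beta.{k}"] = v
        for i, s in enumerate(self.re_sd):
            out[f"re_sd.{i}"] = s
        for (task, stim), s in self.sigma_cells.items():
            out[f"sigma.{task}.{stim:g}"] = s
        for k, v in self.pacemaker.items():
            out[f"pacemaker.{k}"] = v
        for sid, eff in self.subjects.items():
            out[f"subject.{sid}.b0"] = eff.b0
            out[f"subject.{sid}.b1"] = eff.b1
            out[f"subject.{sid}.b2"] = eff.b2
            out[f"subject.{sid}.dlmo_cr1"] = eff.dlmo_cr1
            out[f"subject.{sid}.dlmo_cr2"] = eff.dlmo_cr2
        return out


def occasion_grid(cfg: ProtocolConfig) -> np.ndarray:
    """Occasion times (hours since CR start): 0, 2, ..., within the CR window."""
    return np.arange(0.0, cfg.cr_length_h, cfg.sampling_interval_h)


def _subject_ids(cfg: ProtocolConfig):
    return [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]


def _crs(cfg: ProtocolConfig):
    return [f"CR{k + 1}" for k in range(cfg.n_crs)]


def _draw_subjects(cfg, rng, re_sd, re_corr=None) -> dict[str, SubjectEffects]:
    sd = np.asarray(re_sd, dtype=float)
    C = np.eye(3) if re_corr is None else np.asarray(re_corr, dtype=float)
    cov = np.outer(sd, sd) * C
    out = {}
    for sid in _subject_ids(cfg):
        b = rng.multivariate_normal(np.zeros(3), cov) if np.any(sd > 0) else np.zeros(3)
        d1 = rng.normal(cfg.dlmo_mean_h, cfg.dlmo_sd_h)
        d2 = rng.normal(cfg.dlmo_mean_h, cfg.dlmo_sd_h)
        out[sid] = SubjectEffects(float(b[0]), float(b[1]), float(b[2]), float(d1), float(d2))
    return out


def simulate_melatonin(
    dlmo_h: float,
    cfg: ProtocolConfig = ProtocolConfig(),
    mesor: float = 10.0,
    amplitude: float = 8.0,
    noise_log_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hourly melatonin profile with a known DLMO.

    The noiseless profile is ``mesor + amplitude * cos(2*pi*(t - (dlmo+6))/24)``:
    a nocturnal peak 6 h after the DLMO, so the upward crossing of the mesor
    falls exactly at ``dlmo_h``.  With the default mesor at the 10 pg/ml
    threshold the true DLMO is the threshold crossing itself.  Multiplicative
    lognormal noise (``noise_log_sd`` on the log scale) keeps concentrations
    positive; values are floored at the assay sensitivity (2.8 pg/ml).
    """
    if rng is None:
        rng = np.random.default_rng()
    times = np.arange(0.0, cfg.cr_length_h + 1e-9, cfg.melatonin_interval_h)
    conc = mesor + amplitude * np.cos(2 * np.pi * (times - (dlmo_h + 6.0)) / 24.0)
    if noise_log_sd > 0:
        conc = conc * np.exp(rng.normal(0.0, noise_log_sd, size=conc.shape))
    conc = np.maximum(conc, ASSAY_FLOOR_PGML)
    return pd.DataFrame({"time_h": times, "conc_pgml": conc})


def _melatonin_table(cfg, subjects, noise_log_sd, rng) -> pd.DataFrame:
    frames = []
    for sid, eff in subjects.items():
        for cr in _crs(cfg):
            mel = simulate_melatonin(
                eff.dlmo(cr), cfg, noise_log_sd=noise_log_sd, rng=rng
            )
            mel.insert(0, "cr", cr)
            mel.insert(0, "subject_id", sid)
            frames.append(mel)
    return pd.concat(frames, ignore_index=True)


def _occasion_frame(cfg, subjects) -> pd.DataFrame:
    """Cartesian product of the occasion design with DLMO-referenced time."""
    occ_t = occasion_grid(cfg)
    rows = []
    for sid, eff in subjects.items():
        for cr in _crs(cfg):
            dlmo = eff.dlmo(cr)
            for ot in occ_t:
                for task in cfg.tasks:
                    for stim in cfg.stimuli_s:
                        rows.append(
                            (sid, cr, float(ot), task, float(stim), float(ot - dlmo))
                        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "cr", "occasion_time_h", "task", "stimulus_s", "t_dlmo_h"],
    )


def simulate_from_lmm(
    cfg: ProtocolConfig = ProtocolConfig(),
    beta: dict | None = None,
    re_sd=DEFAULT_RE_SD,
    re_corr=None,
    sigma_cells: dict | None = None,
    spec: ModelSpec = ModelSpec(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Simulate occasion-level ratios directly from the trajectory model.

    ``beta`` maps term names (see :data:`circatiming.lmm.FIXED_TERMS`) to
    coefficients; defaults to :data:`REFERENCE_BETA`.  Returns
    ``(occasion_table, truth)`` where the table carries ``ratio`` outcomes
    y = X beta + Z b_i + eps with per-cell residual SDs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if beta is None:
        beta = dict(REFERENCE_BETA)
    missing = set(spec.fixed_terms) - set(beta)
    if missing:
        raise ValueError(f"beta missing terms: {sorted(missing)}")
    if sigma_cells is None:
        sigma_cells = dict(DEFAULT_SIGMA_CELLS)
    subjects = _draw_subjects(cfg, rng, re_sd, re_corr)
    occ = _occasion_frame(cfg, subjects)
    X, Z, subj_labels, _ = build_design(occ, spec)
    beta_vec = np.asarray([beta[t] for t in spec.fixed_terms], dtype=float)
    b_mat = np.asarray(
        [[subjects[s].b0, subjects[s].b1, subjects[s].b2] for s in subj_labels]
    )
    # restrict b to the spec's random terms (same order as Z columns)
    ridx = [("Intercept", "TASK", "STIM").index(t) for t in spec.random_terms]
    rand_part = np.einsum("ij,ij->i", Z, b_mat[:, ridx])
    sig = np.asarray(
        [sigma_cells[(task, stim)] for task, stim in zip(occ["task"], occ["stimulus_s"])]
    )
    eps = rng.normal(0.0, 1.0, size=len(occ)) * sig
    occ = occ.copy()
    occ["ratio"] = X @ beta_vec + rand_part + eps
    truth = TruthRecord(
        backend="lmm",
        beta=dict(beta),
        re_sd=tuple(re_sd),
        re_corr=np.eye(3) if re_corr is None else np.asarray(re_corr),
        sigma_cells=dict(sigma_cells),
        subjects=subjects,
    )
    return occ, truth


DEFAULT_PACEMAKER = clock.PacemakerParams(
    r_ref=1.0, h_amp=0.15, tau_h=18.2, c_amp=0.05, c_phase=16.0, leak_kappa=0.01
)

#: Between-subject SDs of the mechanistic modulation parameters.
DEFAULT_PACEMAKER_SD = {"h_amp": 0.05, "c_amp": 0.02, "c_phase": 1.0}


def _draw_pacemaker(pop: clock.PacemakerParams, sds: dict, rng) -> tuple[clock.PacemakerParams, int]:
    """Perturb modulation parameters, redrawing invalid combinations."""
    redraws = 0
    for _ in range(1000):
        h = pop.h_amp + rng.normal(0.0, sds.get("h_amp", 0.0))
        c = pop.c_amp + rng.normal(0.0, sds.get("c_amp", 0.0))
        ph = pop.c_phase + rng.normal(0.0, sds.get("c_phase", 0.0))
        if h >= 0 and c >= 0 and h + c < 1:
            return (
                clock.PacemakerParams(
                    r_ref=pop.r_ref, h_amp=h, tau_h=pop.tau_h, c_amp=c,
                    c_phase=ph, period=pop.period, leak_kappa=pop.leak_kappa,
                    t_wake_offset=pop.t_wake_offset,
                ),
                redraws,
            )
        redraws += 1
    raise RuntimeError("could not draw valid pacemaker parameters in 1000 tries")


def simulate_mechanistic(
    cfg: ProtocolConfig = ProtocolConfig(),
    pop: clock.PacemakerParams = DEFAULT_PACEMAKER,
    pacemaker_sd: dict | None = None,
    sigma_cells: dict | None = None,
    melatonin_noise_log_sd: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Simulate trial-level responses through the pacemaker-accumulator model.

    Each subject gets perturbed modulation parameters (invalid draws giving
    non-positive rates are rejected and redrawn, counted in the truth
    record).  Trial noise is applied multiplicatively on the log response so
    responses stay positive; the per-cell residual SDs (ratio units) are
    mapped to log-scale SDs by dividing by 100.

    Returns ``(trial_table, melatonin_table, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if pacemaker_sd is None:
        pacemaker_sd = dict(DEFAULT_PACEMAKER_SD)
    if sigma_cells is None:
        sigma_cells = dict(DEFAULT_SIGMA_CELLS)
    subjects = _draw_subjects(cfg, rng, (0.0, 0.0, 0.0))
    params = {}
    total_redraws = 0
    for sid in subjects:
        params[sid], nre = _draw_pacemaker(pop, pacemaker_sd, rng)
        total_redraws += nre
    occ_t = occasion_grid(cfg)
    rows = []
    for sid, eff in subjects.items():
        p = params[sid]
        for cr in _crs(cfg):
            dlmo = eff.dlmo(cr)
            for ot in occ_t:
                t = ot - dlmo
                for task in cfg.tasks:
                    for stim in cfg.stimuli_s:
                        est, prod = clock.expected_responses(t, stim, p)
                        mean_resp = est if task == "estimation" else prod
                        log_sd = sigma_cells[(task, stim)] / 100.0
                        for k in range(cfg.trials_per_cell):
                            noise = rng.normal(0.0, log_sd) if log_sd > 0 else 0.0
                            rows.append(
                                (sid, cr, float(ot), task, float(stim), k + 1,
                                 float(mean_resp * np.exp(noise)))
                            )
    trials = pd.DataFrame(
        rows,
        columns=["subject_id", "cr", "occasion_time_h", "task", "stimulus_s",
                 "trial_index", "response_s"],
    )
    melatonin = _melatonin_table(cfg, subjects, melatonin_noise_log_sd, rng)
    truth = TruthRecord(
        backend="mechanistic",
        sigma_cells=dict(sigma_cells),
        subjects=subjects,
        pacemaker={
            "pop.r_ref": pop.r_ref, "pop.h_amp": pop.h_amp, "pop.tau_h": pop.tau_h,
            "pop.c_amp": pop.c_amp, "pop.c_phase": pop.c_phase,
            "pop.leak_kappa": pop.leak_kappa,
            **{f"{sid}.{k}": getattr(params[sid], k)
               for sid in params for k in ("h_amp", "c_amp", "c_phase")},
        },
        redraws=total_redraws,
    )
    return trials, melatonin, truth
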