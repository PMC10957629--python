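"""Synthetic crossover studies with known ground truth.

Emulates a protein-uptake crossover trial: 12 participants, three protein
shakes (one the reference), three periods in a balanced rotation so Period
and Intervention are orthogonal, ten blood samples within 180 minutes, and
the nine essential amino acids as analytes. Each series is an exact Wood
curve perturbed by participant-level effects — an additive baseline shift
on d and a multiplicative log-normal shift on the amplitude a, mirroring
the random intercept of the downstream mixed model — plus additive Gaussian
measurement noise, constant per analyte. Non-responder series (optional)
get an amplitude drawn near zero. Washout is assumed perfect: no carryover
is modelled, but an additive Period effect is available to exercise the
Period fixed effect.

Every generated study comes with a ground-truth table holding the true
per-series curve parameters and the true PoIs computed from them with the
same closed forms the analysis uses, so recovery can be scored exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import LONG_COLUMNS, StudyTable
from .errors import ConfigurationError
from .pois import poi_auc, poi_height, poi_time2max
from .woodcurve import WoodParams, wood_eval

#: the nine essential amino acids
EAA = ("His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val")

#: per-analyte (baseline d, peak height, time-to-max m, decay c) for the
#: reference intervention: fasting plasma levels and postprandial excursions
#: in the range reported for adults after a protein meal (umol/L, minutes)
_REF_CURVES = {
    "His": (80.0, 30.0, 45.0, 0.030),
    "Ile": (60.0, 120.0, 40.0, 0.040),
    "Leu": (130.0, 180.0, 40.0, 0.040),
    "Lys": (180.0, 150.0, 45.0, 0.035),
    "Met": (25.0, 30.0, 40.0, 0.040),
    "Phe": (60.0, 40.0, 45.0, 0.030),
    "Thr": (140.0, 80.0, 50.0, 0.030),
    "Trp": (55.0, 35.0, 50.0, 0.030),
    "Val": (230.0, 160.0, 45.0, 0.035),
}

#: (amplitude multiplier, shift of m in minutes) per intervention: the two
#: test proteins digest slower and less completely than the reference
_INTERVENTION_MODS = {"REF": (1.00, 0.0), "TESTA": (0.85, 8.0), "TESTB": (0.70, 15.0)}


def _amplitude_for_height(height: float, m: float, c: float) -> float:
    """Invert Height = a*(b/c)^b*e^-b = a*exp(b*(ln m - 1)) for a."""
    b = m * c
    return height * math.exp(-b * (math.log(m) - 1.0))


def default_true_params() -> dict[tuple[str, str], WoodParams]:
    """Population-mean Wood parameters per (intervention, analyte)."""
    out = {}
    for intervention, (amp_mult, m_shift) in _INTERVENTION_MODS.items():
        for analyte, (d, height, m, c) in _REF_CURVES.items():
            m_i = m + m_shift
            a = _amplitude_for_height(height * amp_mult, m_i, c)
            out[(intervention, analyte)] = WoodParams(a=a, m=m_i, c=c, d=d)
    return out


@dataclass
class SimDesign:
    """Generative description of a synthetic crossover study."""

    n_participants: int = 12
    interventions: tuple[str, ...] = ("REF", "TESTA", "TESTB")
    reference: str = "REF"
    n_periods: int = 3
    times: tuple[float, ...] = (0, 15, 30, 45, 60, 75, 90, 120, 150, 180)
    analytes: tuple[str, ...] = EAA
    true_params: dict[tuple[str, str], WoodParams] = field(
        default_factory=default_true_params)
    baseline_shift_sd: float = 10.0    # additive on d, per participant x analyte
    log_amplitude_sd: float = 0.15     # multiplicative log-normal on a
    noise_sd: float = 5.0              # residual measurement sd, umol/L
    period_effects: tuple[float, ...] | None = None   # additive shift per period
    nonresponse_rate: float = 0.0      # P(participant x analyte series is flat)
    seed: int = 0
    assignment: list[list[str]] | None = None  # per participant, per period

    def __post_init__(self):
        if self.reference not in self.interventions:
            raise ConfigurationError(
                f"reference {self.reference!r} not among {self.interventions}")
        if not 0 <= self.nonresponse_rate <= 1:
            raise ConfigurationError("nonresponse_rate must lie in [0, 1]")
        if min(self.baseline_shift_sd, self.log_amplitude_sd, self.noise_sd) < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.n_periods > len(self.interventions):
            raise ConfigurationError("more periods than interventions")

    def default_assignment(self) -> list[list[str]]:
        """Balanced rotation: participant i starts at intervention i mod k."""
        k = len(self.interventions)
        return [[self.interventions[(i + p) % k] for p in range(self.n_periods)]
                for i in range(self.n_participants)]


def supro_like_design(seed: int = 0, **overrides) -> SimDesign:
    """The default 12-participant, 3-intervention, 9-analyte design."""
    return SimDesign(seed=seed, **overrides)


def simulate_study(design: SimDesign) -> tuple[StudyTable, pd.DataFrame]:
    """Generate one study and its ground truth, reproducibly from the seed.

    Returns
    -------
    (StudyTable,
     ground-truth DataFrame: participant, intervention, analyte, true curve
     parameters, true PoIs at t_f = last sampling time, nonresponder flag).
    """
    assignment = design.assignment or design.default_assignment()
    if len(assignment) != design.n_participants or any(
            len(seq) != design.n_periods for seq in assignment):
        raise ConfigurationError("assignment plan does not match design dimensions")
    for seq in assignment:
        if len(set(seq)) != len(seq):
            raise ConfigurationError("a participant receives an intervention twice")

    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.times, float)
    t_f = float(times.max())
    period_fx = (np.asarray(design.period_effects, float)
                 if design.period_effects is not None
                 else np.zeros(design.n_periods))

    participants = [f"P{i+1:02d}" for i in range(design.n_participants)]
    # participant-level effects, shared across interventions (random intercepts)
    base_shift = rng.normal(0.0, design.baseline_shift_sd,
                            (design.n_participants, len(design.analytes)))
    amp_shift = rng.normal(0.0, design.log_amplitude_sd,
                           (design.n_participants, len(design.analytes)))
    nonresp = rng.random((design.n_participants, len(design.analytes))) < design.nonresponse_rate
    nonresp_amp = rng.uniform(0.0, 0.02, (design.n_participants, len(design.analytes)))

    records, truth_rows = [], []
    for i, pid in enumerate(participants):
        for p in range(design.n_periods):
            intervention = assignment[i][p]
            for j, analyte in enumerate(design.analytes):
                pop = design.true_params[(intervention, analyte)]
                a_true = pop.a * math.exp(amp_shift[i, j])
                if nonresp[i, j]:
                    a_true = pop.a * nonresp_amp[i, j]
                d_true = max(pop.d + base_shift[i, j], 0.0)
                truth = WoodParams(a=a_true, m=pop.m, c=pop.c, d=d_true)
                curve = wood_eval(truth, times) + period_fx[p]
                noise = rng.normal(0.0, design.noise_sd, times.size)
                for t, v in zip(times, curve + noise):
                    records.append((pid, p + 1, intervention, float(t),
                                    analyte, float(v)))
                truth_rows.append({
                    "participant": pid, "intervention": intervention,
                    "analyte": analyte, "period": p + 1,
                    "a": truth.a, "m": truth.m, "c": truth.c, "d": truth.d,
                    "b": truth.b, "t_f": t_f,
                    "auc": poi_auc(truth, t_f), "height": poi_height(truth),
                    "time2max": poi_time2max(truth),
                    "nonresponder": bool(nonresp[i, j]),
                })
    data = pd.DataFrame(records, columns=LONG_COLUMNS)
    table = StudyTable(data, reference_intervention=design.reference,
                       analyte_roster=list(design.analytes))
    return table, pd.DataFrame(truth_rows)


def simulate_effect_scenario(base: SimDesign, auc_ratio: float = 1.0,
                             height_diff: float | None = None,
                             test_interventions: tuple[str, ...] | None = None,
                             ) -> SimDesign:
    """Derive a design with controlled true effects versus the reference.

    Test-intervention population curves are rebuilt from the reference
    curves so that the true AUC equals ``auc_ratio`` times the reference AUC
    (the AUC is linear in the amplitude a, so scaling a by the ratio with
    the shape (m, c) fixed is exact). ``height_diff`` (None = unconstrained) is honored when it is
    consistent with that scaling; since Height is also linear in a, both
    constraints can hold together only when
    height_diff == (auc_ratio - 1) * reference Height. On conflict the AUC
    ratio wins and the realized height difference appears in the returned
    design's ground truth (a note is printed to the log).
    """
    if not auc_ratio > 0:
        raise ConfigurationError(f"auc_ratio must be positive, got {auc_ratio}")
    tests = test_interventions or tuple(
        i for i in base.interventions if i != base.reference)
    unknown = set(tests) - set(base.interventions)
    if unknown:
        raise ConfigurationError(f"unknown test interventions: {sorted(unknown)}")

    new_params = dict(base.true_params)
    for analyte in base.analytes:
        ref = base.true_params[(base.reference, analyte)]
        ref_height = poi_height(ref)
        realized_diff = (auc_ratio - 1.0) * ref_height
        if height_diff is not None and \
                abs(realized_diff - height_diff) > 1e-9 * max(1.0, ref_height):
            logging.getLogger(__name__).info(
                "%s: requested height_diff %.4g conflicts with auc_ratio %.4g; "
                "AUC constraint honored, realized height diff %.4g",
                analyte, height_diff, auc_ratio, realized_diff)
        for lev in tests:
            new_params[(lev, analyte)] = replace(ref, a=ref.a * auc_ratio)
    return replace(base, true_params=new_params)
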