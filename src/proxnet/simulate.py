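"""Synthetic proximity data with planted latent subnetworks.

The generator mirrors the analysis model: K planted subnetworks, each a
participant subset with nonnegative internal tie weights (a row of
U_true) and a temporal activity schedule (a column of H_true), are
superposed into a rate matrix H_true @ U_true and observed as per-epoch
dyadic counts under a Poisson or rounding observation model.  Three
schedule templates cover the qualitative regimes of interest: sparse
large event-day spikes, low-level daily daytime activity, and a
weekday-daytime hub pattern with a midday dip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import scipy.optimize
import yaml

from proxnet import codebook
from proxnet.contacts import (ContactMatrix, DyadIndex, EpochGrid,
                              build_dyad_index, build_epoch_grid)
from proxnet.io import DetectionRecord
from proxnet.nmf import FactorModel


@dataclass
class FactorSpec:
    """One planted subnetwork: membership size, tie weights, schedule."""

    name: str
    kind: str                     # "event" | "diurnal" | "hub"
    membership_size: int
    weight_low: float = 0.5
    weight_high: float = 1.5
    amplitude: float = 1.0
    event_days: list[date] = field(default_factory=list)
    # daily active window, within-day slots in hours
    start_hour: float = 8.0
    end_hour: float = 17.0
    weekdays_only: bool = False
    midday_dip: bool = False
    epoch_jitter: float = 0.0     # +/- fractional per-epoch level variation

    def __post_init__(self) -> None:
        if self.kind not in ("event", "diurnal", "hub"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.membership_size < 2:
            raise ValueError("membership_size must be >= 2")
        if self.amplitude < 0 or self.weight_low < 0:
            raise ValueError("rates and weights must be nonnegative")


@dataclass
class ScenarioConfig:
    """Generator settings for one synthetic community."""

    n_participants: int = 30
    start_date: date = date(2018, 1, 1)
    end_date: date = date(2018, 2, 11)   # 42 days -> 2016 epochs at 30 min
    epoch_minutes: int = 30
    factors: list[FactorSpec] = field(default_factory=list)
    disjoint_memberships: bool = True
    cap: int = 12                        # 2 directions x 6 scans per 30-min epoch
    noise_model: str = "poisson"

    def __post_init__(self) -> None:
        if self.cap is not None and self.cap < 0:
            raise ValueError("cap must be nonnegative")
        for spec in self.factors:
            for d in spec.event_days:
                if not self.start_date <= d <= self.end_date:
                    raise ValueError(f"event day {d} outside the grid")

    def grid(self) -> EpochGrid:
        return build_epoch_grid(self.start_date, self.end_date, self.epoch_minutes)

    def participant_ids(self) -> list[str]:
        width = max(2, len(str(self.n_participants - 1)))
        return [f"p{i:0{width}d}" for i in range(self.n_participants)]


def default_scenario() -> ScenarioConfig:
    """Packaged benchmark scenario: N=30, 3 disjoint subnetworks of 10,
    6 weeks of 30-minute epochs (I=2016)."""
    start = date(2018, 1, 1)
    return ScenarioConfig(
        n_participants=30,
        start_date=start,
        end_date=start + timedelta(days=41),
        factors=[
            FactorSpec(name="farm_events", kind="event", membership_size=10,
                       amplitude=2.0, epoch_jitter=0.8,
                       event_days=[start + timedelta(days=d)
                                   for d in (6, 13, 20, 27, 34)]),
            FactorSpec(name="family_diurnal", kind="diurnal", membership_size=10,
                       amplitude=1.2, start_hour=6.0, end_hour=22.0,
                       epoch_jitter=0.8),
            FactorSpec(name="hall_hub", kind="hub", membership_size=10,
                       amplitude=1.0, start_hour=8.5, end_hour=17.0,
                       weekdays_only=True, midday_dip=True, epoch_jitter=0.8),
        ],
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth against which recovery is scored."""

    config: ScenarioConfig
    participants: list[str]
    grid: EpochGrid
    dyads: DyadIndex
    memberships: list[set[str]]
    H_true: np.ndarray            # I x K
    U_true: np.ndarray            # K x J
    seed: int

    @property
    def K_true(self) -> int:
        return len(self.memberships)


def _schedule(spec: FactorSpec, grid: EpochGrid, rng: np.random.Generator) -> np.ndarray:
    """Build one H_true column from a layer template."""
    col = np.zeros(grid.n_epochs)
    per_day = grid.epochs_per_day
    slot_hours = grid.epoch_minutes / 60.0
    lo = int(spec.start_hour / slot_hours)
    hi = int(math.ceil(spec.end_hour / slot_hours))
    event_days = {d for d in spec.event_days}
    for day in range(grid.n_days):
        day_date = grid.start_date + timedelta(days=day)
        if spec.kind == "event":
            if day_date not in event_days:
                continue
        elif spec.weekdays_only and day_date.weekday() >= 5:
            continue
        base = spec.amplitude * rng.uniform(0.8, 1.2)
        for slot in range(lo, min(hi, per_day)):
            level = base
            hour = slot * slot_hours
            if spec.kind == "diurnal" and 9.0 <= hour < 17.0:
                continue  # at-home contacts: morning and evening only
            if spec.midday_dip and 12.0 <= hour < 13.0:
                level *= 0.3
            if spec.epoch_jitter > 0:
                level *= rng.uniform(1 - spec.epoch_jitter, 1 + spec.epoch_jitter)
            col[day * per_day + slot] = level
    return col


def generate_truth(config: ScenarioConfig, seed: int = 0) -> SyntheticTruth:
    """Draw memberships, tie weights and schedules; deterministic per seed."""
    if not config.factors:
        raise ValueError("scenario has no factor specs")
    total = sum(s.membership_size for s in config.factors)
    if config.disjoint_memberships and total > config.n_participants:
        raise ValueError(f"disjoint memberships need {total} participants, "
                         f"have {config.n_participants}")
    for s in config.factors:
        if s.membership_size > config.n_participants:
            raise ValueError(f"membership of {s.name} exceeds N")
    rng = np.random.default_rng(seed)
    participants = config.participant_ids()
    grid = config.grid()
    dyads = build_dyad_index(participants)

    memberships: list[set[str]] = []
    if config.disjoint_memberships:
        pool = list(rng.permutation(participants))
        for s in config.factors:
            memberships.append({pool.pop() for _ in range(s.membership_size)})
    else:
        for s in config.factors:
            memberships.append(set(rng.choice(participants, size=s.membership_size,
                                              replace=False)))

    K = len(config.factors)
    U_true = np.zeros((K, dyads.n_dyads))
    for k, (spec, members) in enumerate(zip(config.factors, memberships)):
        for j, (a, b) in enumerate(dyads.pairs):
            if a in members and b in members:
                U_true[k, j] = rng.uniform(spec.weight_low, spec.weight_high)
    H_true = np.column_stack([_schedule(spec, grid, rng)
                              for spec in config.factors])
    return SyntheticTruth(config=config, participants=participants, grid=grid,
                          dyads=dyads, memberships=memberships,
                          H_true=H_true, U_true=U_true, seed=seed)


def observe_contacts(truth: SyntheticTruth, noise_model: str | None = None,
                     cap: int | None = None, seed: int = 0) -> ContactMatrix:
    """Observe the superposed rate matrix as per-epoch dyadic counts.

    ``poisson``: y_ij ~ Poisson(sum_k h_ik u_kj), truncated at the cap;
    ``rounded``: y_ij = round(sum_k h_ik u_kj).
    """
    noise_model = noise_model or truth.config.noise_model
    cap = truth.config.cap if cap is None else cap
    if cap is not None and cap < 0:
        raise ValueError("cap must be nonnegative")
    rate = truth.H_true @ truth.U_true
    if noise_model == "poisson":
        rng = np.random.default_rng(seed)
        Y = rng.poisson(rate)
    elif noise_model == "rounded":
        Y = np.rint(rate).astype(np.int64)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    if cap is not None:
        Y = np.minimum(Y, cap)
    return ContactMatrix(Y.astype(np.int64), truth.grid, truth.dyads)


def emit_detection_log(cm: ContactMatrix, seed: int = 0) -> list[DetectionRecord]:
    """Expand counts into detection records (round-trip exact under rule=sum).

    Each count y_ij becomes y_ij records for dyad j with timestamps
    uniform within epoch i and directions alternating A->B, B->A, ...
    Records are emitted in epoch-major order, sorted by time within an
    epoch cell.
    """
    rng = np.random.default_rng(seed)
    grid, dyads = cm.grid, cm.dyads
    epoch_seconds = grid.epoch_minutes * 60
    records: list[DetectionRecord] = []
    rows, cols = np.nonzero(cm.Y)
    for i, j in zip(rows.tolist(), cols.tolist()):
        y = int(cm.Y[i, j])
        a, b = dyads.pair(j)
        start = grid.epoch_start(i)
        offsets = sorted(rng.uniform(0, epoch_seconds, size=y).tolist())
        for m, off in enumerate(offsets):
            ts = start + timedelta(seconds=off)
            obs, seen = (a, b) if m % 2 == 0 else (b, a)
            records.append(DetectionRecord(ts, obs, seen))
    return records


@dataclass
class RecoveryReport:
    """Factor-matched agreement between a fit and the planted truth."""

    assignment: list[int]           # truth factor k -> model factor assignment[k]
    u_correlations: list[float]
    h_correlations: list[float]
    membership_precision: list[float]
    membership_recall: list[float]

    @property
    def mean_u_correlation(self) -> float:
        vals = [c for c in self.u_correlations if not np.isnan(c)]
        return float(np.mean(vals)) if vals else float("nan")


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_recovery(truth: SyntheticTruth, model: FactorModel,
                      membership_threshold: float = 0.2) -> RecoveryReport:
    """Match fitted factors to planted ones and score the agreement.

    Factors are paired by maximizing total Pearson correlation between
    U rows (Hungarian assignment; constant rows contribute 0 and report
    NaN).  Membership precision/recall compares the planted member sets
    to participants whose strongest within-factor tie exceeds
    ``membership_threshold`` times the factor's maximum weight.
    """
    K = truth.K_true
    if model.K < K:
        raise ValueError(f"model rank {model.K} is below planted rank {K}")
    corr = np.zeros((K, model.K))
    for kt in range(K):
        for km in range(model.K):
            c = _safe_corr(truth.U_true[kt], model.U[km])
            corr[kt, km] = 0.0 if np.isnan(c) else c
    row, col = scipy.optimize.linear_sum_assignment(-corr)
    assignment = [int(col[list(row).index(kt)]) for kt in range(K)]

    u_corrs, h_corrs, precs, recs = [], [], [], []
    for kt in range(K):
        km = assignment[kt]
        u_corrs.append(_safe_corr(truth.U_true[kt], model.U[km]))
        h_corrs.append(_safe_corr(truth.H_true[:, kt], model.H[:, km]))
        row_u = model.U[km]
        strength = {p: 0.0 for p in truth.participants}
        for j, (a, b) in enumerate(truth.dyads.pairs):
            strength[a] = max(strength[a], row_u[j])
            strength[b] = max(strength[b], row_u[j])
        cut = membership_threshold * max(row_u.max(), 1e-300)
        inferred = {p for p, s in strength.items() if s > cut}
        planted = truth.memberships[kt]
        tp = len(inferred & planted)
        precs.append(tp / len(inferred) if inferred else float("nan"))
        recs.append(tp / len(planted) if planted else float("nan"))
    return RecoveryReport(assignment, u_corrs, h_corrs, precs, recs)


def planted_tie_strength(truth: SyntheticTruth) -> np.ndarray:
    """N x K matrix of each participant's total planted tie weight per factor."""
    S = np.zeros((len(truth.participants), truth.K_true))
    pidx = {p: i for i, p in enumerate(truth.participants)}
    for k in range(truth.K_true):
        for j, (a, b) in enumerate(truth.dyads.pairs):
            w = truth.U_true[k, j]
            S[pidx[a], k] += w
            S[pidx[b], k] += w
    return S


def generate_survey(truth: SyntheticTruth, effect_map: dict[str, tuple[int, float]],
                    seed: int = 0, missing_rate: float = 0.0) -> pd.DataFrame:
    """Survey responses driven by planted factor tie strengths.

    ``effect_map`` sends an item code to ``(factor_index, beta)``: the
    item's latent mean shifts by ``beta`` times the participant's
    standardized total tie weight in that factor.  Items within a
    multi-item scale additionally share a per-participant latent trait
    (loading 0.8; the reverse-keyed openness item loads negatively and
    weakly) so each scale has realistic internal consistency.  Responses
    are the latent value plus unit Gaussian noise, rounded and clipped
    to the item's scale range.
    """
    rng = np.random.default_rng(seed)
    strengths = planted_tie_strength(truth)
    z = np.zeros_like(strengths)
    for k in range(strengths.shape[1]):
        s = strengths[:, k]
        z[:, k] = (s - s.mean()) / s.std() if s.std() > 0 else 0.0

    ranges = {}
    for cfg in codebook.SCALES.values():
        for it in cfg["items"]:
            ranges[it] = cfg["range"]
    ranges["happiness"] = codebook.SINGLE_ITEMS["happiness"]["range"]
    ranges["subjective_health"] = codebook.SINGLE_ITEMS["subjective_health"]["range"]

    n = len(truth.participants)
    scale_of_item = {it: name for name, cfg in codebook.SCALES.items()
                     for it in cfg["items"]}
    traits = {name: rng.normal(size=n) for name in codebook.SCALES}
    data: dict[str, np.ndarray] = {}
    for item in codebook.ALL_ITEMS:
        lo, hi = ranges[item]
        mid = (lo + hi) / 2.0
        latent = np.full(n, mid, dtype=float)
        scale = scale_of_item.get(item)
        if scale is not None:
            loading = -0.3 if item == "op_problems" else 0.8
            latent = latent + loading * traits[scale]
        if item in effect_map:
            k, beta = effect_map[item]
            latent = latent + beta * z[:, k]
        latent = latent + rng.normal(0.0, 1.0, size=n)
        resp = np.clip(np.rint(latent), lo, hi)
        if missing_rate > 0:
            mask = rng.uniform(size=n) < missing_rate
            resp = resp.astype(float)
            resp[mask] = np.nan
        data[item] = resp
    return pd.DataFrame(data, index=pd.Index(truth.participants,
                                             name="participant_id"))


# ---------------------------------------------------------------------------
# config (de)serialization

def scenario_to_dict(config: ScenarioConfig) -> dict:
    return {
        "n_participants": config.n_participants,
        "start_date": config.start_date.isoformat(),
        "end_date": config.end_date.isoformat(),
        "epoch_minutes": config.epoch_minutes,
        "disjoint_memberships": config.disjoint_memberships,
        "cap": config.cap,
        "noise_model": config.noise_model,
        "factors": [
            {
                "name": s.name, "kind": s.kind,
                "membership_size": s.membership_size,
                "weight_low": s.weight_low, "weight_high": s.weight_high,
                "amplitude": s.amplitude,
                "event_days": [d.isoformat() for d in s.event_days],
                "start_hour": s.start_hour, "end_hour": s.end_hour,
                "weekdays_only": s.weekdays_only, "midday_dip": s.midday_dip,
            }
            for s in config.factors
        ],
    }


def scenario_from_dict(d: dict) -> ScenarioConfig:
    factors = [
        FactorSpec(
            name=f["name"], kind=f["kind"],
            membership_size=int(f["membership_size"]),
            weight_low=float(f.get("weight_low", 0.5)),
            weight_high=float(f.get("weight_high", 1.5)),
            amplitude=float(f.get("amplitude", 1.0)),
            event_days=[date.fromisoformat(x) for x in f.get("event_days", [])],
            start_hour=float(f.get("start_hour", 8.0)),
            end_hour=float(f.get("end_hour", 17.0)),
            weekdays_only=bool(f.get("weekdays_only", False)),
            midday_dip=bool(f.get("midday_dip", False)),
        )
        for f in d.get("factors", [])
    ]
    return ScenarioConfig(
        n_participants=int(d["n_participants"]),
        start_date=date.fromisoformat(d["start_date"]),
        end_date=date.fromisoformat(d["end_date"]),
        epoch_minutes=int(d.get("epoch_minutes", 30)),
        factors=factors,
        disjoint_memberships=bool(d.get("disjoint_memberships", True)),
        cap=d.get("cap", 12),
        noise_model=d.get("noise_model", "poisson"),
    )


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(config), fh, sort_keys=False)
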