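"""Synthetic cohort generator for facial action-unit streams.

Emulates the data the pipeline was designed for: per-participant OpenFace
2.0 frame streams over 18 AUs and a clinical table (UHR cases vs healthy
controls).  Each AU evolves as an independent two-state (active/inactive)
Markov chain; the presence channel is the current state and the intensity
channel is drawn from a state-conditional scaled Beta (inactive: on
[0, 5] concentrated near 0; active: on [1, 5]).

The chain is parameterised through the three headline metrics it should
realize for each participant (proportion of frames with intensity>1, mean
intensity, switch proportion): baseline per-AU latent metrics get Gaussian
between-participant heterogeneity plus additive group / antipsychotic
shifts, and the chain's (p_on, p_off) and active-state Beta mean are
solved in closed form to hit those targets.  The solved latent values are
recorded per participant (``true_metrics``) so recovery tests can compare
realized statistics against known ground truth.

Clinician ratings and symptom scores are linear-plus-noise functions of
the true metrics, calibrated so the pooled-cohort Pearson correlation with
the weighted metric composite lands near the configured target.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import catalog
from ._seeds import stream
from .ingest import AUSequence, openface_columns

_N_AU = len(catalog.AU_IDS)

#: Clinical table columns, in file order.
CLINICAL_COLUMNS = (
    "id",
    "group",
    "sex",
    "ap_status",
    "hisoc_item1",
    "hisoc_f1",
    "hisoc_f2",
    "hisoc_f3",
    "hisoc_f4",
    "hisoc_total",
    "caarms",
    "sans",
)

#: (case mean, case SD, control mean, control SD, kind) for each outcome,
#: matching the study population's descriptive statistics.
OUTCOME_SCALES: dict[str, tuple[float, float, float, float, str]] = {
    "hisoc_item1": (3.00, 0.80, 3.86, 0.68, "likert5"),
    "hisoc_f1": (19.12, 3.14, 24.03, 2.67, "continuous"),
    "hisoc_f2": (16.66, 2.42, 19.85, 2.34, "continuous"),
    "hisoc_f3": (12.85, 2.64, 15.41, 2.33, "continuous"),
    "hisoc_f4": (2.71, 0.68, 3.88, 0.69, "continuous"),
    "hisoc_total": (51.45, 7.03, 63.23, 6.30, "continuous"),
    "caarms": (50.08, 14.31, 1.46, 2.69, "nonneg"),
    "sans": (1.43, 0.50, float("nan"), float("nan"), "cases_only"),
}


@dataclass(frozen=True)
class OnOffProfile:
    """Two-state chain plus state-conditional intensity for one AU.

    ``p_on``/``p_off`` are per-frame switching probabilities.  Inactive
    intensity is Beta(a, b) scaled to [0, 5] and concentrated near 0;
    active intensity is Beta(a, b) scaled to [1, 5], so an active frame
    always clears the intensity>1 threshold and the intensity>1 proportion
    is controlled by state occupancy alone (keeping the metric targets
    separably solvable).
    """

    p_on: float
    p_off: float
    intensity_active: tuple[float, float] = (4.0, 3.0)
    intensity_inactive: tuple[float, float] = (1.2, 12.0)

    def __post_init__(self) -> None:
        for p in (self.p_on, self.p_off):
            if not (0.0 < p < 1.0) or not np.isfinite(p):
                raise ValueError("switch probabilities must be in (0, 1)")
        for a, b in (self.intensity_active, self.intensity_inactive):
            if a <= 0 or b <= 0 or not np.isfinite(a) or not np.isfinite(b):
                raise ValueError("Beta parameters must be positive and finite")

    @property
    def pi_active(self) -> float:
        return self.p_on / (self.p_on + self.p_off)

    @property
    def switch_rate(self) -> float:
        """Stationary per-pair flip probability 2*p_on*p_off/(p_on+p_off)."""
        return stationary_switch_rate(self.p_on, self.p_off)


def stationary_switch_rate(p_on: float, p_off: float) -> float:
    return 2.0 * p_on * p_off / (p_on + p_off)


def profile_from_occupancy(
    pi_active: float,
    switch_rate: float,
    intensity_active: tuple[float, float] = (4.0, 3.0),
    intensity_inactive: tuple[float, float] = (1.2, 12.0),
) -> OnOffProfile:
    """Build a profile from (stationary active fraction, flip rate)."""
    q = switch_rate / (2.0 * pi_active * (1.0 - pi_active))
    return OnOffProfile(
        p_on=q * pi_active,
        p_off=q * (1.0 - pi_active),
        intensity_active=intensity_active,
        intensity_inactive=intensity_inactive,
    )


# Baseline (stationary active fraction, flip rate) per AU.  AU45 (blink)
# flips far more often than the tonic units; brow/mouth units sit in a
# moderate activity range.
_BASELINE_OCCUPANCY: dict[int, tuple[float, float]] = {
    1: (0.20, 0.035), 2: (0.18, 0.030), 4: (0.22, 0.040), 5: (0.12, 0.025),
    6: (0.25, 0.045), 7: (0.30, 0.050), 9: (0.10, 0.020), 10: (0.24, 0.040),
    12: (0.28, 0.045), 14: (0.26, 0.040), 15: (0.15, 0.030), 17: (0.22, 0.035),
    20: (0.12, 0.025), 23: (0.18, 0.030), 25: (0.35, 0.060), 26: (0.30, 0.055),
    28: (0.10, 0.020), 45: (0.15, 0.120),
}


def default_profiles() -> dict[int, OnOffProfile]:
    return {au: profile_from_occupancy(*_BASELINE_OCCUPANCY[au]) for au in catalog.AU_IDS}


@dataclass(frozen=True)
class RatingCoupling:
    """Linear-plus-noise link from true AU metrics to one clinical outcome.

    ``weights`` maps (au, metric) to a weight; ``target_r`` is the signed
    pooled-cohort Pearson correlation between the outcome and the weighted
    metric composite (|target_r| < 1); ``noise_sd`` overrides the default
    sqrt(1-r^2) noise scale; ``scope`` is "all" or "case" (symptom scores
    couple within cases only).
    """

    weights: dict[tuple[int, str], float]
    target_r: float
    noise_sd: float | None = None
    scope: str = "all"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("coupling needs at least one weight")
        if not abs(self.target_r) < 1.0:
            raise ValueError("target correlation magnitude must be in [0, 1)")
        if self.scope not in ("all", "case"):
            raise ValueError("scope must be 'all' or 'case'")


def default_rating_couplings() -> dict[str, RatingCoupling]:
    """Study-like couplings: clinician-rated facial affect tracks several
    expressivity metrics (pooled r in the 0.2-0.45 band); attenuated
    psychotic symptoms track blink variation negatively within cases."""
    affect_weights = {
        (1, "intensity"): 1.0,
        (15, "presence"): 0.7,
        (12, "variation"): 0.8,
        (45, "presence"): 0.7,
        (25, "presence"): 0.6,
    }
    return {
        "hisoc_item1": RatingCoupling(weights=affect_weights, target_r=0.40),
        "hisoc_f1": RatingCoupling(weights=affect_weights, target_r=0.32),
        "hisoc_f2": RatingCoupling(weights=affect_weights, target_r=0.25),
        "hisoc_f3": RatingCoupling(weights=affect_weights, target_r=0.25),
        "hisoc_f4": RatingCoupling(weights=affect_weights, target_r=0.30),
        "hisoc_total": RatingCoupling(weights=affect_weights, target_r=0.35),
        "caarms": RatingCoupling(
            weights={(45, "variation"): -1.0, (7, "presence"): 0.5},
            target_r=0.30,
            scope="case",
        ),
        "sans": RatingCoupling(
            weights={(26, "presence"): -1.0}, target_r=0.25, scope="case"
        ),
    }


def default_effect_map() -> dict[tuple[str, int, str], float]:
    """Planted group effects: cases show more AU7 presence and less AU45
    variation.  Magnitudes are simulation parameters, not study claims."""
    return {
        ("case", 7, "presence"): 0.15,
        ("case", 45, "variation"): -0.05,
    }


def default_ap_effect_map() -> dict[tuple[int, str], float]:
    """Antipsychotic-exposed subgroup: suppressed expressivity on the AUs
    the sensitivity analysis targets."""
    out: dict[tuple[int, str], float] = {}
    for au in (5, 15, 23, 26):
        out[(au, "presence")] = -0.08
        out[(au, "intensity")] = -0.35
        out[(au, "variation")] = -0.012
    return out


@dataclass
class CohortConfig:
    """Study-design constants for one synthetic cohort.

    Defaults mirror the study: 108 cases / 65 controls, 45-second
    recordings at 30 fps with ~3 s jitter, about a third of cases
    antipsychotic-exposed, and a contamination fraction of participants
    carrying a low-confidence tracking span.
    """

    n_case: int = 108
    n_control: int = 65
    fps: float = 30.0
    duration_mean_s: float = 45.0
    duration_jitter_s: float = 3.0
    seed: int = 0
    au_profiles: dict[int, OnOffProfile] = field(default_factory=default_profiles)
    effect_map: dict[tuple[str, int, str], float] = field(default_factory=default_effect_map)
    heterogeneity: dict[str, float] = field(
        default_factory=lambda: {"presence": 0.06, "intensity": 0.25, "variation": 0.02}
    )
    rating_couplings: dict[str, RatingCoupling] = field(default_factory=default_rating_couplings)
    contamination: float = 0.10
    ap_exposed_fraction: float = 0.35
    ap_effect_map: dict[tuple[int, str], float] = field(default_factory=default_ap_effect_map)
    female_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control < 0:
            raise ValueError("need n_case > 0 and n_control >= 0")
        if not (self.fps > 0 and np.isfinite(self.fps)):
            raise ValueError("fps must be positive and finite")
        if self.duration_mean_s <= 0 or self.duration_jitter_s < 0:
            raise ValueError("invalid duration parameters")
        for name in ("contamination", "ap_exposed_fraction", "female_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for m, sd in self.heterogeneity.items():
            if m not in catalog.METRICS or sd < 0 or not np.isfinite(sd):
                raise ValueError(f"bad heterogeneity entry {m}={sd}")
        for key, delta in self.effect_map.items():
            g, au, metric = key
            if g not in ("case", "control") or au not in catalog.AU_IDS or metric not in catalog.METRICS:
                raise ValueError(f"bad effect_map key {key}")
            if not np.isfinite(delta):
                raise ValueError(f"non-finite effect for {key}")
        for (au, metric), delta in self.ap_effect_map.items():
            if au not in catalog.AU_IDS or metric not in catalog.METRICS or not np.isfinite(delta):
                raise ValueError(f"bad ap_effect_map entry ({au}, {metric})")
        if set(self.au_profiles) != set(catalog.AU_IDS):
            raise ValueError("au_profiles must cover exactly the 18-AU catalog")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["au_profiles"] = {str(k): asdict(v) for k, v in sorted(self.au_profiles.items())}
        d["effect_map"] = {f"{g}|{au}|{m}": v for (g, au, m), v in sorted(self.effect_map.items())}
        d["ap_effect_map"] = {f"{au}|{m}": v for (au, m), v in sorted(self.ap_effect_map.items())}
        d["rating_couplings"] = {
            k: {
                "weights": {f"{au}|{m}": w for (au, m), w in sorted(c.weights.items())},
                "target_r": c.target_r,
                "noise_sd": c.noise_sd,
                "scope": c.scope,
            }
            for k, c in sorted(self.rating_couplings.items())
        }
        return d


def config_hash(config: CohortConfig) -> str:
    """sha256 over the canonicalized config (stable across runs)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


@dataclass
class SyntheticParticipant:
    id: str
    group: str  # "case" | "control"
    sex: str  # "F" | "M"
    ap_status: str  # "naive" | "exposed" | "not_applicable"
    sequence: AUSequence
    clinical: dict[str, float | str]
    true_metrics: dict[int, tuple[float, float, float]]  # au -> (presence, intensity, variation)


# ---------------------------------------------------------------------------
# latent-metric bookkeeping


def _baseline_latents(profiles: dict[int, OnOffProfile]) -> dict[str, np.ndarray]:
    """Per-AU baseline latent metrics and state-conditional constants."""
    aus = catalog.AU_IDS
    a_act = np.array([profiles[a].intensity_active[0] for a in aus])
    b_act = np.array([profiles[a].intensity_active[1] for a in aus])
    a_in = np.array([profiles[a].intensity_inactive[0] for a in aus])
    b_in = np.array([profiles[a].intensity_inactive[1] for a in aus])
    pi0 = np.array([profiles[a].pi_active for a in aus])
    s0 = np.array([profiles[a].switch_rate for a in aus])
    # inactive intensity is 5*Beta, so the >1 threshold is 0.2 on the unit
    # scale; active intensity is 1+4*Beta and always exceeds 1
    pe_in = stats.beta.sf(0.2, a_in, b_in)
    mu_in = 5.0 * a_in / (a_in + b_in)
    mu_act0 = 1.0 + 4.0 * a_act / (a_act + b_act)
    return {
        "a_act": a_act, "b_act": b_act, "a_in": a_in, "b_in": b_in,
        "pi0": pi0, "s0": s0, "pe_in": pe_in,
        "mu_in": mu_in, "mu_act0": mu_act0,
        "presence0": pi0 + (1 - pi0) * pe_in,
        "intensity0": pi0 * mu_act0 + (1 - pi0) * mu_in,
        "variation0": s0,
    }


def _solve_chain(base: dict, m_p: np.ndarray, m_i: np.ndarray, m_v: np.ndarray) -> dict:
    """Solve per-AU chain parameters hitting the target latent metrics.

    Closed-form inversion: occupancy pi from the intensity>1 target (an
    active frame always exceeds 1, an inactive frame does with the fixed
    inactive exceedance), the active-state Beta mean (at fixed
    concentration) from the mean-intensity target, and (p_on, p_off) from
    the flip-rate target at fixed pi.  Returns the implied (exact) latent
    metrics alongside the parameters — clipping at boundaries is recorded
    honestly in the implied values.
    """
    pe_in, mu_in = base["pe_in"], base["mu_in"]
    k = base["a_act"] + base["b_act"]
    pi = np.clip((m_p - pe_in) / (1.0 - pe_in), 0.02, 0.98)
    mu_act = np.clip((m_i - (1 - pi) * mu_in) / pi, 1.05, 4.95)
    a_act = np.clip(k * (mu_act - 1.0) / 4.0, 0.05, k - 0.05)
    b_act = k - a_act
    q = m_v / (2.0 * pi * (1.0 - pi))
    p_on = np.clip(q * pi, 1e-4, 0.97)
    p_off = np.clip(q * (1.0 - pi), 1e-4, 0.97)
    s = 2.0 * p_on * p_off / (p_on + p_off)
    pi_eff = p_on / (p_on + p_off)
    return {
        "p_on": p_on, "p_off": p_off, "pi": pi_eff,
        "a_act": a_act, "b_act": b_act,
        "presence_true": pi_eff + (1 - pi_eff) * pe_in,
        "intensity_true": pi_eff * (1.0 + 4.0 * a_act / (a_act + b_act)) + (1 - pi_eff) * mu_in,
        "variation_true": s,
    }


_METRIC_CLIP = {"presence": (0.01, 0.95), "intensity": (0.2, 4.8), "variation": (0.004, 0.35)}


# ---------------------------------------------------------------------------
# generation


def generate_cohort(config: CohortConfig) -> list[SyntheticParticipant]:
    """Generate the synthetic cohort: frame streams plus clinical table.

    Deterministic for a given seed; each participant draws from a child
    stream keyed by their id, so shared id prefixes reproduce identically
    when the cohort grows.
    """
    base = _baseline_latents(config.au_profiles)
    aus = catalog.AU_IDS
    au_index = {a: i for i, a in enumerate(aus)}
    het_sd = np.array([
        [config.heterogeneity.get("presence", 0.0),
         config.heterogeneity.get("intensity", 0.0),
         config.heterogeneity.get("variation", 0.0)]
    ])  # (1, 3)

    ids, groups = [], []
    for i in range(config.n_case):
        ids.append(f"UHR{i + 1:04d}")
        groups.append("case")
    for i in range(config.n_control):
        ids.append(f"HC{i + 1:04d}")
        groups.append("control")

    meta = []  # per participant static info
    latent = []  # per participant solved chain dicts
    draws = []  # per participant random blocks
    metric_order = ("presence", "intensity", "variation")
    for pid, group in zip(ids, groups):
        rng = stream(config.seed, "participant", pid)
        dur = max(4.0 / config.fps, rng.normal(config.duration_mean_s, config.duration_jitter_s))
        T = max(4, int(round(dur * config.fps)))
        sex = "F" if rng.random() < config.female_fraction else "M"
        if group == "case":
            ap = "exposed" if rng.random() < config.ap_exposed_fraction else "naive"
        else:
            ap = "not_applicable"
        het = rng.standard_normal((_N_AU, 3))
        eps = {name: float(rng.standard_normal()) for name in OUTCOME_SCALES}
        contaminated = rng.random() < config.contamination
        span_frac = float(rng.uniform(0.12, 0.35))
        span_start_u = float(rng.random())

        # latent metric targets: baseline + heterogeneity + group/AP shifts
        targets = np.empty((_N_AU, 3))
        targets[:, 0] = base["presence0"]
        targets[:, 1] = base["intensity0"]
        targets[:, 2] = base["variation0"]
        targets += het * het_sd
        for (g, au, metric), delta in config.effect_map.items():
            if g == group:
                targets[au_index[au], metric_order.index(metric)] += delta
        if ap == "exposed":
            for (au, metric), delta in config.ap_effect_map.items():
                targets[au_index[au], metric_order.index(metric)] += delta
        for j, metric in enumerate(metric_order):
            lo, hi = _METRIC_CLIP[metric]
            targets[:, j] = np.clip(targets[:, j], lo, hi)
        solved = _solve_chain(base, targets[:, 0], targets[:, 1], targets[:, 2])

        init_u = rng.random(_N_AU)
        trans_u = rng.random((T, _N_AU))
        act_draw = 1.0 + 4.0 * rng.beta(solved["a_act"], solved["b_act"], size=(T, _N_AU))
        inact_draw = 5.0 * rng.beta(base["a_in"], base["b_in"], size=(T, _N_AU))
        conf = np.clip(rng.normal(0.975, 0.012, T), 0.0, 1.0)
        success = np.ones(T, dtype=int)
        if contaminated:
            span_len = max(1, int(round(span_frac * T)))
            start = int(span_start_u * (T - span_len)) if T > span_len else 0
            conf[start : start + span_len] = rng.uniform(0.30, 0.78, span_len)
            success[start : start + span_len] = (rng.random(span_len) >= 0.25).astype(int)
        pose = signal.lfilter([0.01], [1.0, -0.97], rng.standard_normal((T, 3)), axis=0)

        meta.append((pid, group, sex, ap, T, eps))
        latent.append(solved)
        draws.append((init_u, trans_u, act_draw, inact_draw, conf, success, pose))

    # batched chain simulation across participants
    n = len(ids)
    t_max = max(m[4] for m in meta)
    trans = np.ones((n, t_max, _N_AU))
    for i, (_, tu, *_rest) in enumerate(draws):
        trans[i, : tu.shape[0], :] = tu
    p_on = np.stack([d["p_on"] for d in latent])
    p_off = np.stack([d["p_off"] for d in latent])
    pi = np.stack([d["pi"] for d in latent])
    state = np.stack([draws[i][0] for i in range(n)]) < pi
    presence = np.empty((n, t_max, _N_AU), dtype=bool)
    for t in range(t_max):
        presence[:, t, :] = state
        flip_p = np.where(state, p_off, p_on)
        state ^= trans[:, t, :] < flip_p

    participants: list[SyntheticParticipant] = []
    columns = openface_columns()
    for i, (pid, group, sex, ap, T, eps) in enumerate(meta):
        init_u, trans_u, act_draw, inact_draw, conf, success, pose = draws[i]
        pres = presence[i, :T, :]
        inten = np.where(pres, act_draw, inact_draw)
        data = {
            "frame": np.arange(1, T + 1),
            "face_id": np.zeros(T, dtype=int),
            "timestamp": np.arange(T) / config.fps,
            "confidence": conf,
            "success": success,
            "pose_Rx": pose[:, 0],
            "pose_Ry": pose[:, 1],
            "pose_Rz": pose[:, 2],
        }
        for a in catalog.INTENSITY_AU_IDS:
            data[catalog.intensity_column(a)] = inten[:, au_index[a]]
        for a in aus:
            data[catalog.presence_column(a)] = pres[:, au_index[a]].astype(int)
        frames = pd.DataFrame(data, columns=columns)
        seq = AUSequence(participant_id=pid, frames=frames, n_raw=T)
        true_m = {
            a: (
                float(latent[i]["presence_true"][au_index[a]]),
                float(latent[i]["intensity_true"][au_index[a]]),
                float(latent[i]["variation_true"][au_index[a]]),
            )
            for a in aus
        }
        participants.append(
            SyntheticParticipant(
                id=pid, group=group, sex=sex, ap_status=ap,
                sequence=seq, clinical={}, true_metrics=true_m,
            )
        )

    _attach_clinical(participants, config, [m[5] for m in meta])
    return participants


def _attach_clinical(
    participants: list[SyntheticParticipant],
    config: CohortConfig,
    eps_list: list[dict[str, float]],
) -> None:
    groups = np.array([p.group for p in participants])
    is_case = groups == "case"
    f_case = float(is_case.mean())

    def composite(coupling: RatingCoupling) -> np.ndarray:
        c = np.zeros(len(participants))
        for (au, metric), w in coupling.weights.items():
            j = {"presence": 0, "intensity": 1, "variation": 2}[metric]
            c += w * np.array([p.true_metrics[au][j] for p in participants])
        return c

    for name, (c_mean, c_sd, h_mean, h_sd, kind) in OUTCOME_SCALES.items():
        eps = np.array([e[name] for e in eps_list])
        coupling = config.rating_couplings.get(name)
        if coupling is None:
            z_out = eps
        else:
            mask = is_case if coupling.scope == "case" else np.ones(len(participants), bool)
            comp = composite(coupling)
            cs = comp[mask].std()
            z_comp = np.zeros_like(comp)
            if cs > 0:
                z_comp[mask] = (comp[mask] - comp[mask].mean()) / cs
            if coupling.scope == "case" or kind == "cases_only":
                lam = 1.0  # within-group construction: no between-group inflation
            else:
                sd2 = f_case * c_sd**2 + (1 - f_case) * h_sd**2
                var_off = f_case * (1 - f_case) * (c_mean - h_mean) ** 2
                lam = float(np.sqrt(sd2 / (sd2 + var_off)))
            r_w = float(np.clip(coupling.target_r / lam, -0.97, 0.97))
            noise = coupling.noise_sd if coupling.noise_sd is not None else np.sqrt(1 - r_w**2)
            z_out = r_w * z_comp + noise * eps
            z_out = z_out / np.sqrt(r_w**2 + noise**2)
            if coupling.scope == "case":
                z_out[~mask] = eps[~mask]
        values = np.where(is_case, c_mean + c_sd * z_out, h_mean + h_sd * z_out)
        if kind == "likert5":
            values = np.clip(np.rint(values), 1, 5)
        elif kind == "nonneg":
            values = np.clip(values, 0.0, None)
        elif kind == "cases_only":
            values = np.where(is_case, np.clip(values, 0.0, None), np.nan)
        for p, v in zip(participants, values):
            p.clinical[name] = float(v)
    for p in participants:
        p.clinical.update(id=p.id, group=p.group, sex=p.sex, ap_status=p.ap_status)


def clinical_frame(cohort: list[SyntheticParticipant]) -> pd.DataFrame:
    df = pd.DataFrame([p.clinical for p in cohort])
    return df[list(CLINICAL_COLUMNS)]


def true_metric_frame(cohort: list[SyntheticParticipant]) -> pd.DataFrame:
    """Latent (ground-truth) metric values, columns named like the realized
    metric columns (``AU12_variation`` etc.)."""
    rows = {}
    for p in cohort:
        row = {}
        for au in catalog.AU_IDS:
            pres, inten, var = p.true_metrics[au]
            lab = catalog.au_label(au)
            key = f"{lab}_activity" if not catalog.has_intensity(au) else f"{lab}_presence_gt1"
            row[key] = pres
            if catalog.has_intensity(au):
                row[f"{lab}_intensity_mean"] = inten
            row[f"{lab}_variation"] = var
        rows[p.id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "id"
    return out


def write_cohort(
    cohort: list[SyntheticParticipant],
    directory,
    config: CohortConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Write one OpenFace-dialect CSV per participant, the clinical table,
    and a manifest (file list, seed, config hash).  Refuses to clobber an
    existing cohort unless ``overwrite`` is set."""
    directory = str(directory)
    manifest_path = os.path.join(directory, "manifest.json")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    frames_dir = os.path.join(directory, "frames")
    os.makedirs(frames_dir, exist_ok=True)
    files = {}
    for p in cohort:
        rel = os.path.join("frames", f"{p.id}.csv")
        p.sequence.frames.to_csv(os.path.join(directory, rel), index=False)
        files[p.id] = rel
    clinical_frame(cohort).to_csv(os.path.join(directory, "clinical.csv"), index=False)
    manifest = {
        "n_participants": len(cohort),
        "seed": config.seed if config is not None else None,
        "config_hash": config_hash(config) if config is not None else None,
        "clinical": "clinical.csv",
        "files": files,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
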