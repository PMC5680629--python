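"""Individual-based simulator of the pond angling experiment.

Generates everything the downstream analysis consumes: a stocked population
of juvenile carp with correlated traits (boldness BP, total length TL,
growth increment G, body/head shape scores SB/SH, sheltering SP), PIT-antenna
detection logs at two feeding spots and a shelter, a trait-dependent
per-session angling capture process, and 16-landmark photographs in TPS form.

The generative model, per fish i and day d:

* feeding-spot visits: ``count ~ Poisson(24 * BP_i * exp(e_id))`` with
  lognormal day noise ``e`` whose variance is solved so that the intraclass
  correlation of weekly mean rates equals a target repeatability;
* sheltering: a daily total-minutes budget ``24 * SP_i * exp(e'_id)`` split
  into non-overlapping presence intervals;
* capture: each one-hour angling session, an independent Bernoulli trial with
  ``logit p_i = intercept + sum_j coef_j * z_ij`` on the true z-scale traits;
  landed fish are released and stay at risk (recaptures are logged).

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ANTENNAS, TRAITS, SimConfig
from . import io as aio
from .morpho import LandmarkConfig, write_tps

__all__ = [
    "ExperimentBundle",
    "simulate_individuals",
    "simulate_daily_metrics",
    "simulate_detections",
    "simulate_angling",
    "calibrate_capture_intercept",
    "simulate_landmarks",
    "simulate_experiment",
    "write_fixture",
    "TEMPLATE_LANDMARKS",
    "shape_bases",
]

_DAY_S = 86400

# Distinct, fixed substream labels per operation so each simulate_* call is
# independently reproducible from (label, seed).
_STREAM = {"individuals": 1, "detections": 2, "angling": 3, "landmarks": 4, "calibrate": 5}


def _rng_for(op: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[op], int(seed)])


# ---------------------------------------------------------------------------
# individuals


def simulate_individuals(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the stocked population: correlated traits, pond labels, attrition flags.

    Traits are multivariate normal with the configured means/SDs and
    (PD-repaired) correlation matrix.  Rate-like traits (BP, SP) and TL are
    floored at 0.  ``alive`` (no predation) and ``tag_retained`` flags are
    independent Bernoulli draws applied as end-of-experiment censoring.
    """
    if rng is None:
        rng = _rng_for("individuals", cfg.seed)
    n = cfg.n_fish
    L = np.linalg.cholesky(cfg.corr)
    z = rng.standard_normal((n, len(TRAITS))) @ L.T
    x = cfg.trait_mean_vector() + z * cfg.trait_sd_vector()
    df = pd.DataFrame(x, columns=[t.lower() for t in TRAITS])
    df.insert(0, "fish_id", [f"F{i + 1:03d}" for i in range(n)])
    df.insert(1, "pond", np.repeat(np.arange(1, cfg.n_ponds + 1), cfg.n_per_pond))
    df = df.rename(
        columns={
            "bp": "bp_true",
            "tl": "tl_mm",
            "g": "growth_mm",
            "sb": "sb_true",
            "sh": "sh_true",
            "sp": "sp_true",
        }
    )
    for col in ("bp_true", "sp_true", "tl_mm"):
        df[col] = df[col].clip(lower=0.0 if col != "tl_mm" else 1.0)
    df["arch_score"] = rng.standard_normal(n)
    df["alive"] = rng.random(n) >= cfg.p_predation
    df["tag_retained"] = rng.random(n) >= cfg.p_tagloss
    return df


# ---------------------------------------------------------------------------
# behavior in ponds


def _day_noise_sigma2(
    between_var: float, mean_sq: float, target: float, d_eff: float, poisson_term: float = 0.0
) -> float:
    """Lognormal day-noise variance giving the target ICC of weekly means.

    Solves ``between / (between + within)`` = target where the within-fish
    variance of a weekly mean is ``[ (exp(s2)-1)*E[X^2] + poisson ] / d_eff``.
    Returns 0 when the target exceeds what the irreducible (Poisson) noise
    allows or when there is no between-fish variance.
    """
    if target <= 0 or between_var <= 0:
        return 0.0
    needed_daily_var = between_var * (1.0 - target) / target * d_eff
    factor = (needed_daily_var - poisson_term) / mean_sq if mean_sq > 0 else 0.0
    if factor <= 0:
        return 0.0
    return float(np.log1p(factor))


def simulate_daily_metrics(
    ind: pd.DataFrame,
    cfg: SimConfig,
    target_repeatability: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-fish per-day activity: visit counts per feeding spot, shelter minutes.

    This is the statistical core of :func:`simulate_detections`; the event
    emission downstream preserves these daily values exactly, so repeatability
    properties can be studied here directly at negligible cost.
    """
    if target_repeatability is None:
        target_repeatability = cfg.target_repeatability
    if not 0 <= target_repeatability < 1:
        raise ValueError("target_repeatability must be in [0, 1)")
    if rng is None:
        rng = _rng_for("detections", cfg.seed)
    n = len(ind)
    n_days = cfg.n_detection_days
    week2 = min(7, cfg.angling_days)
    d_eff = 2.0 / (1.0 / cfg.obs_days + 1.0 / week2)  # harmonic mean of period lengths

    bp = ind["bp_true"].to_numpy(dtype=float)
    sp = ind["sp_true"].to_numpy(dtype=float)

    s2_bp = _day_noise_sigma2(
        np.var(bp), np.mean(bp**2), target_repeatability, d_eff, poisson_term=np.mean(bp) / 24.0
    )
    s2_sp = _day_noise_sigma2(np.var(sp), np.mean(sp**2), target_repeatability, d_eff)

    # per-fish close-spot rate: tightly coupled to the distant-spot rate
    close_factor = np.exp(rng.normal(0.0, 0.12, n))
    close = bp * close_factor

    shape = (n, n_days)
    rate_distant = bp[:, None] * np.exp(rng.normal(-s2_bp / 2.0, np.sqrt(s2_bp), shape))
    rate_close = close[:, None] * np.exp(rng.normal(-s2_bp / 2.0, np.sqrt(s2_bp), shape))
    n_distant = rng.poisson(24.0 * rate_distant)
    n_close = rng.poisson(24.0 * rate_close)
    shelter_min = np.minimum(
        24.0 * sp[:, None] * np.exp(rng.normal(-s2_sp / 2.0, np.sqrt(s2_sp), shape)), 1440.0
    )

    out = pd.DataFrame(
        {
            "fish_id": np.repeat(ind["fish_id"].to_numpy(), n_days),
            "day": np.tile(np.arange(n_days), n),
            "n_close": n_close.ravel(),
            "n_distant": n_distant.ravel(),
            "shelter_min": shelter_min.ravel(),
        }
    )
    return out


_N_VISIT_SLOTS = _DAY_S // 180  # 180 s visit slots keep merged visits distinct


def simulate_detections(
    ind: pd.DataFrame,
    cfg: SimConfig,
    target_repeatability: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit raw PIT reads realizing the daily activity of :func:`simulate_daily_metrics`.

    Each feeding-spot visit becomes a burst of 1-5 reads within 10 s; visits
    are placed in disjoint 180-s slots so that a 60-s debounce downstream
    recovers the daily counts exactly.  Each shelter stay emits reads every
    45 s from entry to exit, with the exit read at the exact interval end.
    Returns a DataFrame (fish_id, antenna, timestamp) sorted by time.
    """
    if rng is None:
        rng = _rng_for("detections", cfg.seed)
    daily = simulate_daily_metrics(ind, cfg, target_repeatability, rng=rng)

    fish_col: list[np.ndarray] = []
    ant_col: list[np.ndarray] = []
    t_col: list[np.ndarray] = []

    def emit_visits(fish: str, day: int, count: int, antenna_code: int) -> None:
        count = int(min(count, _N_VISIT_SLOTS))
        if count == 0:
            return
        slots = rng.choice(_N_VISIT_SLOTS, size=count, replace=False)
        starts = day * _DAY_S + slots * 180 + rng.integers(0, 110, count)
        n_reads = rng.integers(1, 6, count)
        total = int(n_reads.sum())
        t = np.empty(total, dtype=np.int64)
        pos = 0
        for s, k in zip(starts, n_reads):
            offs = np.sort(rng.integers(0, 11, k - 1)) if k > 1 else np.empty(0, dtype=int)
            t[pos] = s
            t[pos + 1 : pos + k] = s + offs
            pos += k
        fish_col.append(np.repeat(fish, total))
        ant_col.append(np.repeat(antenna_code, total))
        t_col.append(t)

    def emit_shelter(fish: str, day: int, total_min: float) -> None:
        if total_min <= 0.5:
            return
        n_stays = int(min(24, max(1, np.ceil(total_min / 50.0))))
        dur_s = total_min * 60.0 / n_stays
        hours = np.sort(rng.choice(24, size=n_stays, replace=False))
        max_jitter = max(1.0, 3600.0 - dur_s - 1.0)
        starts = day * _DAY_S + hours * 3600 + rng.random(n_stays) * max_jitter
        for s in starts:
            reads = np.arange(s, s + dur_s, 45.0)
            reads = np.append(reads, s + dur_s)
            k = len(reads)
            fish_col.append(np.repeat(fish, k))
            ant_col.append(np.repeat(2, k))
            t_col.append(np.round(reads).astype(np.int64))

    for fish, day, nc, nd, sm in daily.itertuples(index=False):
        emit_visits(fish, day, nc, 0)
        emit_visits(fish, day, nd, 1)
        emit_shelter(fish, day, sm)

    if not t_col:
        return pd.DataFrame(columns=["fish_id", "antenna", "timestamp"])
    t = np.concatenate(t_col)
    df = pd.DataFrame(
        {
            "fish_id": np.concatenate(fish_col),
            "antenna": pd.Categorical.from_codes(
                np.concatenate(ant_col).astype(int), categories=list(ANTENNAS)
            ).astype(str),
            "t": t,
        }
    )
    df = df.sort_values(["t", "fish_id", "antenna"], kind="mergesort", ignore_index=True)
    base = pd.Timestamp(cfg.base_date)
    df["timestamp"] = base + pd.to_timedelta(df.pop("t"), unit="s")
    return df[["fish_id", "antenna", "timestamp"]]


# ---------------------------------------------------------------------------
# angling


def _true_z(ind: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    cols = {"BP": "bp_true", "TL": "tl_mm", "G": "growth_mm", "SB": "sb_true",
            "SH": "sh_true", "SP": "sp_true"}
    mu, sd = cfg.trait_mean_vector(), cfg.trait_sd_vector()
    x = np.column_stack([ind[cols[t]].to_numpy(dtype=float) for t in TRAITS])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def capture_probability(ind: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Per-session landing probability for each fish under the configured hazard."""
    eta = cfg.capture_intercept + _true_z(ind, cfg) @ cfg.capture_coef_vector()
    return expit(eta)


def simulate_angling(
    ind: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Run the angling phase; returns all landings (recaptures included).

    Columns: fish_id, day (1-based), session (1-based within day).  Landed
    fish are released immediately and remain at risk, as in the experiment.
    """
    if rng is None:
        rng = _rng_for("angling", cfg.seed)
    p = capture_probability(ind, cfg)
    n_sessions = cfg.angling_days * cfg.sessions_per_day
    hits = rng.random((len(ind), n_sessions)) < p[:, None]
    fish_idx, sess_idx = np.nonzero(hits)
    return pd.DataFrame(
        {
            "fish_id": ind["fish_id"].to_numpy()[fish_idx],
            "day": sess_idx // cfg.sessions_per_day + 1,
            "session": sess_idx % cfg.sessions_per_day + 1,
        }
    )


def expected_capture_fraction(
    cfg: SimConfig,
    horizon_days: int,
    intercept: float | None = None,
    n_mc: int = 40000,
    inner_seed: int = 12345,
) -> float:
    """Monte-Carlo expectation of the ever-captured fraction within a horizon.

    The per-fish trait draw is Monte-Carlo; the session process is integrated
    analytically (``1 - (1-p)^sessions``), so the estimate is smooth in the
    intercept and suitable for bisection.
    """
    rng = np.random.default_rng([_STREAM["calibrate"], int(inner_seed)])
    L = np.linalg.cholesky(cfg.corr)
    z = rng.standard_normal((n_mc, len(TRAITS))) @ L.T
    a = cfg.capture_intercept if intercept is None else intercept
    eta = a + z @ cfg.capture_coef_vector()
    sessions = horizon_days * cfg.sessions_per_day
    return float(np.mean(1.0 - (1.0 - expit(eta)) ** sessions))


def calibrate_capture_intercept(
    cfg: SimConfig,
    horizon_days: int,
    target_fraction: float,
    tol: float = 1e-3,
    inner_seed: int = 12345,
) -> float:
    """Bisect the hazard intercept so the expected ever-captured fraction hits a target."""
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    lo, hi = -30.0, 10.0
    f = lambda a: expected_capture_fraction(cfg, horizon_days, a, inner_seed=inner_seed)
    if not f(lo) < target_fraction < f(hi):
        raise ValueError(f"target fraction {target_fraction} unreachable for this hazard")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if f(mid) < target_fraction:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    if abs(f(a) - target_fraction) > max(tol, 0.01):
        raise ValueError("bisection failed to reach target within tolerance")
    return a


# ---------------------------------------------------------------------------
# landmarks

# Left-side carp template, 16 landmarks in the standard digitizing order
# (jaw tip, jaw corner, pectoral/pelvic/anal-fin insertions, peduncle,
# lateral-line end, dorsal fin, head points, eye, operculum).  Unit body
# length, y up.
TEMPLATE_LANDMARKS = np.array(
    [
        [0.00, 0.00],   # 1  tip of upper jaw
        [0.05, -0.02],  # 2  posterior corner of upper jaw
        [0.25, -0.12],  # 3  pectoral fin insertion
        [0.45, -0.15],  # 4  pelvic fin insertion
        [0.65, -0.14],  # 5  anterior anal-fin insertion
        [0.72, -0.13],  # 6  posterior anal-fin insertion
        [0.85, -0.08],  # 7  ventral peduncle, max curvature
        [0.95, 0.00],   # 8  posterior end of lateral line
        [0.85, 0.07],   # 9  dorsal peduncle, max curvature
        [0.72, 0.12],   # 10 posterior dorsal-fin insertion
        [0.52, 0.16],   # 11 anterior dorsal-fin insertion
        [0.22, 0.12],   # 12 dorsal insertion of head
        [0.10, 0.06],   # 13 dorsal edge of head (above eye)
        [0.09, 0.01],   # 14 center of eye
        [0.10, -0.05],  # 15 ventral edge of head (below eye)
        [0.20, -0.02],  # 16 posterior end of operculum
    ]
)

HEAD_LANDMARKS = (0, 1, 11, 12, 14, 15)  # landmarks 1, 2, 12, 13, 15, 16
_TRUNK = tuple(range(2, 11))  # landmarks 3-11


def shape_bases() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal deformation directions (body depth, head shape, arching).

    Each is a 16x2 displacement field orthogonal to the similarity
    transformations of the template (translation, scaling and rotation), i.e.
    a pure shape change that Procrustes superimposition cannot absorb; the
    three flattened vectors are mutually orthonormal.
    """
    v_sb = np.zeros((16, 2))
    v_sb[list(_TRUNK), 1] = TEMPLATE_LANDMARKS[list(_TRUNK), 1]  # inflate body depth
    head = np.array(HEAD_LANDMARKS)
    head_center = TEMPLATE_LANDMARKS[head].mean(axis=0)
    # head aspect-ratio change (stretch x, compress y): a genuine shape
    # deformation that survives Procrustes scaling of the head subset,
    # unlike a radial head inflation which is absorbed by centroid size
    v_sh = np.zeros((16, 2))
    rel = TEMPLATE_LANDMARKS[head] - head_center
    v_sh[head, 0] = rel[:, 0]
    v_sh[head, 1] = -rel[:, 1]
    x = TEMPLATE_LANDMARKS[:, 0]
    v_arch = np.zeros((16, 2))
    v_arch[:, 1] = (x - x.mean()) ** 2  # dorsoventral quadratic bend

    centered = TEMPLATE_LANDMARKS - TEMPLATE_LANDMARKS.mean(axis=0)
    scale_field = centered.ravel()
    rot_field = np.column_stack([-centered[:, 1], centered[:, 0]]).ravel()
    similarity = [scale_field / np.linalg.norm(scale_field), rot_field / np.linalg.norm(rot_field)]

    basis = []
    for v in (v_sb, v_sh, v_arch):
        u = (v - v.mean(axis=0)).ravel()
        for b in similarity + basis:
            u = u - (u @ b) * b
        u = u / np.linalg.norm(u)
        basis.append(u)
    return tuple(b.reshape(16, 2) for b in basis)


def simulate_landmarks(
    ind: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[LandmarkConfig]:
    """Landmark configurations: size by TL, shape by SB/SH, arching nuisance, noise."""
    if rng is None:
        rng = _rng_for("landmarks", cfg.seed)
    v_sb, v_sh, v_arch = shape_bases()
    configs = []
    for row in ind.itertuples(index=False):
        tl = row.tl_mm
        deform = (
            cfg.sb_magnitude * row.sb_true * v_sb
            + cfg.sh_magnitude * row.sh_true * v_sh
            + cfg.arch_magnitude * row.arch_score * v_arch
        )
        noise = rng.normal(0.0, cfg.landmark_noise_sd, (16, 2))
        coords = (TEMPLATE_LANDMARKS + deform + noise) * tl
        configs.append(LandmarkConfig(fish_id=row.fish_id, coords=coords))
    return configs


# ---------------------------------------------------------------------------
# bundle


@dataclass
class ExperimentBundle:
    """One complete simulated experiment."""

    cfg: SimConfig
    individuals: pd.DataFrame
    detections: pd.DataFrame
    captures: pd.DataFrame
    landmarks: list[LandmarkConfig]

    @property
    def roster(self) -> pd.DataFrame:
        """Fish with complete records (survived predation, retained the tag)."""
        return self.individuals[self.individuals["alive"] & self.individuals["tag_retained"]]


def simulate_experiment(cfg: SimConfig) -> ExperimentBundle:
    """Simulate the full pond experiment under one config (deterministic in cfg.seed)."""
    ind = simulate_individuals(cfg)
    detections = simulate_detections(ind, cfg)
    captures = simulate_angling(ind, cfg)
    landmarks = simulate_landmarks(ind, cfg)
    return ExperimentBundle(cfg, ind, detections, captures, landmarks)


def write_fixture(bundle: ExperimentBundle, directory) -> dict:
    """Write the bundle as plain-text files; returns the path map.

    Files: detections.csv, captures.csv, traits.csv, landmarks.tps,
    config.yaml.  All round-trip losslessly through the package readers.
    Records are censored to complete-record fish (attrition is applied at the
    end of the experiment: fish lost to predation or tag loss leave no usable
    dataset, as in the real study where 94 of 120 fish could be analyzed).
    """
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": d / "detections.csv",
        "captures": d / "captures.csv",
        "traits": d / "traits.csv",
        "landmarks": d / "landmarks.tps",
        "config": d / "config.yaml",
    }
    roster = bundle.roster
    keep = set(roster["fish_id"])
    det = bundle.detections[bundle.detections["fish_id"].isin(keep)]
    cap = bundle.captures[bundle.captures["fish_id"].isin(keep)]
    lms = [c for c in bundle.landmarks if c.fish_id in keep]
    aio.write_detections(det, paths["detections"])
    aio.write_captures(cap, paths["captures"])
    aio.write_traits(roster, paths["traits"])
    write_tps(lms, paths["landmarks"])
    bundle.cfg.to_yaml(paths["config"])
    return paths
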