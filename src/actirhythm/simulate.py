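"""Synthetic actigraphy and cohort generator.

The generator emulates week-long inpatient wrist-actigraphy recordings so
the whole analysis chain can be exercised without any real data:

* a **diurnal envelope** per day, a rectified (truncated) cosine
  ``mesor + amplitude * max(0, cos(2*pi*(t - acrophase)/24))`` so nights
  sit on a true nonnegative floor (the mesor) rather than a negative
  half-wave;
* **day-to-day jitter** of the acrophase and amplitude (normal, per day);
* a **fragmentation layer**: a two-state (active/rest) Markov chain at
  1-minute resolution, switching with per-minute probability
  ``frag_rate``, multiplied onto the rhythmic (amplitude) component of
  the envelope (active = 1, rest = 0) while the mesor stays an additive
  floor.  The chain starts active, so ``frag_rate = 0`` means no
  fragmentation.  Keeping the floor outside the fragmentation makes IS
  and IV exactly invariant to the floor level, so a raised nocturnal
  floor moves L5 and RA without dragging the stability/fragmentation
  indicators along — the contrast structure reported for poststroke
  inpatients;
* additive within-minute noise, with the result clipped at 0.

Activity units are arbitrary (no device calibration exists); only
within-pipeline comparisons are meaningful.

Cohorts draw one :class:`RhythmParams` per participant from per-group
distributions, and attach clinical scores statistically linked to the
rhythm: the Barthel Index increases with daytime activity level and
day-to-day stability, the 4AT delirium screen decreases with the true
relative amplitude.  The shipped :func:`paperlike_spec` gives the
stroke-like group a raised nocturnal floor (hence higher L5, lower RA)
and both groups a common daytime amplitude distribution (hence similar
M10), mirroring the contrast structure reported for poststroke
inpatients versus matched rehabilitation controls.

Randomness: a single root seed; per-participant child seeds are spawned
deterministically (``numpy.random.SeedSequence``), so cohorts are
reproducible and participants independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import InsufficientDaysError, ValidationError
from .metrics import L5_MINUTES, M10_MINUTES
from .series import DEFAULT_START, MINUTES_PER_DAY, AccelRecording, EpochSeries

__all__ = [
    "RhythmParams",
    "ParamDist",
    "ScoreLink",
    "CohortSpec",
    "generate_epoch_series",
    "generate_accel",
    "generate_cohort",
    "paperlike_spec",
    "null_spec",
]

MIN_DAYS = 7


@dataclass
class RhythmParams:
    """Parameters of one simulated participant's rest-activity rhythm.

    mesor : activity units/min, >= 0
        Mean floor level; with the rectified-cosine envelope this is the
        nocturnal activity floor.
    amplitude : activity units/min, >= 0
        Peak-over-mesor height of the diurnal modulation.
    acrophase : hours in [0, 24)
        Clock time of the daily activity peak.
    phase_jitter_sd, amp_jitter_sd : hours / units, >= 0
        Day-to-day SD of acrophase and amplitude.
    frag_rate : [0, 1]
        Per-minute switching probability of the rest/active chain.
    noise_sd : >= 0
        SD of additive within-minute noise (clipped at 0).
    n_days : int >= 7
        Recording length in whole days (a week is the analysis minimum).
    epoch_len : fixed at 1 minute.
    """

    mesor: float = 1.8
    amplitude: float = 90.0
    acrophase: float = 14.0
    phase_jitter_sd: float = 1.2
    amp_jitter_sd: float = 8.0
    frag_rate: float = 0.04
    noise_sd: float = 2.0
    n_days: int = 7
    epoch_len: int = 1

    def __post_init__(self):
        for name in ("mesor", "amplitude", "phase_jitter_sd", "amp_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.frag_rate <= 1.0:
            raise ValidationError("frag_rate must be in [0, 1]")
        if not 0.0 <= self.acrophase < 24.0:
            raise ValidationError("acrophase must be in [0, 24)")
        if self.epoch_len != 1:
            raise ValidationError("epoch_len is fixed at 1 minute")
        if int(self.n_days) != self.n_days or self.n_days < MIN_DAYS:
            raise InsufficientDaysError(
                f"insufficient days: n_days={self.n_days} < {MIN_DAYS} (a week minimum)"
            )
        self.n_days = int(self.n_days)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _minute_envelope(params: RhythmParams, rng: np.random.Generator) -> np.ndarray:
    """Noiseless envelope x fragmentation, one value per minute, flattened."""
    d = params.n_days
    acro = np.full(d, params.acrophase)
    if params.phase_jitter_sd > 0:
        acro = acro + rng.normal(0.0, params.phase_jitter_sd, d)
    amp = np.full(d, params.amplitude)
    if params.amp_jitter_sd > 0:
        amp = np.maximum(0.0, amp + rng.normal(0.0, params.amp_jitter_sd, d))
    t = (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0  # hours, minute centres
    phase = 2.0 * np.pi * (t[None, :] - acro[:, None]) / 24.0
    rhythm = (amp[:, None] * np.maximum(0.0, np.cos(phase))).ravel()
    if params.frag_rate > 0:
        switches = rng.random(rhythm.size) < params.frag_rate
        switches[0] = False  # chain starts in the active state
        state = (np.cumsum(switches) % 2 == 0).astype(float)
        rhythm = rhythm * state
    return params.mesor + rhythm


def generate_epoch_series(params: RhythmParams, seed, start_time=DEFAULT_START) -> EpochSeries:
    """Simulate one participant's minute acti-count series.

    Deterministic per (params, seed); counts are nonnegative and the
    series spans exactly ``n_days * 1440`` minutes from local midnight.
    """
    rng = _rng(seed)
    counts = _minute_envelope(params, rng)
    if params.noise_sd > 0:
        counts = counts + rng.normal(0.0, params.noise_sd, counts.size)
    counts = np.maximum(counts, 0.0)
    return EpochSeries(start_time=pd.Timestamp(start_time).normalize(), counts=counts)


def envelope_profile(params: RhythmParams) -> np.ndarray:
    """Noiseless, jitter-free single-day minute profile of the envelope."""
    t = (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0
    phase = 2.0 * np.pi * (t - params.acrophase) / 24.0
    return params.mesor + params.amplitude * np.maximum(0.0, np.cos(phase))


def envelope_rar(params: RhythmParams) -> tuple[float, float, float]:
    """(M10, L5, RA) of the noiseless, jitter- and fragmentation-free envelope.

    The generator's own ground truth for a participant's rhythm strength,
    by direct window search on the single-day profile.  Fragmentation
    thins only the rhythmic component, so realised RA sits below this
    value but is monotone in it.
    """
    prof = envelope_profile(params)
    csum = np.concatenate([[0.0], prof.cumsum()])
    m = (csum[M10_MINUTES:] - csum[: MINUTES_PER_DAY - M10_MINUTES + 1]) / M10_MINUTES
    l = (csum[L5_MINUTES:] - csum[: MINUTES_PER_DAY - L5_MINUTES + 1]) / L5_MINUTES
    m10, l5 = float(m.max()), float(l.min())
    ra = (m10 - l5) / (m10 + l5) if m10 + l5 > 0 else float("nan")
    return m10, l5, ra


# ---------------------------------------------------------------------------
# Raw accelerometry
# ---------------------------------------------------------------------------

def generate_accel(
    params: RhythmParams,
    sample_rate: float = 30.0,
    seed=0,
    minutes: int | None = None,
    burst_prob: float = 0.3,
    burst_band: tuple[float, float] = (0.8, 2.5),
    gain: float = 0.005,
    sensor_noise_sd: float = 0.002,
    start_time=DEFAULT_START,
) -> AccelRecording:
    """Simulate raw tri-axial acceleration driven by the same rhythm process.

    Samples are gravity (0, 0, 1 g) + movement bursts + white sensor
    noise.  Each 2-second block carries, with probability ``burst_prob``
    (only while the envelope x fragmentation process is active), a
    sinusoidal burst at a random frequency inside ``burst_band`` (within
    the 0.5-3 Hz actigraphy band), amplitude ``gain`` x the block's
    envelope level, along a random fixed 3-D direction.  ``minutes`` caps
    the emitted duration for desk-scale work; the rhythm process itself is
    always the full ``n_days`` so the cap is a plain truncation.
    """
    if sample_rate < 6.0:
        raise ValidationError(
            f"sample_rate {sample_rate} Hz < 6 Hz: 3 Hz movement band would alias"
        )
    spb = sample_rate * 2.0  # samples per 2-s block
    if abs(spb - round(spb)) > 1e-9:
        raise ValidationError("sample_rate must give whole 2-s blocks")
    spb = int(round(spb))
    rng = _rng(seed)
    activity = _minute_envelope(params, rng)
    if minutes is not None:
        if minutes < 1:
            raise ValidationError("minutes must be >= 1")
        activity = activity[:minutes]
    n_blocks = activity.size * 30
    block_level = np.repeat(activity, 30)

    burst = rng.random(n_blocks) < burst_prob
    burst &= block_level > 0
    freq = rng.uniform(burst_band[0], burst_band[1], n_blocks)
    phase0 = rng.uniform(0.0, 2.0 * np.pi, n_blocks)
    direction = rng.normal(size=(n_blocks, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)

    tt = np.arange(spb) / sample_rate
    osc = np.sin(2.0 * np.pi * freq[:, None] * tt[None, :] + phase0[:, None])
    amp = gain * block_level * burst
    movement = (amp[:, None] * osc)[:, :, None] * direction[:, None, :]
    samples = movement.reshape(-1, 3)
    if sensor_noise_sd > 0:
        samples = samples + rng.normal(0.0, sensor_noise_sd, samples.shape)
    samples[:, 2] += 1.0  # gravity
    return AccelRecording(
        start_time=pd.Timestamp(start_time).normalize(),
        sample_rate=float(sample_rate),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class ParamDist:
    """Normal distribution for one rhythm parameter, truncated to [lo, hi]."""

    mean: float
    sd: float = 0.0
    lo: float = 0.0
    hi: float = math.inf

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if not self.lo <= self.mean <= self.hi:
            raise ValidationError("mean must lie within [lo, hi]")

    def draw(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd) if self.sd > 0 else self.mean,
                             self.lo, self.hi))


@dataclass
class ScoreLink:
    """Linear links from rhythm ground truth to clinical scores.

    BI = bi_intercept + bi_day * z(daytime level) + bi_stability * z(-phase jitter)
         + N(0, bi_noise_sd), rounded and clipped to [0, 100];
    4AT = fourat_intercept + fourat_ra * z(envelope RA) + N(0, fourat_noise_sd),
          rounded and clipped to [0, 12], administered only to
          ``fourat_groups`` (mirroring a delirium screen given to the
          stroke group only).
    """

    bi_intercept: float = 35.0
    bi_day: float = 12.0
    bi_stability: float = 8.0
    bi_noise_sd: float = 8.0
    fourat_intercept: float = 4.0
    fourat_ra: float = -2.0
    fourat_noise_sd: float = 1.5
    fourat_groups: tuple[str, ...] = ("stroke",)

    def __post_init__(self):
        if self.bi_noise_sd < 0 or self.fourat_noise_sd < 0:
            raise ValidationError("degenerate score_link: noise SDs must be >= 0")


_GROUP_FIELDS = (
    "mesor", "amplitude", "acrophase", "phase_jitter_sd",
    "amp_jitter_sd", "frag_rate", "noise_sd",
)


@dataclass
class CohortSpec:
    """Two-group synthetic cohort specification.

    ``groups`` maps a label to a dict of :class:`ParamDist` (one per
    rhythm parameter); participants draw their :class:`RhythmParams`
    independently from their group's distributions.
    """

    n_per_group: int
    groups: dict[str, dict[str, ParamDist]]
    score_link: ScoreLink = field(default_factory=ScoreLink)
    n_days: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if not self.groups:
            raise ValidationError("at least one group required")
        for label, dists in self.groups.items():
            missing = set(_GROUP_FIELDS) - set(dists)
            if missing:
                raise ValidationError(f"group {label!r} missing distributions: {sorted(missing)}")

    def to_dict(self) -> dict:
        link = asdict(self.score_link)
        link["fourat_groups"] = list(link["fourat_groups"])  # YAML-friendly
        return {
            "n_per_group": self.n_per_group,
            "n_days": self.n_days,
            "seed": self.seed,
            "score_link": link,
            "groups": {
                g: {k: asdict(v) for k, v in dists.items()}
                for g, dists in self.groups.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        known = {"n_per_group", "n_days", "seed", "score_link", "groups"}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown cohort spec keys: {sorted(unknown)}")
        link = d.get("score_link", {})
        if isinstance(link, dict):
            link = dict(link)
            if "fourat_groups" in link:
                link["fourat_groups"] = tuple(link["fourat_groups"])
            link = ScoreLink(**link)
        groups = {
            g: {k: (v if isinstance(v, ParamDist) else ParamDist(**v)) for k, v in dists.items()}
            for g, dists in d["groups"].items()
        }
        return cls(
            n_per_group=int(d["n_per_group"]),
            groups=groups,
            score_link=link,
            n_days=int(d.get("n_days", 7)),
            seed=int(d.get("seed", 0)),
        )


def paperlike_spec(n_per_group: int = 25, n_days: int = 7, seed: int = 0) -> CohortSpec:
    """Shipped default cohort: stroke-like vs inpatient-control-like.

    The stroke-like group carries a raised nocturnal floor (mesor ~4.3 vs
    ~1.8 units/min, matching the published L5 group medians) and a
    slightly reduced daytime amplitude chosen so the expected composite
    M10 is the same in both groups: in expectation L5 is elevated and RA
    depressed in the stroke-like group while M10, IS and IV are
    comparable — the significance pattern the nonparametric comparison
    should recover.  Magnitudes are anchored to the published group
    medians of the poststroke inpatient study this design emulates; units
    remain arbitrary.
    """
    common = {
        "acrophase": ParamDist(14.0, 1.5, lo=0.0, hi=23.99),
        "phase_jitter_sd": ParamDist(1.2, 0.4, lo=0.0),
        "amp_jitter_sd": ParamDist(8.0, 3.0, lo=0.0),
        "frag_rate": ParamDist(0.04, 0.015, lo=0.001, hi=0.3),
        "noise_sd": ParamDist(2.0, 0.5, lo=0.0),
    }
    return CohortSpec(
        n_per_group=n_per_group,
        groups={
            "stroke": {
                "mesor": ParamDist(4.3, 2.0, lo=0.3),
                "amplitude": ParamDist(83.0, 35.0, lo=5.0),
                **common,
            },
            "control": {
                "mesor": ParamDist(1.8, 1.0, lo=0.2),
                "amplitude": ParamDist(90.0, 35.0, lo=5.0),
                **common,
            },
        },
        n_days=n_days,
        seed=seed,
    )


def null_spec(n_per_group: int = 25, n_days: int = 7, seed: int = 0) -> CohortSpec:
    """Both groups drawn from the control-like distribution (for null checks)."""
    spec = paperlike_spec(n_per_group=n_per_group, n_days=n_days, seed=seed)
    spec.groups["stroke"] = dict(spec.groups["control"])
    return spec


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_cohort(
    spec: CohortSpec, start_time=DEFAULT_START
) -> tuple[pd.DataFrame, dict[str, EpochSeries]]:
    """Generate a full cohort: participant table + per-participant epochs.

    Returns a DataFrame with columns ``participant_id, group,
    barthel_index, four_at`` (4AT NaN where not administered) and a map
    ``participant_id -> EpochSeries``.  Fully deterministic per spec seed.
    """
    root = np.random.SeedSequence(spec.seed)
    labels = list(spec.groups)
    n_total = spec.n_per_group * len(labels)
    children = root.spawn(n_total + 1)
    score_rng = np.random.default_rng(children[-1])

    rows = []
    epochs: dict[str, EpochSeries] = {}
    day_level, stability, true_ra = [], [], []
    i = 0
    for label in labels:
        dists = spec.groups[label]
        for k in range(spec.n_per_group):
            child = children[i]
            prng = np.random.default_rng(child)
            params = RhythmParams(
                **{f: dists[f].draw(prng) for f in _GROUP_FIELDS}, n_days=spec.n_days
            )
            pid = f"{label}_{k + 1:03d}"
            epochs[pid] = generate_epoch_series(params, seed=prng, start_time=start_time)
            m10e, l5e, rae = envelope_rar(params)
            day_level.append(m10e)
            stability.append(-params.phase_jitter_sd)
            true_ra.append(rae)
            rows.append({"participant_id": pid, "group": label})
            i += 1

    link = spec.score_link
    z_day = _zscore(np.array(day_level))
    z_stab = _zscore(np.array(stability))
    z_ra = _zscore(np.array(true_ra))
    bi = (
        link.bi_intercept
        + link.bi_day * z_day
        + link.bi_stability * z_stab
        + score_rng.normal(0.0, link.bi_noise_sd, n_total)
    )
    fourat = (
        link.fourat_intercept
        + link.fourat_ra * z_ra
        + score_rng.normal(0.0, link.fourat_noise_sd, n_total)
    )
    table = pd.DataFrame(rows)
    table["barthel_index"] = np.clip(np.round(bi), 0, 100).astype(int)
    table["four_at"] = np.clip(np.round(fourat), 0, 12)
    table.loc[~table["group"].isin(link.fourat_groups), "four_at"] = np.nan
    return table, epochs
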