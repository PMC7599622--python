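"""Synthetic participants: latent inattention -> behavior and SWAN scores.

The generator formalizes the hypothesis behind the instrument: more
inattentive children omit more jumps and jump closer to the gap, and both
effects strengthen as the inter-stimulus (IS) time grows, because a longer
quiet interval gives attention more room to drift.

Each participant carries a latent inattention level ``lam`` in [0, 1]
that drives two channels:

* **Omissions.**  Attention lapses accrue over the IS interval as a
  Poisson hazard proportional to ``lam``; the gap is missed entirely with
  probability ``1 - exp(-lapse_rate * lam * is_time)``.

* **Jump distance.**  Voluntary jumps follow a scalar-timing (Weber-law)
  model: distances are lognormal with multiplicative noise, so a
  participant's spread scales with their typical distance.  Inattention
  shifts the log-distance down by ``attention_gain * lam *
  max(is_time - is_threshold, 0) / is_ref``; below ``is_threshold`` the
  rapid stimulus train keeps even inattentive players engaged and the
  distance signal vanishes, which is what makes short-IS blocks poor
  predictors.  The floor at zero distance means inattentive participants'
  distances both shrink and compress, so the distance IQR falls with
  inattention alongside the median.

The same latent ``lam`` generates the 9-item SWAN inattention subscale:
item scores are a noisy, discretized readout of ``3 * (1 - 2*lam)``, so a
*higher* SWAN total means *better* attention.  Cohort-level correlations
between session metrics and SWAN totals therefore come out positive for
median and IQR and negative for omission counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .schedule import BlockConfig, Schedule, build_default_schedule, interstimulus_time
from .task_engine import NO_JUMP, ResponsePolicy, SessionLog, simulate_session

__all__ = [
    "ParticipantProfile",
    "SwanScore",
    "Cohort",
    "lapse_probability",
    "behavior_policy",
    "sample_swan",
    "generate_cohort",
    "make_lambda_sampler",
]

@dataclass(frozen=True)
class ParticipantProfile:
    """Latent traits of one synthetic participant.

    Parameters
    ----------
    participant_id
        Unique label.
    lam
        Latent inattention in [0, 1]; 0 = fully attentive.
    d0
        Preferred jump distance of an attentive player (track units).
    sigma_d
        Jump-distance variability at the preferred distance (track units);
        internally a multiplicative log-scale SD of ``sigma_d / d0``.
    lapse_rate
        Per-second lapse hazard multiplier; scales omission probability.
    swan_sigma
        SD of the per-item noise on the SWAN readout (score points).
    attention_gain
        Log-distance shift per unit ``lam`` at the reference IS time.
    is_threshold
        IS time (s) below which inattention stops affecting distances.
    is_ref
        Reference IS time (s) normalizing the attention shift.
    """

    participant_id: str
    lam: float
    d0: float = 3.0
    sigma_d: float = 1.5
    lapse_rate: float = 0.6
    swan_sigma: float = 1.0
    attention_gain: float = 1.0
    is_threshold: float = 1.0
    is_ref: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigurationError("lam must be in [0, 1]")
        for name in ("d0", "sigma_d", "lapse_rate", "swan_sigma",
                     "attention_gain", "is_threshold", "is_ref"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.d0 <= 0 or self.is_ref <= 0:
            raise ConfigurationError("d0 and is_ref must be > 0")


@dataclass(frozen=True)
class SwanScore:
    """9-item SWAN inattention subscale; items in [-3, 3], total their sum."""

    items: tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise ConfigurationError("SWAN inattention subscale has exactly 9 items")
        if any(i < -3 or i > 3 for i in self.items):
            raise ConfigurationError("SWAN items must lie in [-3, 3]")
        if self.total != sum(self.items):
            raise ConfigurationError("SWAN total must equal the item sum")


@dataclass
class Cohort:
    """Parallel per-participant profiles, SWAN scores and session logs."""

    profiles: list[ParticipantProfile] = field(default_factory=list)
    swan: list[SwanScore] = field(default_factory=list)
    logs: list[SessionLog] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.profiles) == len(self.swan) == len(self.logs)):
            raise ConfigurationError("profiles, swan and logs must be parallel lists")
        ids = [p.participant_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.profiles]

    def swan_totals(self) -> dict[str, int]:
        return {p.participant_id: s.total for p, s in zip(self.profiles, self.swan)}

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p, s, log in zip(self.profiles, self.swan, self.logs):
            h.update(f"{p.participant_id}|{p.lam!r}|{s.items}\n".encode())
            h.update(log.digest().encode())
        return h.hexdigest()


def lapse_probability(lam: float, is_time: float, lapse_rate: float) -> float:
    """Probability of missing a gap after an IS interval of ``is_time`` seconds.

    ``1 - exp(-lapse_rate * lam * is_time)``: zero for a fully attentive
    participant and strictly increasing in both ``lam`` and ``is_time``.
    """
    if lam < 0 or is_time < 0 or lapse_rate < 0:
        raise ConfigurationError("lapse_probability inputs must be nonnegative")
    return 1.0 - math.exp(-lapse_rate * lam * is_time)


def behavior_policy(profile: ParticipantProfile) -> ResponsePolicy:
    """Response policy realizing the profile's latent inattention.

    Per gap: lapse (omission) with the hazard-based probability; otherwise
    jump at a lognormal distance whose log-mean is shifted down by the
    IS-gated attention term.  Deterministic given the random stream.
    """
    sigma_log = profile.sigma_d / profile.d0

    def policy(block: BlockConfig, gap_index: int, rng: np.random.Generator):
        t = interstimulus_time(block)
        # The uniform is always drawn so the stream advances identically
        # for lapsed and attended gaps up to the jump itself.
        if rng.random() < lapse_probability(profile.lam, t, profile.lapse_rate):
            return NO_JUMP
        shift = (
            profile.attention_gain
            * profile.lam
            * max(t - profile.is_threshold, 0.0)
            / profile.is_ref
        )
        noise = sigma_log * rng.standard_normal() if sigma_log > 0 else 0.0
        return profile.d0 * math.exp(-shift + noise)

    return policy


def sample_swan(
    profile: ParticipantProfile, seed: int | np.random.SeedSequence | np.random.Generator
) -> SwanScore:
    """Draw a 9-item SWAN inattention subscale for the profile.

    The latent readout is ``a = 3 * (1 - 2*lam)`` (attentive -> +3,
    maximally inattentive -> -3); each item is ``round(a + noise)`` clamped
    to [-3, 3].  Higher totals mean better attention.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = 3.0 * (1.0 - 2.0 * profile.lam)
    raw = a + profile.swan_sigma * rng.standard_normal(9)
    items = tuple(int(v) for v in np.clip(np.rint(raw), -3, 3))
    return SwanScore(items=items, total=sum(items))


LambdaSampler = Callable[[np.random.Generator], float]


def make_lambda_sampler(spec: object) -> LambdaSampler:
    """Turn a distribution spec into a sampler for the latent inattention.

    Accepts a callable ``rng -> float`` or a tuple: ``("uniform", lo, hi)``,
    ``("beta", a, b)`` or ``("constant", v)``; values are clipped to [0, 1].
    """
    if callable(spec):
        return spec  # type: ignore[return-value]
    if isinstance(spec, Sequence) and spec and isinstance(spec[0], str):
        name = spec[0].lower()
        args = [float(v) for v in spec[1:]]
        if name == "uniform" and len(args) == 2 and 0 <= args[0] <= args[1] <= 1:
            return lambda rng: rng.uniform(args[0], args[1])
        if name == "beta" and len(args) == 2 and args[0] > 0 and args[1] > 0:
            return lambda rng: float(rng.beta(args[0], args[1]))
        if name == "constant" and len(args) == 1 and 0 <= args[0] <= 1:
            return lambda rng: args[0]
    raise ConfigurationError(f"invalid lambda distribution spec: {spec!r}")


def generate_cohort(
    n: int = 32,
    lambda_dist: object = ("uniform", 0.0, 1.0),
    seed: int = 0,
    schedule: Schedule | None = None,
    airtime: float = 1.0,
    **profile_kwargs,
) -> Cohort:
    """Generate ``n`` participants, each with a SWAN score and a full session.

    Participant ``i`` draws all its randomness from sub-streams of
    ``SeedSequence([seed, i])``, so the first ``k`` participants are
    identical whatever ``n`` is, and the whole cohort is reproducible
    from the single master seed.
    """
    if n < 0:
        raise ConfigurationError("cohort size must be >= 0")
    sampler = make_lambda_sampler(lambda_dist)
    sched = schedule if schedule is not None else build_default_schedule()
    profiles: list[ParticipantProfile] = []
    swans: list[SwanScore] = []
    logs: list[SessionLog] = []
    for i in range(n):
        root = np.random.SeedSequence([int(seed), i])
        lam_ss, swan_ss, sess_ss = root.spawn(3)
        lam = float(np.clip(sampler(np.random.default_rng(lam_ss)), 0.0, 1.0))
        pid = f"P{i + 1:03d}"
        profile = ParticipantProfile(participant_id=pid, lam=lam, **profile_kwargs)
        profiles.append(profile)
        swans.append(sample_swan(profile, swan_ss))
        logs.append(
            simulate_session(sched, behavior_policy(profile), pid, sess_ss, airtime)
        )
    return Cohort(profiles=profiles, swan=swans, logs=logs)
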