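"""Synthetic fission-fusion focal-follow data with planted social structure.

The generator emulates scan and event sampling of a community of wild chimpanzees:
12 focal individuals followed in 18-minute focal follows of 9 instantaneous scans at
2-minute intervals. Social structure is *planted*: a latent symmetric dyadic affinity
``alpha`` on [0, 1] drives party co-membership exposure, within-10-m proximity
(logistic link on affinity), grooming conditional on proximity, and per-category
communication event rates per hour spent in proximity. A total dominance order drives
pant-grunt direction (always lower- to higher-ranked) and the rates of dominance
gestures (increasing in rank distance).

Because the truth is planted, every downstream stage — dyadic rate measures, network
construction, bond classification, permutation inference — has a known target to
recover, which is what the test suite exercises.

All randomness flows from a single root seed through named substreams
(``community`` / ``scans`` / ``events``), so each stage is independently reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .records import (
    CommEvent,
    GESTURE_FUNCTIONS,
    GROOMING_CATEGORIES,
    PANT_GRUNT,
    PANT_HOOT_FUNCTIONS,
    ScanRecord,
)

__all__ = [
    "CommunityConfig",
    "AffinityModel",
    "FollowPlan",
    "ConfigError",
    "generate_community",
    "generate_scans",
    "generate_events",
    "generate_dataset",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG stream of a root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# Study-group demography: 12 focal adults, 6 male / 6 female, with observation
# effort (total follow minutes), oestrus flags and the alpha pair.
# ---------------------------------------------------------------------------

STUDY_GROUP = pd.DataFrame(
    [
        # id, sex, age_years, minutes_observed, oestrous, alpha
        ("BB", "M", 21, 516, False, False),
        ("HW", "M", 15, 1030, False, False),
        ("KT", "M", 15, 1026, False, False),
        ("KU", "F", 29, 910, False, False),
        ("KW", "F", 27, 510, False, False),
        ("ML", "F", 33, 1118, True, False),
        ("MS", "M", 17, 524, False, False),
        ("NB", "F", 46, 500, True, True),
        ("NK", "M", 26, 582, False, True),
        ("RH", "F", 43, 1038, False, False),
        ("SQ", "M", 17, 554, False, False),
        ("ZM", "F", 40, 710, True, False),
    ],
    columns=["id", "sex", "age_years", "minutes_observed", "oestrous", "alpha"],
)

#: Default dominance order (most dominant first): alpha male, then the remaining
#: males, then the alpha female and remaining females. Invented plumbing — the study
#: community's full rank order is not published; pant-grunt direction only requires a
#: total order.
DEFAULT_RANK_ORDER = ("NK", "BB", "HW", "KT", "MS", "SQ", "NB", "KU", "KW", "ML", "RH", "ZM")

#: Default maternal-kin pairs (synthetic; the community's pedigree is not published).
DEFAULT_KIN_PAIRS = frozenset({frozenset({"NB", "ZM"})})

#: Per-category communication rates, events (sequences) per hour in proximity,
#: averaged over all ordered dyads. Magnitudes follow the observed per-function means.
DEFAULT_EVENT_RATES: dict[str, float] = {
    "Threat to dominate": 0.07,
    "Food sharing": 0.002,
    "Other threat": 0.07,
    "Travel": 0.034,
    "Copulation": 0.14,
    "Reassurance": 0.08,
    "Greeting": 0.27,
    "Gesture to mutually groom": 0.07,
    "Gesture to receive groom": 0.20,
    "Gesture to give groom": 0.37,
    "Play": 0.17,
    "Synchronized low-intensity pant-hoot": 0.049,
    "Solo high-intensity pant-hoot": 0.08,
    "Synchronized high-intensity pant-hoot": 0.20,
    PANT_GRUNT: 0.33,
}

#: Categories whose rates increase with rank distance rather than affinity.
DOMINANCE_FUNCTIONS = ("Threat to dominate", "Other threat")

#: Grooming time budget, minutes per hour in proximity, by category, dyad average.
DEFAULT_GROOMING_RATES = {"given": 0.69, "received": 0.53, "mutual": 0.66}

#: Beta prior of the latent symmetric affinity. Right-skewed: most dyads weakly
#: bonded, a few strongly bonded.
ALPHA_BETA_SHAPE = (0.8, 1.5)

#: Two generic morphological type labels per function, used to exercise the
#: repertoire-filter machinery; real gesture-type coding is out of scope.
def _gesture_types_for(category: str) -> tuple[str, str]:
    stem = category.lower().replace(" ", "-")
    return (f"{stem}/type-a", f"{stem}/type-b")


@dataclass(frozen=True)
class CommunityConfig:
    """Demography and sampling design of the synthetic community."""

    n_focal: int = 12
    n_nonfocal: int = 0
    sexes: tuple[str, ...] = tuple(STUDY_GROUP["sex"])
    ages: tuple[float, ...] = tuple(STUDY_GROUP["age_years"])
    ids: tuple[str, ...] = tuple(STUDY_GROUP["id"])
    minutes_observed: tuple[int, ...] = tuple(STUDY_GROUP["minutes_observed"])
    kin_pairs: frozenset[frozenset[str]] = DEFAULT_KIN_PAIRS
    oestrous_ids: frozenset[str] = frozenset(STUDY_GROUP.loc[STUDY_GROUP.oestrous, "id"])
    rank_order: tuple[str, ...] = DEFAULT_RANK_ORDER
    seed: int = 0

    def validate(self) -> None:
        n = self.n_focal + self.n_nonfocal
        if self.n_focal < 3:
            raise ConfigError(f"n_focal={self.n_focal} below minimum 3")
        if self.n_nonfocal < 0:
            raise ConfigError(f"n_nonfocal={self.n_nonfocal} negative")
        if len(self.ids) != n:
            raise ConfigError(f"ids: expected {n} labels, got {len(self.ids)}")
        if len(set(self.ids)) != n:
            raise ConfigError("ids: duplicate labels")
        if len(self.sexes) != n or any(s not in ("M", "F") for s in self.sexes):
            raise ConfigError("sexes: need one of M/F per individual")
        if len(self.ages) != n or any(a <= 0 for a in self.ages):
            raise ConfigError("ages: need one positive age per individual")
        if len(self.minutes_observed) != self.n_focal or any(
            m <= 0 for m in self.minutes_observed
        ):
            raise ConfigError("minutes_observed: need positive minutes per focal")
        if sorted(self.rank_order) != sorted(self.ids):
            raise ConfigError("rank_order: must be a total order over all ids")
        known = set(self.ids)
        for pair in self.kin_pairs:
            if len(pair) != 2 or not pair <= known:
                raise ConfigError(f"kin_pairs: bad pair {sorted(pair)}")
        if not self.oestrous_ids <= known:
            raise ConfigError("oestrous_ids: unknown ids")

    @property
    def focal_ids(self) -> tuple[str, ...]:
        return self.ids[: self.n_focal]

    @classmethod
    def synthetic(cls, n_focal: int, n_nonfocal: int = 0, seed: int = 0) -> "CommunityConfig":
        """Random demography for community sizes other than the shipped study group."""
        rng = substream(seed, "demography")
        n = n_focal + n_nonfocal
        ids = tuple(f"I{i:02d}" for i in range(n))
        sexes = tuple(rng.choice(["M", "F"], size=n))
        ages = tuple(float(a) for a in rng.integers(13, 48, size=n))
        minutes = tuple(int(m) for m in rng.integers(500, 1119, size=n_focal))
        females = [i for i, s in zip(ids, sexes) if s == "F"]
        oestrous = frozenset(rng.choice(females, size=1)) if females else frozenset()
        rank = tuple(rng.permutation(ids))
        return cls(
            n_focal=n_focal,
            n_nonfocal=n_nonfocal,
            sexes=sexes,
            ages=ages,
            ids=ids,
            minutes_observed=minutes,
            kin_pairs=frozenset(),
            oestrous_ids=oestrous,
            rank_order=rank,
            seed=seed,
        )


@dataclass
class AffinityModel:
    """Planted social process: latent affinity, link functions, and event rates.

    ``alpha`` is the symmetric latent affinity; ``alpha_dir`` adds mean-zero
    directional noise (clipped to [0, 1]) so proximity can be non-reciprocated,
    which is what makes preferred non-reciprocated bonds possible downstream.

    The proximity link is logistic in the directional affinity:
    ``P(within 10 m | same party) = expit(logit(prox_base) + prox_slope * (a - 1/2))``.
    Grooming and affiliative gesture rates scale as normalized powers of affinity so
    the dyad-average rates equal the configured per-category magnitudes while the
    distribution across dyads stays strongly right-skewed, as observed rate tables
    in this literature are.
    """

    ids: tuple[str, ...]
    alpha: np.ndarray  # symmetric (n, n), zero diagonal
    alpha_dir: np.ndarray  # directional (n, n), zero diagonal
    rank_order: tuple[str, ...]
    party_prob: float = 0.55
    prox_base: float = 0.58
    prox_slope: float = 12.0
    asymmetry_scale: float = 0.08
    grooming_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROOMING_RATES)
    )
    grooming_exponent: float = 5.5
    event_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    affinity_exponent: float = 5.5
    alpha_beta_shape: tuple[float, float] = ALPHA_BETA_SHAPE

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.alpha = np.asarray(self.alpha, float)
        self.alpha_dir = np.asarray(self.alpha_dir, float)
        if self.alpha.shape != (n, n) or self.alpha_dir.shape != (n, n):
            raise ConfigError("alpha matrices must be (n, n)")
        if not np.allclose(self.alpha, self.alpha.T):
            raise ConfigError("alpha must be symmetric")
        for m in (self.alpha, self.alpha_dir):
            if np.any((m < 0) | (m > 1)):
                raise ConfigError("affinities must lie in [0, 1]")
        if not 0 <= self.party_prob <= 1 or not 0 <= self.prox_base <= 1:
            raise ConfigError("party_prob and prox_base must lie in [0, 1]")
        if any(r < 0 for r in self.event_rates.values()):
            raise ConfigError("event rates must be nonnegative")
        if any(r < 0 for r in self.grooming_rates.values()):
            raise ConfigError("grooming rates must be nonnegative")
        self._index = {i: k for k, i in enumerate(self.ids)}
        self._rank = {i: k for k, i in enumerate(self.rank_order)}

    # -- link functions ----------------------------------------------------

    def prox_prob(self, a: str, b: str) -> float:
        """P(a records b within 10 m | b in a's party)."""
        if self.prox_base <= 0.0:
            return 0.0
        if self.prox_base >= 1.0:
            return 1.0
        x = self.alpha_dir[self._index[a], self._index[b]]
        return float(expit(logit(self.prox_base) + self.prox_slope * (x - 0.5)))

    def _affinity_weight(self, a: str, b: str, exponent: float) -> float:
        """alpha^k normalized by the prior mean of alpha^k (dataset-average ~ 1)."""
        x = self.alpha[self._index[a], self._index[b]]
        sa, sb = self.alpha_beta_shape
        # E[alpha^k] for alpha ~ Beta(sa, sb)
        mean_pow = math.exp(
            math.lgamma(sa + exponent)
            + math.lgamma(sa + sb)
            - math.lgamma(sa)
            - math.lgamma(sa + sb + exponent)
        )
        return x**exponent / mean_pow

    def groom_prob(self, a: str, b: str) -> float:
        """Per-scan probability that a grooms with b, given b within 10 m."""
        total = sum(self.grooming_rates.values()) / 60.0
        return min(1.0, total * self._affinity_weight(a, b, self.grooming_exponent))

    def rank_distance_weight(self, a: str, b: str) -> float:
        n = len(self.ids)
        mean_dist = (n + 1) / 3.0  # mean |r_i - r_j| over ordered pairs of 0..n-1
        return abs(self._rank[a] - self._rank[b]) / mean_dist

    def event_rate(self, category: str, a: str, b: str) -> float:
        """Per-hour-in-proximity event rate for the ordered dyad (a, b)."""
        base = self.event_rates.get(category, 0.0)
        if base == 0.0:
            return 0.0
        if category == PANT_GRUNT:
            # only lower- to higher-ranked; doubled so the all-dyad mean is preserved
            return 2.0 * base if self._rank[a] > self._rank[b] else 0.0
        if category in DOMINANCE_FUNCTIONS:
            return base * self.rank_distance_weight(a, b)
        if category in PANT_HOOT_FUNCTIONS:
            return base  # broadcast call: node-level rate, not affinity-weighted
        return base * self._affinity_weight(a, b, self.affinity_exponent)

    def outranks(self, a: str, b: str) -> bool:
        return self._rank[a] < self._rank[b]


@dataclass(frozen=True)
class Follow:
    focal_id: str
    follow_id: str
    start: datetime


@dataclass
class FollowPlan:
    """Sampling skeleton: per-focal follows of 9 scans at 2-minute intervals."""

    follows: list[Follow]
    n_scans: int = 9
    scan_interval_min: int = 2
    min_gap_min: int = 20
    minutes_range: tuple[int, int] | None = None

    @property
    def follow_minutes(self) -> int:
        return self.n_scans * self.scan_interval_min

    def validate(self) -> None:
        if self.n_scans < 1 or self.scan_interval_min < 1:
            raise ConfigError("n_scans and scan_interval_min must be positive")
        per_focal: dict[str, list[Follow]] = {}
        for f in self.follows:
            per_focal.setdefault(f.focal_id, []).append(f)
        for focal, fs in per_focal.items():
            fs.sort(key=lambda f: f.start)
            for prev, nxt in zip(fs, fs[1:]):
                gap = (nxt.start - prev.start).total_seconds() / 60.0
                if gap < self.follow_minutes + self.min_gap_min:
                    raise ConfigError(
                        f"follows for {focal} closer than the {self.min_gap_min}-min "
                        f"independence gap"
                    )
            if self.minutes_range is not None:
                total = len(fs) * self.follow_minutes
                lo, hi = self.minutes_range
                if not lo <= total <= hi:
                    raise ConfigError(
                        f"{focal}: total {total} follow minutes outside [{lo}, {hi}]"
                    )

    def total_minutes(self, focal_id: str) -> int:
        return sum(1 for f in self.follows if f.focal_id == focal_id) * self.follow_minutes

    @classmethod
    def from_minutes(
        cls,
        minutes_per_focal: dict[str, int],
        start: datetime = datetime(2008, 3, 1, 7, 0),
    ) -> "FollowPlan":
        """Schedule round-robin follows totalling roughly the requested minutes.

        Follows for distinct focals are interleaved through 07:00-16:00 field days;
        consecutive follows of the same focal end up well past the 20-min gap.
        """
        follows: list[Follow] = []
        remaining = {f: max(1, round(m / 18)) for f, m in minutes_per_focal.items()}
        t = start
        counter = {f: 0 for f in minutes_per_focal}
        last_start: dict[str, datetime] = {}
        min_spacing = timedelta(minutes=18 + 20)  # follow length + independence gap
        while any(v > 0 for v in remaining.values()):
            for focal in minutes_per_focal:
                if remaining[focal] <= 0:
                    continue
                if focal in last_start and t < last_start[focal] + min_spacing:
                    t = last_start[focal] + min_spacing
                if t.hour >= 16:  # end of field day
                    t = (t + timedelta(days=1)).replace(hour=7, minute=0)
                counter[focal] += 1
                follows.append(Follow(focal, f"{focal}-F{counter[focal]:03d}", t))
                last_start[focal] = t
                remaining[focal] -= 1
                t += timedelta(minutes=20)
        return cls(follows)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_community(config: CommunityConfig) -> tuple[pd.DataFrame, AffinityModel]:
    """Realize the community: node attribute table plus the planted affinity model.

    Deterministic given ``config.seed``. The returned :class:`AffinityModel` is the
    ground truth against which recovery of the social structure can be tested.
    """
    config.validate()
    rng = substream(config.seed, "community")
    n = len(config.ids)
    sa, sb = ALPHA_BETA_SHAPE
    tri = rng.beta(sa, sb, size=n * (n - 1) // 2)
    alpha = np.zeros((n, n))
    alpha[np.triu_indices(n, 1)] = tri
    alpha = alpha + alpha.T
    model = AffinityModel(
        ids=config.ids,
        alpha=alpha,
        alpha_dir=alpha.copy(),
        rank_order=config.rank_order,
    )
    noise = rng.normal(0.0, model.asymmetry_scale, size=(n, n))
    np.fill_diagonal(noise, 0.0)
    model.alpha_dir = np.clip(alpha + noise, 0.0, 1.0)
    np.fill_diagonal(model.alpha_dir, 0.0)

    rank_of = {i: k + 1 for k, i in enumerate(config.rank_order)}
    kin_ids = {
        i: ";".join(sorted({p for pair in config.kin_pairs if i in pair for p in pair} - {i}))
        for i in config.ids
    }
    attrs = pd.DataFrame(
        {
            "id": config.ids,
            "sex": config.sexes,
            "age_years": config.ages,
            "is_focal": [i < config.n_focal for i in range(n)],
            "minutes_observed": list(config.minutes_observed) + [0] * config.n_nonfocal,
            "oestrous": [i in config.oestrous_ids for i in config.ids],
            "rank": [rank_of[i] for i in config.ids],
            "kin_ids": [kin_ids[i] for i in config.ids],
        }
    )
    return attrs, model


def default_follow_plan(config: CommunityConfig) -> FollowPlan:
    """Follow plan matching the per-focal observation minutes of the study design."""
    return FollowPlan.from_minutes(dict(zip(config.focal_ids, config.minutes_observed)))


def generate_scans(
    plan: FollowPlan, model: AffinityModel, seed: int = 0
) -> list[ScanRecord]:
    """Simulate instantaneous scan records for every follow in the plan.

    Party membership is resampled once per follow (fission-fusion changes are slow
    relative to the 2-min scan tick); within-10-m membership is drawn per scan per
    party member from the logistic proximity link; a grooming partner (at most one
    per scan) is drawn among within-10-m neighbors with affinity-weighted probability.
    """
    plan.validate()
    rng = substream(seed, "scans")
    others_of = {i: [j for j in model.ids if j != i] for i in model.ids}
    groom_cats = list(model.grooming_rates)
    groom_total = sum(model.grooming_rates.values())
    groom_w = (
        np.array([model.grooming_rates[c] / groom_total for c in groom_cats])
        if groom_total > 0
        else None
    )
    records: list[ScanRecord] = []
    for follow in sorted(plan.follows, key=lambda f: (f.start, f.focal_id)):
        focal = follow.focal_id
        others = others_of[focal]
        party = [b for b in others if rng.random() < model.party_prob]
        p10 = np.array([model.prox_prob(focal, b) for b in party])
        pg = np.array([model.groom_prob(focal, b) for b in party])
        for s in range(plan.n_scans):
            ts = follow.start + timedelta(minutes=plan.scan_interval_min * s)
            if party:
                near_mask = rng.random(len(party)) < p10
            else:
                near_mask = np.zeros(0, dtype=bool)
            within10 = [b for b, m in zip(party, near_mask) if m]
            grooming, partner = "none", None
            if within10 and groom_w is not None:
                cand = [
                    b
                    for b, m, p in zip(party, near_mask, pg)
                    if m and rng.random() < p
                ]
                if cand:
                    partner = cand[int(rng.integers(len(cand)))]
                    grooming = groom_cats[int(rng.choice(len(groom_cats), p=groom_w))]
            records.append(
                ScanRecord(
                    focal_id=focal,
                    follow_id=follow.follow_id,
                    scan_index=s + 1,
                    timestamp=ts,
                    party_ids=frozenset(party),
                    within10_ids=frozenset(within10),
                    grooming=grooming,
                    grooming_partner=partner,
                )
            )
    return records


def generate_events(
    scans: list[ScanRecord], model: AffinityModel, seed: int = 0
) -> list[CommEvent]:
    """Simulate the continuous communication record accompanying the scans.

    Within each 2-minute scan interval, events toward each concurrent within-10-m
    neighbor arrive as a Poisson process at the planted per-dyad rate (events per hour
    in proximity). Pant-hoots are broadcast: the signaller emits them at the node-level
    rate whenever at least one neighbor is within 10 m, and *all* within-10-m
    individuals are recipients. Pant-grunts are emitted only up the hierarchy.
    """
    if not scans:
        return []
    rng = substream(seed, "events")
    dt_hours = 2.0 / 60.0
    events: list[CommEvent] = []
    counter = 0
    dyadic_cats = [
        c
        for c in list(GESTURE_FUNCTIONS) + [PANT_GRUNT]
        if model.event_rates.get(c, 0.0) > 0
    ]
    hoot_cats = [c for c in PANT_HOOT_FUNCTIONS if model.event_rates.get(c, 0.0) > 0]
    for scan in sorted(scans, key=lambda s: (s.timestamp, s.focal_id)):
        near = sorted(scan.within10_ids)
        if not near:
            continue
        focal = scan.focal_id

        def emit(category: str, recipients: frozenset[str], k: int) -> None:
            nonlocal counter
            offsets = np.sort(rng.random(k)) * 120.0
            for off in offsets:
                counter += 1
                is_gesture = category in GESTURE_FUNCTIONS
                gtype = None
                flags = (False,) * 5
                if is_gesture:
                    gtype = _gesture_types_for(category)[int(rng.integers(2))]
                    flags = tuple(bool(f) for f in rng.random(5) < 0.45)
                    if rng.random() < 0.85 and not any(flags):
                        flags = (True,) + flags[1:]
                events.append(
                    CommEvent(
                        event_id=f"E{counter:06d}",
                        timestamp=scan.timestamp + timedelta(seconds=float(off)),
                        signaller_id=focal,
                        recipient_ids=recipients,
                        category=category,
                        gesture_type=gtype,
                        goal=category if is_gesture else None,
                        context="field" if is_gesture else None,
                        intentionality_flags=flags,
                    )
                )

        for b in near:
            for cat in dyadic_cats:
                rate = model.event_rate(cat, focal, b)
                if rate <= 0:
                    continue
                k = int(rng.poisson(rate * dt_hours))
                if k:
                    emit(cat, frozenset({b}), k)
        for cat in hoot_cats:
            k = int(rng.poisson(model.event_rates[cat] * dt_hours))
            if k:
                emit(cat, frozenset(near), k)
    events.sort(key=lambda e: (e.timestamp, e.event_id))
    return events


def generate_dataset(
    config: CommunityConfig | None = None, plan: FollowPlan | None = None
) -> tuple[pd.DataFrame, AffinityModel, list[ScanRecord], list[CommEvent]]:
    """Convenience: community -> follow plan -> scans -> events, one root seed."""
    config = config or CommunityConfig()
    attrs, model = generate_community(config)
    plan = plan or default_follow_plan(config)
    scans = generate_scans(plan, model, seed=config.seed)
    events = generate_events(scans, model, seed=config.seed)
    return attrs, model, scans, events
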